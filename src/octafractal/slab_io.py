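"""Reading and writing of slab images, masks, metadata tables and result tables.

Cohort layout on disk::

    cohort_dir/
        eyes.csv                # one row per eye (clinical covariates + NPA label)
        <eye_id>/
            <eye_id>_SCP.png
            <eye_id>_DCP.png

Images are single-channel PNG or TIFF, 8- or 16-bit; 16-bit input is linearly
rescaled by its maximum so the histogram shape survives for Otsu thresholding.
Masks are written as 8-bit PNG with values {0, 255}.  Tables are RFC-4180 CSV,
UTF-8, "." decimal separator.  Pixel coordinates are row-major, origin
top-left, 0-based.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

MIN_DIM = 32

# ITU-R BT.601 luma weights, used to collapse RGB(A) input deterministically.
_LUMA = np.array([0.299, 0.587, 0.114])


class Plexus(str, enum.Enum):
    """Retinal capillary layer of an en-face slab."""

    SCP = "SCP"
    DCP = "DCP"


class Group(str, enum.Enum):
    """Perfusion group: NPA iff at least one peripheral quadrant is non-perfused."""

    NPA = "NPA"
    WELL_PERFUSED = "WELL_PERFUSED"


@dataclass(frozen=True)
class OCTASlab:
    """One grayscale en-face OCTA slab (nominally a 3x3 mm macular scan)."""

    eye_id: str
    plexus: Plexus
    pixels: np.ndarray  # 2-D uint8
    scan_width_mm: float = 3.0
    scan_height_mm: float = 3.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"slab pixels must be 2-D, got ndim={px.ndim}")
        if min(px.shape) < MIN_DIM:
            raise ValidationError(
                f"slab must be at least {MIN_DIM}x{MIN_DIM}, got {px.shape}"
            )
        if px.dtype != np.uint8:
            raise ValidationError(f"slab pixels must be uint8, got {px.dtype}")
        if self.scan_width_mm <= 0 or self.scan_height_mm <= 0:
            raise ValidationError("scan dimensions must be positive")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class EyeRecord:
    """Per-eye clinical covariates plus the FA-derived non-perfusion label."""

    eye_id: str
    npa_quadrants: int
    bcva_letters: float
    cmt_um: float
    age_years: float
    sex: str
    diabetes_type: str

    def __post_init__(self) -> None:
        if self.npa_quadrants not in (0, 1, 2, 3, 4):
            raise ValidationError(
                f"npa_quadrants must be in 0..4, got {self.npa_quadrants}"
            )
        if self.cmt_um <= 0:
            raise ValidationError(f"cmt_um must be positive, got {self.cmt_um}")
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.diabetes_type not in ("T1", "T2"):
            raise ValidationError(
                f"diabetes_type must be 'T1' or 'T2', got {self.diabetes_type!r}"
            )

    @property
    def group(self) -> Group:
        return Group.NPA if self.npa_quadrants >= 1 else Group.WELL_PERFUSED


EYE_TABLE_COLUMNS = [
    "eye_id",
    "npa_quadrants",
    "bcva_letters",
    "cmt_um",
    "age_years",
    "sex",
    "diabetes_type",
]


def _to_gray_uint8(arr: np.ndarray) -> np.ndarray:
    """Collapse channels and rescale to uint8 deterministically.

    8-bit input (including luma-collapsed 8-bit RGB) keeps its scale; deeper
    bit depths are linearly rescaled by the image maximum.
    """
    a = np.asarray(arr)
    was_8bit = a.dtype == np.uint8
    if a.ndim == 3:
        if a.shape[2] in (3, 4):
            a = a[:, :, :3].astype(np.float64) @ _LUMA
        elif a.shape[2] == 1:
            a = a[:, :, 0]
        else:
            raise ValidationError(f"unsupported channel count {a.shape[2]}")
    elif a.ndim != 2:
        raise ValidationError(f"unsupported image dimensionality {a.ndim}")
    if a.dtype == np.uint8:
        return a
    a = a.astype(np.float64)
    amax = a.max()
    if not was_8bit and amax > 0:
        a = a * (255.0 / amax)
    return np.rint(a).clip(0, 255).astype(np.uint8)


def read_slab(path: os.PathLike | str, plexus: Plexus | str, eye_id: str) -> OCTASlab:
    """Read a PNG/TIFF slab image into an :class:`OCTASlab`.

    Multi-channel input is collapsed to luminance; bit depths above 8 are
    rescaled by the image maximum.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"slab image not found: {path}")
    try:
        raw = iio.imread(path)
    except (IOError, OSError):
        raise
    except Exception as exc:  # undecodable content
        raise IOError(f"cannot decode image {path}: {exc}") from exc
    return OCTASlab(eye_id=eye_id, plexus=Plexus(plexus), pixels=_to_gray_uint8(raw))


def write_slab(slab: OCTASlab, path: os.PathLike | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, slab.pixels)
    return path


def write_mask(mask: np.ndarray, path: os.PathLike | str) -> Path:
    """Write a boolean mask as an 8-bit PNG with values {0, 255}."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))
    return path


def read_mask(path: os.PathLike | str) -> np.ndarray:
    arr = iio.imread(Path(path))
    return np.asarray(arr) > 0


def read_eye_table(path: os.PathLike | str) -> list[EyeRecord]:
    """Read ``eyes.csv``; one :class:`EyeRecord` per row, order preserved."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"eye table not found: {path}")
    df = pd.read_csv(path)
    for col in EYE_TABLE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"eye table missing required column '{col}'")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                EyeRecord(
                    eye_id=str(row["eye_id"]),
                    npa_quadrants=int(row["npa_quadrants"]),
                    bcva_letters=float(row["bcva_letters"]),
                    cmt_um=float(row["cmt_um"]),
                    age_years=float(row["age_years"]),
                    sex=str(row["sex"]),
                    diabetes_type=str(row["diabetes_type"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return records


def write_eye_table(records: Sequence[EyeRecord], path: os.PathLike | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [
            {
                "eye_id": r.eye_id,
                "npa_quadrants": r.npa_quadrants,
                "bcva_letters": r.bcva_letters,
                "cmt_um": r.cmt_um,
                "age_years": r.age_years,
                "sex": r.sex,
                "diabetes_type": r.diabetes_type,
            }
            for r in records
        ],
        columns=EYE_TABLE_COLUMNS,
    )
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.12g")
    return path


_PLEXUS_ORDER = {Plexus.SCP: 0, Plexus.DCP: 1}

FEATURE_TABLE_COLUMNS = ["eye_id", "plexus", "fd", "lac", "fit_r2", "n_box_sizes"]


def write_feature_table(rows: Iterable[dict], path: os.PathLike | str) -> Path:
    """Write per-slab fractal features as CSV.

    Each row dict needs keys ``eye_id, plexus, fd, lac, fit_r2, n_box_sizes``.
    Ordering is a pure function of content: by eye_id, then SCP before DCP.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = list(rows)
    df = pd.DataFrame(rows, columns=FEATURE_TABLE_COLUMNS)
    if len(df):
        df["plexus"] = df["plexus"].map(lambda p: Plexus(p).value)
        df = df.sort_values(
            by=["eye_id", "plexus"],
            key=lambda s: s.map(lambda v: _PLEXUS_ORDER[Plexus(v)]) if s.name == "plexus" else s,
            kind="mergesort",
        ).reset_index(drop=True)
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.12g")
    return path


def read_feature_table(path: os.PathLike | str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError(f"feature table not found: {path}")
    df = pd.read_csv(path)
    for col in FEATURE_TABLE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"feature table missing required column '{col}'")
    return df


def slab_path(cohort_dir: os.PathLike | str, eye_id: str, plexus: Plexus | str) -> Path:
    plexus = Plexus(plexus)
    return Path(cohort_dir) / eye_id / f"{eye_id}_{plexus.value}.png"


def load_cohort(cohort_dir: os.PathLike | str) -> tuple[list[EyeRecord], dict[tuple[str, Plexus], OCTASlab]]:
    """Load a cohort directory: eye table plus both slabs per eye.

    Raises an I/O error naming every eye whose slab images are missing.
    """
    cohort_dir = Path(cohort_dir)
    records = read_eye_table(cohort_dir / "eyes.csv")
    slabs: dict[tuple[str, Plexus], OCTASlab] = {}
    missing: list[str] = []
    for rec in records:
        for plexus in (Plexus.SCP, Plexus.DCP):
            p = slab_path(cohort_dir, rec.eye_id, plexus)
            if not p.exists():
                missing.append(f"{rec.eye_id}:{plexus.value}")
                continue
            slabs[(rec.eye_id, plexus)] = read_slab(p, plexus, rec.eye_id)
    if missing:
        raise IOError("missing slab images for: " + ", ".join(sorted(missing)))
    return records, slabs
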