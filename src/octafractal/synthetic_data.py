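"""Synthetic fixtures and a calibrated synthetic DME cohort.

Two kinds of output:

* **Analytic fixtures** with known fractal dimension (filled square,
  one-pixel line, single pixel, Sierpinski carpet, random dust) used to
  validate the box-counting estimator against closed forms.

* **A synthetic cohort** of en-face capillary-plexus slabs plus clinical
  covariates.  Each slab is a capillary-mesh-like texture: the near-zero
  level set of band-pass-filtered Gaussian noise forms a connected lace of
  vessel ribbons, a central disk is cleared as the foveal avascular zone,
  and ischemic dropout is modeled by clearing randomly placed elliptical
  patches until a target fraction of vessel area is removed.  Per-eye
  dropout grows linearly with the number of peripherally non-perfused
  quadrants.

The generator's free constants (`BASE_DENSITY_*`, `DROPOUT_PER_QUADRANT`,
mesh scale) are calibration constants: they were fixed once by a grid search
so that the *measured* pipeline FD/LAC group means approximate the target
group statistics in :class:`GroupCalibration`, and are committed here as
versioned numbers.  Tests never re-calibrate them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .exceptions import ValidationError
from .slab_io import (
    EyeRecord,
    OCTASlab,
    Plexus,
    slab_path,
    write_eye_table,
    write_slab,
)

# --------------------------------------------------------------------------
# analytic fixtures


class FixtureKind(str, enum.Enum):
    FILLED = "FILLED"
    LINE = "LINE"
    SINGLE_PIXEL = "SINGLE_PIXEL"
    SIERPINSKI_CARPET = "SIERPINSKI_CARPET"
    RANDOM_DUST = "RANDOM_DUST"


@dataclass(frozen=True)
class FixtureSpec:
    kind: FixtureKind
    size_px: int = 64
    level: int = 0  # carpet recursion depth
    density: float = 0.05  # RANDOM_DUST only
    seed: int = 0  # RANDOM_DUST only


def sierpinski_carpet(level: int) -> np.ndarray:
    """Level-n Sierpinski carpet on a 3^n grid (center ninth removed each level)."""
    if level < 0:
        raise ValidationError("carpet level must be >= 0")
    c = np.ones((1, 1), dtype=bool)
    for _ in range(level):
        n = c.shape[0]
        nxt = np.zeros((3 * n, 3 * n), dtype=bool)
        for i in range(3):
            for j in range(3):
                if (i, j) != (1, 1):
                    nxt[i * n : (i + 1) * n, j * n : (j + 1) * n] = c
        c = nxt
    return c


def make_fixture(spec: FixtureSpec) -> np.ndarray:
    """Deterministic boolean bitmap for a validation fixture."""
    n = spec.size_px
    if spec.kind is FixtureKind.SIERPINSKI_CARPET:
        if n != 3**spec.level:
            raise ValidationError(
                f"carpet of level {spec.level} must have size 3^{spec.level} = {3**spec.level}, got {n}"
            )
        return sierpinski_carpet(spec.level)
    if n < 1:
        raise ValidationError("size_px must be positive")
    if spec.kind is FixtureKind.FILLED:
        return np.ones((n, n), dtype=bool)
    if spec.kind is FixtureKind.LINE:
        img = np.zeros((n, n), dtype=bool)
        img[n // 2, :] = True
        return img
    if spec.kind is FixtureKind.SINGLE_PIXEL:
        img = np.zeros((n, n), dtype=bool)
        img[n // 2, n // 2] = True
        return img
    if spec.kind is FixtureKind.RANDOM_DUST:
        rng = np.random.default_rng(spec.seed)
        return rng.random((n, n)) < spec.density
    raise ValidationError(f"unknown fixture kind {spec.kind}")


# --------------------------------------------------------------------------
# plexus texture generator

# Calibration constants — fixed by a one-off grid search against the fractal
# pipeline (see docs/methods.md); committed, never tuned at test time.
MESH_SIGMA_PX = 0.8          # Gaussian scale of the band-pass field; sets mesh cell size
BASE_DENSITY_SCP = 0.50      # vessel area fraction before FAZ/dropout, SCP
BASE_DENSITY_DCP = 0.55      # slightly denser deep plexus
DROPOUT_PER_QUADRANT = 0.24  # vessel-area fraction removed per non-perfused quadrant
DROPOUT_JITTER_SD = 0.02     # per-eye jitter on total dropout fraction
MAX_DROPOUT = 0.95           # ceiling on per-eye dropout fraction
PATCH_AXIS_FRAC = (0.01, 0.04)  # ischemic patch semi-axes, fraction of image width
FAZ_RADIUS_FRAC = 0.10       # FAZ radius as a fraction of image width (~0.3 mm on 3 mm)
DEFAULT_IMAGE_SIZE = 256

_VESSEL_LEVEL = 185.0
_BACKGROUND_LEVEL = 45.0
_RENDER_NOISE_SD = 14.0


def _mesh_field(size_px: int, rng: np.random.Generator) -> np.ndarray:
    """Band-pass filtered white noise; its zero level set is a connected lace."""
    noise = rng.standard_normal((size_px, size_px))
    lo = ndimage.gaussian_filter(noise, MESH_SIGMA_PX)
    hi = ndimage.gaussian_filter(noise, 2.5 * MESH_SIGMA_PX)
    return lo - hi


def generate_plexus(
    density: float,
    dropout: float,
    faz_radius_frac: float = FAZ_RADIUS_FRAC,
    size_px: int = DEFAULT_IMAGE_SIZE,
    seed: int | np.random.SeedSequence = 0,
    eye_id: str = "synthetic",
    plexus: Plexus = Plexus.SCP,
) -> OCTASlab:
    """Render one synthetic en-face plexus slab as an 8-bit grayscale image.

    ``density`` is the vessel area fraction of the intact mesh; ``dropout``
    the fraction of that vessel area cleared by ischemic patches.  Fully
    reproducible from ``seed``.
    """
    if not 0.0 < density <= 1.0:
        raise ValidationError(f"density must be in (0, 1], got {density}")
    if not 0.0 <= dropout < 1.0:
        raise ValidationError(f"dropout must be in [0, 1), got {dropout}")
    if size_px < 32:
        raise ValidationError("size_px must be >= 32")
    rng = np.random.default_rng(seed)

    field_ = _mesh_field(size_px, rng)
    # vessels = pixels nearest the zero level set, up to the requested area
    q = np.quantile(np.abs(field_), density)
    mask = np.abs(field_) <= q

    # foveal avascular zone
    yy, xx = np.mgrid[:size_px, :size_px]
    center = (size_px - 1) / 2.0
    faz_r = faz_radius_frac * size_px
    mask &= (yy - center) ** 2 + (xx - center) ** 2 > faz_r**2

    # ischemic dropout: clear elliptical patches until the target vessel area
    # fraction is removed; each patch is rasterized only on its bounding box
    target_removed = dropout * mask.sum()
    removed = 0
    guard = 0
    while removed < target_removed and guard < 20_000:
        guard += 1
        cy, cx = rng.uniform(0, size_px, 2)
        a = rng.uniform(*PATCH_AXIS_FRAC) * size_px  # semi-axes
        b = rng.uniform(*PATCH_AXIS_FRAC) * size_px
        theta = rng.uniform(0, np.pi)
        rmax = max(a, b)
        y0 = max(int(cy - rmax) - 1, 0)
        y1 = min(int(cy + rmax) + 2, size_px)
        x0 = max(int(cx - rmax) - 1, 0)
        x1 = min(int(cx + rmax) + 2, size_px)
        if y0 >= y1 or x0 >= x1:
            continue
        dy = yy[y0:y1, x0:x1] - cy
        dx = xx[y0:y1, x0:x1] - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        patch = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        sub = mask[y0:y1, x0:x1]
        removed += int((sub & patch).sum())
        sub &= ~patch

    img = np.where(mask, _VESSEL_LEVEL, _BACKGROUND_LEVEL)
    img = img + rng.normal(0.0, _RENDER_NOISE_SD, img.shape)
    # sparse salt speckle, removed downstream by the median filter
    salt = rng.random(img.shape) < 0.002
    img[salt] = 255.0
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return OCTASlab(eye_id=eye_id, plexus=plexus, pixels=pixels)


# --------------------------------------------------------------------------
# cohort generator


@dataclass(frozen=True)
class CohortSpec:
    """Composition and generator settings of a synthetic cohort.

    Defaults reproduce the study composition: 50 eyes, 60% with peripheral
    non-perfusion, and 6/4/9/11 NPA eyes with 1/2/3/4 affected quadrants.
    """

    n_eyes: int = 50
    npa_fraction: float = 0.60
    quadrant_distribution: tuple[int, int, int, int] = (6, 4, 9, 11)
    dropout_per_quadrant: float = DROPOUT_PER_QUADRANT
    base_density: float = BASE_DENSITY_SCP
    base_density_dcp: float = BASE_DENSITY_DCP
    image_size_px: int = DEFAULT_IMAGE_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        n_npa = round(self.n_eyes * self.npa_fraction)
        if sum(self.quadrant_distribution) != n_npa:
            raise ValidationError(
                f"quadrant_distribution sums to {sum(self.quadrant_distribution)}, "
                f"expected round({self.n_eyes} * {self.npa_fraction}) = {n_npa}"
            )
        if not 0.0 <= self.dropout_per_quadrant <= 1.0:
            raise ValidationError("dropout_per_quadrant must be in [0, 1]")


@dataclass(frozen=True)
class GroupStats:
    mean: float
    sd: float


@dataclass(frozen=True)
class GroupCalibration:
    """Target group-level statistics the generator is calibrated against.

    Defaults transcribe the study's group summaries (mean +/- SD): fractal
    parameters per plexus for the NPA and well-perfused groups, and the
    clinical covariates.
    """

    fd_scp_npa: GroupStats = GroupStats(1.21, 0.58)
    fd_scp_wp: GroupStats = GroupStats(1.92, 0.03)
    lac_scp_npa: GroupStats = GroupStats(0.39, 0.06)
    lac_scp_wp: GroupStats = GroupStats(0.31, 0.08)
    fd_dcp_npa: GroupStats = GroupStats(1.25, 0.40)
    fd_dcp_wp: GroupStats = GroupStats(1.94, 0.03)
    lac_dcp_npa: GroupStats = GroupStats(0.38, 0.05)
    lac_dcp_wp: GroupStats = GroupStats(0.31, 0.06)
    bcva_npa: GroupStats = GroupStats(61.83, 12.23)
    bcva_wp: GroupStats = GroupStats(64.70, 12.64)
    cmt_npa: GroupStats = GroupStats(442.13, 115.75)
    cmt_wp: GroupStats = GroupStats(420.28, 106.02)
    age_npa: GroupStats = GroupStats(63.8, 10.51)
    age_wp: GroupStats = GroupStats(70.40, 9.84)
    male_frac_npa: float = 16 / 30
    male_frac_wp: float = 11 / 20


def _truncnorm(rng: np.random.Generator, stats: GroupStats, lo: float, hi: float) -> float:
    """Normal draw truncated by rejection to a plausible clinical range."""
    for _ in range(1000):
        x = rng.normal(stats.mean, stats.sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(stats.mean, lo, hi))


def generate_cohort(
    spec: CohortSpec = CohortSpec(),
    calib: GroupCalibration = GroupCalibration(),
) -> tuple[list[EyeRecord], dict[tuple[str, Plexus], OCTASlab]]:
    """Generate the full synthetic cohort: eye records plus SCP/DCP slabs.

    All randomness flows from ``spec.seed`` through a spawned
    ``numpy.random.SeedSequence`` tree: one child per eye for covariates,
    plus one grandchild per plexus for the image texture.
    """
    quadrant_labels = [0] * (spec.n_eyes - sum(spec.quadrant_distribution))
    for q, count in enumerate(spec.quadrant_distribution, start=1):
        quadrant_labels.extend([q] * count)
    if len(quadrant_labels) != spec.n_eyes:
        raise ValidationError("quadrant distribution does not match n_eyes")

    root = np.random.SeedSequence(spec.seed)
    eye_seeds = root.spawn(spec.n_eyes)

    records: list[EyeRecord] = []
    slabs: dict[tuple[str, Plexus], OCTASlab] = {}
    for i, (q, eye_ss) in enumerate(zip(quadrant_labels, eye_seeds)):
        eye_id = f"eye{i + 1:03d}"
        cov_rng = np.random.default_rng(eye_ss)
        npa = q >= 1
        bcva = _truncnorm(cov_rng, calib.bcva_npa if npa else calib.bcva_wp, 0, 100)
        cmt = _truncnorm(cov_rng, calib.cmt_npa if npa else calib.cmt_wp, 150, 900)
        age = _truncnorm(cov_rng, calib.age_npa if npa else calib.age_wp, 18, 95)
        sex = "M" if cov_rng.random() < (calib.male_frac_npa if npa else calib.male_frac_wp) else "F"
        dm = "T1" if cov_rng.random() < 0.15 else "T2"
        records.append(
            EyeRecord(
                eye_id=eye_id,
                npa_quadrants=q,
                bcva_letters=round(bcva, 1),
                cmt_um=round(cmt, 1),
                age_years=round(age, 1),
                sex=sex,
                diabetes_type=dm,
            )
        )
        dropout = spec.dropout_per_quadrant * q
        if q >= 1:
            dropout += cov_rng.normal(0.0, DROPOUT_JITTER_SD)
        dropout = float(np.clip(dropout, 0.0, MAX_DROPOUT))
        scp_ss, dcp_ss = eye_ss.spawn(2)
        slabs[(eye_id, Plexus.SCP)] = generate_plexus(
            spec.base_density, dropout, size_px=spec.image_size_px,
            seed=scp_ss, eye_id=eye_id, plexus=Plexus.SCP,
        )
        slabs[(eye_id, Plexus.DCP)] = generate_plexus(
            spec.base_density_dcp, dropout, size_px=spec.image_size_px,
            seed=dcp_ss, eye_id=eye_id, plexus=Plexus.DCP,
        )
    return records, slabs


def write_cohort(
    out_dir: Path | str,
    spec: CohortSpec = CohortSpec(),
    calib: GroupCalibration = GroupCalibration(),
) -> Path:
    """Generate a cohort and write it in the on-disk layout."""
    out_dir = Path(out_dir)
    records, slabs = generate_cohort(spec, calib)
    write_eye_table(records, out_dir / "eyes.csv")
    for (eye_id, plexus), slab in slabs.items():
        write_slab(slab, slab_path(out_dir, eye_id, plexus))
    return out_dir
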