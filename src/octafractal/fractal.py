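"""Box-counting fractal dimension and gliding-box lacunarity on skeletons.

Fractal dimension (FD) is the slope of the ordinary least-squares fit of
log N(eps) against log(1/eps), where N(eps) is the number of eps x eps grid
boxes containing at least one skeleton pixel, averaged over several grid
origins to suppress grid-phase variance.  For planar images FD lies in
[0, 2]: 0 for a point, 1 for a smooth curve, 2 for a space-filling set.

Lacunarity (LAC) quantifies the "gappiness" of the same skeleton: an r x r
window glides with unit step over every fully contained position, the vessel
mass M per window is recorded, and

    Lambda(r) = <M^2> / <M>^2  =  1 + CV^2(M).

A translation-invariant texture has Lambda = 1; clustered, gap-rich textures
have Lambda >> 1.  The scalar summary reported per slab is the mean over r of
the normalized value  Lambda_n(r) = 1 - 1/Lambda(r), which lies in [0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import (
    DegenerateInputError,
    EmptyMaskError,
    StageError,
    ValidationError,
)
from .preprocess import BinaryMap, SkeletonMap, binarize, skeletonize
from .slab_io import OCTASlab


@dataclass(frozen=True)
class BoxCountCurve:
    """Mean occupied-box count N(eps) per box size, across grid origins."""

    box_sizes_px: tuple[int, ...]
    counts: tuple[float, ...]
    n_origins: int

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.box_sizes_px)
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValidationError("box sizes must be strictly increasing")
        if any(c <= 0 for c in self.counts):
            raise ValidationError("box counts must be strictly positive")
        if self.n_origins < 1:
            raise ValidationError("n_origins must be >= 1")
        object.__setattr__(self, "box_sizes_px", sizes)
        object.__setattr__(self, "counts", tuple(float(c) for c in self.counts))


@dataclass(frozen=True)
class FractalResult:
    """FD, LAC and fit diagnostics for one slab."""

    fd: float
    fd_raw: float  # pre-clamp OLS slope
    lac: float
    fit_r2: float
    curve: BoxCountCurve
    lac_curve: tuple[tuple[int, float], ...]
    otsu_threshold: int | None = None
    n_skeleton_px: int | None = None


def default_box_sizes(shape: tuple[int, int]) -> list[int]:
    """Dyadic ladder 2, 4, ..., up to floor(min(H, W) / 4)."""
    top = min(shape) // 4
    sizes = []
    s = 2
    while s <= top:
        sizes.append(s)
        s *= 2
    if len(sizes) < 3:
        raise ValidationError(f"image of shape {shape} too small for a 3-point ladder")
    return sizes


def fd_fit_sizes(shape: tuple[int, int]) -> list[int]:
    """Default FD fit range: the four coarsest sizes of the dyadic ladder.

    The finest dyadic scales probe the one-pixel width of the skeleton
    strands rather than the space-filling of the network, so the slope is
    fitted over the coarsest four sizes (8..64 px on a 256 px slab); smaller
    images use the whole ladder.
    """
    sizes = default_box_sizes(shape)
    return sizes[-4:] if len(sizes) > 4 else sizes


def lac_window_sizes(shape: tuple[int, int]) -> list[int]:
    """Default lacunarity windows: the dyadic ladder above the strand width."""
    sizes = default_box_sizes(shape)
    return sizes[1:] if len(sizes) > 4 else sizes


def grid_offsets(box_size: int, n_origins: int) -> list[tuple[int, int]]:
    """Deterministic grid origins on a uniform lattice over [0, eps)^2.

    The lattice is k x k with k = ceil(sqrt(n_origins)); offsets are taken in
    row-major order, so (0, 0) always comes first.
    """
    if n_origins < 1:
        raise ValidationError("n_origins must be >= 1")
    k = int(np.ceil(np.sqrt(n_origins)))
    lattice = [(i * box_size // k, j * box_size // k) for i in range(k) for j in range(k)]
    return lattice[:n_origins]


def _count_occupied(skeleton: np.ndarray, eps: int, offset: tuple[int, int]) -> int:
    """Occupied-box count for one grid origin; partial edge boxes participate.

    The grid origin sits at (-oy, -ox), so pixel (r, c) falls in box
    ((r + oy) // eps, (c + ox) // eps).
    """
    rows, cols = np.nonzero(skeleton)
    iy = (rows + offset[0]) // eps
    ix = (cols + offset[1]) // eps
    n_ix = int(ix.max()) + 1 if ix.size else 0
    return int(np.unique(iy * n_ix + ix).size)


def box_count(
    skeleton: SkeletonMap | np.ndarray,
    box_sizes: Sequence[int] | None = None,
    n_origins: int = 4,
) -> BoxCountCurve:
    """Multi-origin box counting of a binary skeleton.

    For each box size the occupied-box count is evaluated at ``n_origins``
    deterministic grid offsets (see :func:`grid_offsets`) and the mean count
    is stored.
    """
    skel = skeleton.skeleton if isinstance(skeleton, SkeletonMap) else np.asarray(skeleton, bool)
    if not skel.any():
        raise EmptyMaskError("cannot box-count an empty skeleton")
    if box_sizes is None:
        box_sizes = default_box_sizes(skel.shape)
    box_sizes = [int(b) for b in box_sizes]
    if any(b < 1 for b in box_sizes):
        raise ValidationError("box sizes must be >= 1")
    if max(box_sizes) > min(skel.shape):
        raise ValidationError(
            f"box size {max(box_sizes)} exceeds image dimension {min(skel.shape)}"
        )
    counts = []
    for eps in box_sizes:
        per_origin = [_count_occupied(skel, eps, off) for off in grid_offsets(eps, n_origins)]
        counts.append(float(np.mean(per_origin)))
    return BoxCountCurve(box_sizes_px=tuple(box_sizes), counts=tuple(counts), n_origins=n_origins)


def fit_fd(curve: BoxCountCurve) -> tuple[float, float, float]:
    """OLS fit of log N(eps) on log(1/eps).

    Returns ``(fd, fd_raw, fit_r2)`` where ``fd`` is the slope clamped to
    [0, 2], ``fd_raw`` the unclamped slope, and ``fit_r2`` the coefficient of
    determination of the regression.
    """
    if len(curve.box_sizes_px) < 3:
        raise ValidationError("FD fit requires at least 3 box sizes")
    x = np.log(1.0 / np.asarray(curve.box_sizes_px, dtype=np.float64))
    y = np.log(np.asarray(curve.counts, dtype=np.float64))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    fd_raw = float(slope)
    return float(np.clip(fd_raw, 0.0, 2.0)), fd_raw, float(r2)


def gliding_box_lacunarity(
    skeleton: SkeletonMap | np.ndarray,
    box_sizes: Sequence[int] | None = None,
) -> list[tuple[int, float]]:
    """Gliding-box lacunarity Lambda(r) = <M^2>/<M>^2 per window size.

    The r x r window visits every fully contained position with step 1.
    Sizes whose windows carry zero total mass are skipped; if every size is
    skipped a :class:`DegenerateInputError` is raised.
    """
    skel = skeleton.skeleton if isinstance(skeleton, SkeletonMap) else np.asarray(skeleton, bool)
    if not skel.any():
        raise EmptyMaskError("cannot compute lacunarity of an empty skeleton")
    if box_sizes is None:
        box_sizes = default_box_sizes(skel.shape)
    H, W = skel.shape
    # summed-area table with a zero border: window sums in O(1) per position
    sat = np.zeros((H + 1, W + 1), dtype=np.int64)
    np.cumsum(np.cumsum(skel, axis=0), axis=1, out=sat[1:, 1:])
    out: list[tuple[int, float]] = []
    for r in box_sizes:
        r = int(r)
        if r < 1 or r > min(H, W):
            raise ValidationError(f"window size {r} invalid for image of shape {skel.shape}")
        m = (
            sat[r:, r:] - sat[:-r, r:] - sat[r:, :-r] + sat[:-r, :-r]
        ).astype(np.float64)
        mean = m.mean()
        if mean == 0.0:
            continue  # no mass visible at this size
        out.append((r, float(np.mean(m * m) / (mean * mean))))
    if not out:
        raise DegenerateInputError("no window size carried vessel mass")
    return out


def summarize_lac(lac_curve: Sequence[tuple[int, float]], mode: str = "normalized") -> float:
    """Scalar lacunarity summary across window sizes.

    ``normalized`` (default): mean of Lambda_n(r) = 1 - 1/Lambda(r), in [0, 1).
    ``raw``: mean of Lambda(r).  ``cv2``: mean of Lambda(r) - 1 = CV^2(M).
    """
    if not lac_curve:
        raise ValidationError("lacunarity curve is empty")
    lams = np.asarray([lam for _, lam in lac_curve], dtype=np.float64)
    if mode == "normalized":
        return float(np.mean(1.0 - 1.0 / lams))
    if mode == "raw":
        return float(np.mean(lams))
    if mode == "cv2":
        return float(np.mean(lams - 1.0))
    raise ValidationError(f"unknown lacunarity summary mode {mode!r}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the per-slab pipeline."""

    filter_order: str = "pre"
    median_radius_px: int = 2
    box_sizes: tuple[int, ...] | None = None  # None -> dyadic auto ladder
    n_origins: int = 4
    lac_box_sizes: tuple[int, ...] | None = None  # None -> same auto ladder
    lac_normalization: str = "normalized"


def analyze_skeleton(skel: SkeletonMap, config: AnalysisConfig = AnalysisConfig()) -> FractalResult:
    """FD and LAC of an existing skeleton (no preprocessing stages)."""
    fd_sizes = config.box_sizes if config.box_sizes is not None else fd_fit_sizes(skel.skeleton.shape)
    lac_sizes = (
        config.lac_box_sizes if config.lac_box_sizes is not None else lac_window_sizes(skel.skeleton.shape)
    )
    curve = box_count(skel, fd_sizes, config.n_origins)
    fd, fd_raw, r2 = fit_fd(curve)
    lac_curve = gliding_box_lacunarity(skel, lac_sizes)
    lac = summarize_lac(lac_curve, config.lac_normalization)
    return FractalResult(
        fd=fd,
        fd_raw=fd_raw,
        lac=lac,
        fit_r2=r2,
        curve=curve,
        lac_curve=tuple(lac_curve),
        n_skeleton_px=skel.n_pixels,
    )


def analyze_slab(slab: OCTASlab, config: AnalysisConfig = AnalysisConfig()) -> FractalResult:
    """Full per-slab pipeline: binarize -> skeletonize -> FD + LAC.

    Stage errors are re-raised as :class:`StageError` naming the stage.
    """
    try:
        binary = binarize(slab, config.median_radius_px, config.filter_order)
    except Exception as exc:
        raise StageError("binarize", exc) from exc
    try:
        skel = skeletonize(binary)
    except Exception as exc:
        raise StageError("skeletonize", exc) from exc
    try:
        result = analyze_skeleton(skel, config)
    except Exception as exc:
        raise StageError("fractal", exc) from exc
    return FractalResult(
        fd=result.fd,
        fd_raw=result.fd_raw,
        lac=result.lac,
        fit_r2=result.fit_r2,
        curve=result.curve,
        lac_curve=result.lac_curve,
        otsu_threshold=binary.otsu_threshold,
        n_skeleton_px=skel.n_pixels,
    )
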