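"""Quantitative burden heatmaps and spatial-resolution matching.

Binary positive-pixel masks are aggregated into percent-positive maps on
a metric grid (the 1 mm^2 tile map used for voxel-wise comparison with
PET), and histology maps are smoothed to the PET's effective resolution:
the smoothness of a field is summarised by the full width at half
maximum (FWHM) of the equivalent Gaussian kernel, estimated from the
variance ratio of first differences of a stationary Gaussian random
field, and fields are blurred iteratively until their estimated FWHM
matches a target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .segmentation import BinaryMask

__all__ = [
    "BurdenHeatmap",
    "SmoothnessEstimate",
    "percent_positive_heatmap",
    "estimate_fwhm",
    "blur_to_fwhm",
    "resample_heatmap",
]

# FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class BurdenHeatmap:
    """Fraction of marker-positive pixels per metric grid cell."""

    grid: np.ndarray
    spacing_mm: float
    valid_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.grid.shape != self.valid_mask.shape:
            raise ValueError("valid_mask must match grid shape")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        vals = self.grid[self.valid_mask & np.isfinite(self.grid)]
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("burden fractions must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape


@dataclass
class SmoothnessEstimate:
    """Per-axis FWHM of the equivalent Gaussian smoothing kernel, in mm.

    An axis whose difference variance is incompatible with a positive
    kernel width (d^2 >= 2 s^2, i.e. no detectable smoothness) is marked
    inestimable with NaN.
    """

    fwhm_mm: tuple[float, ...]
    method: str = "variance_ratio"

    @property
    def mean_fwhm_mm(self) -> float:
        vals = [f for f in self.fwhm_mm if np.isfinite(f)]
        return float(np.mean(vals)) if vals else float("nan")

    def estimable(self) -> bool:
        return all(np.isfinite(f) for f in self.fwhm_mm)


def percent_positive_heatmap(
    mask: BinaryMask, tile_mm: float = 1.0, min_coverage: float = 0.5
) -> BurdenHeatmap:
    """Aggregate a binary mask into per-tile positive fractions.

    Each source pixel is assigned to the tile containing its centre
    (tiles anchored at the image's top-left corner); a tile's value is
    positive pixels / total pixels in the tile.  Edge tiles covering less
    than ``min_coverage`` of a full tile's pixel budget are marked
    invalid rather than silently diluting fractions.  Positive pixels are
    conserved: sum(cell * pixels_in_cell) equals the mask's positive
    count.
    """
    px_mm = mask.pixel_size_um / 1000.0
    if tile_mm < px_mm:
        raise ValueError("tile size must be at least one pixel")
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must lie in (0, 1]")
    n_rows, n_cols = mask.shape
    row_idx = np.floor((np.arange(n_rows) + 0.5) * px_mm / tile_mm).astype(int)
    col_idx = np.floor((np.arange(n_cols) + 0.5) * px_mm / tile_mm).astype(int)
    nt_r, nt_c = row_idx[-1] + 1, col_idx[-1] + 1
    flat = (row_idx[:, None] * nt_c + col_idx[None, :]).ravel()
    total = np.bincount(flat, minlength=nt_r * nt_c).astype(float)
    pos = np.bincount(flat, weights=mask.grid.ravel().astype(float),
                      minlength=nt_r * nt_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, pos / np.maximum(total, 1), np.nan)
    full_tile = (tile_mm / px_mm) ** 2
    valid = (total / full_tile) >= min_coverage
    grid = frac.reshape(nt_r, nt_c)
    grid = np.where(np.isnan(grid), 0.0, grid)
    return BurdenHeatmap(
        grid=grid,
        spacing_mm=tile_mm,
        valid_mask=valid.reshape(nt_r, nt_c),
        provenance={
            "op": "percent_positive_heatmap",
            "pixel_size_um": mask.pixel_size_um,
            "tile_mm": tile_mm,
            "min_coverage": min_coverage,
            "threshold_used": mask.threshold_used,
        },
    )


def _as_spacing(spacing_mm, ndim: int) -> np.ndarray:
    s = np.atleast_1d(np.asarray(spacing_mm, dtype=float))
    if s.size == 1:
        s = np.full(ndim, s[0])
    if s.size != ndim or np.any(s <= 0):
        raise ValueError("spacing must be positive, scalar or one value per axis")
    return s


def estimate_fwhm(
    field: np.ndarray, spacing_mm, mask: np.ndarray | None = None
) -> SmoothnessEstimate:
    """Estimate per-axis smoothing FWHM from first-difference variances.

    For a stationary Gaussian random field smoothed with a Gaussian of
    width sigma, the variance d^2 of first differences along an axis with
    grid step h and the field variance s^2 satisfy
    ``d^2 / (2 s^2) = 1 - exp(-h^2 / (4 sigma^2))``, giving

        FWHM = h * sqrt(-2 ln 2 / ln(1 - d^2 / (2 s^2)))

    Differences are taken only between pairs of valid cells; axes with
    d^2 >= 2 s^2 (white noise or rougher) are inestimable (NaN).
    """
    field = np.asarray(field, dtype=float)
    spacing = _as_spacing(spacing_mm, field.ndim)
    if mask is None:
        mask = np.ones(field.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != field.shape:
            raise ValueError("mask must match field shape")
    vals = field[mask]
    if vals.size < 100:
        raise ValueError("need at least 100 valid cells to estimate FWHM")
    s2 = float(np.var(vals, ddof=1))
    if s2 == 0:
        raise ValueError("field is constant within the mask; FWHM undefined")
    fwhm = []
    for ax in range(field.ndim):
        sl_a = [slice(None)] * field.ndim
        sl_b = [slice(None)] * field.ndim
        sl_a[ax] = slice(1, None)
        sl_b[ax] = slice(None, -1)
        pair_ok = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        d = (field[tuple(sl_a)] - field[tuple(sl_b)])[pair_ok]
        if d.size < 2:
            fwhm.append(float("nan"))
            continue
        d2 = float(np.mean(d * d))
        ratio = d2 / (2.0 * s2)
        if ratio >= 1.0 or ratio <= 0.0:
            fwhm.append(float("nan"))
            continue
        fwhm.append(float(spacing[ax] * np.sqrt(-2.0 * np.log(2.0) / np.log1p(-ratio))))
    return SmoothnessEstimate(fwhm_mm=tuple(fwhm))


def _masked_gaussian(field, mask, sigma_cells) -> np.ndarray:
    """Gaussian smoothing with kernels renormalized over valid cells."""
    if np.all(np.asarray(sigma_cells) == 0):
        return field.copy()
    m = mask.astype(float)
    num = gaussian_filter(field * m, sigma=sigma_cells, mode="constant", cval=0.0)
    den = gaussian_filter(m, sigma=sigma_cells, mode="constant", cval=0.0)
    out = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return out


def blur_to_fwhm(
    field: np.ndarray,
    spacing_mm,
    target_fwhm_mm: float,
    *,
    mask: np.ndarray | None = None,
    tolerance: float = 0.02,
    max_iter: int = 25,
) -> tuple[np.ndarray, SmoothnessEstimate, bool]:
    """Smooth a field until its estimated FWHM matches a target.

    The cumulative kernel width per axis starts at
    sqrt(target^2 - current^2) (current taken as 0 on inestimable axes,
    i.e. below grid scale) and is refined by re-estimating the smoothed
    field: composition of Gaussians is additive in squared width, so an
    undershoot adds the missing squared width while an overshoot removes
    half the excess.  Smoothing always restarts from the original field
    with the cumulative kernel, so overshoots are recoverable.  Returns
    (smoothed field, final estimate, converged flag); a False flag means
    ``max_iter`` was reached outside tolerance.  Raises when the target
    is below the current estimate (a blur cannot sharpen).
    """
    field = np.asarray(field, dtype=float)
    spacing = _as_spacing(spacing_mm, field.ndim)
    if target_fwhm_mm <= 0:
        raise ValueError("target FWHM must be positive")
    if mask is None:
        mask = np.ones(field.shape, dtype=bool)
    current = estimate_fwhm(field, spacing, mask)
    cur = np.array([0.0 if not np.isfinite(f) else f for f in current.fwhm_mm])
    if np.any(cur > target_fwhm_mm * (1 + tolerance)):
        raise ValueError(
            f"target FWHM {target_fwhm_mm} mm is below the current estimate "
            f"{tuple(current.fwhm_mm)}; smoothing cannot sharpen"
        )
    if np.all(np.abs(cur - target_fwhm_mm) <= tolerance * target_fwhm_mm):
        return field.copy(), current, True
    total2 = np.maximum(target_fwhm_mm**2 - cur**2, 0.0)
    est = current
    smoothed = field
    for _ in range(max_iter):
        sigma_cells = np.sqrt(total2) / FWHM_PER_SIGMA / spacing
        smoothed = _masked_gaussian(field, mask, sigma_cells)
        est = estimate_fwhm(smoothed, spacing, mask)
        got = np.array([np.nan if not np.isfinite(f) else f for f in est.fwhm_mm])
        if np.any(~np.isfinite(got)):
            got = np.where(np.isfinite(got), got, 0.0)
        rel = np.abs(got - target_fwhm_mm) / target_fwhm_mm
        if np.all(rel <= tolerance):
            return smoothed, est, True
        under = got < target_fwhm_mm
        total2 = np.where(
            under,
            total2 + (target_fwhm_mm**2 - got**2),
            np.maximum(total2 - 0.5 * (got**2 - target_fwhm_mm**2), 0.0),
        )
    warnings.warn(
        f"blur_to_fwhm did not reach target {target_fwhm_mm} mm within "
        f"{max_iter} iterations (estimate {est.fwhm_mm})",
        RuntimeWarning,
    )
    return smoothed, est, False


def resample_heatmap(
    h: BurdenHeatmap, target_spacing_mm: float, mode: str = "mean"
) -> BurdenHeatmap:
    """Downsample a heatmap to a coarser metric grid.

    ``mean`` assigns each source cell to the target cell containing its
    centre and averages over valid source cells, conserving the
    area-weighted mean over the valid region; ``linear`` interpolates at
    target cell centres.
    """
    if target_spacing_mm < h.spacing_mm:
        raise ValueError("resample_heatmap only downsamples (target >= source spacing)")
    if mode not in ("mean", "linear"):
        raise ValueError(f"unknown resampling mode: {mode!r}")
    n_rows, n_cols = h.grid.shape
    ratio = h.spacing_mm / target_spacing_mm
    if mode == "mean":
        row_idx = np.floor((np.arange(n_rows) + 0.5) * ratio).astype(int)
        col_idx = np.floor((np.arange(n_cols) + 0.5) * ratio).astype(int)
        nt_r, nt_c = row_idx[-1] + 1, col_idx[-1] + 1
        flat = (row_idx[:, None] * nt_c + col_idx[None, :]).ravel()
        w = h.valid_mask.ravel().astype(float)
        den = np.bincount(flat, weights=w, minlength=nt_r * nt_c)
        num = np.bincount(flat, weights=w * h.grid.ravel(), minlength=nt_r * nt_c)
        with np.errstate(invalid="ignore", divide="ignore"):
            grid = np.where(den > 0, num / np.maximum(den, 1), 0.0)
        valid = den > 0
        grid = grid.reshape(nt_r, nt_c)
        valid = valid.reshape(nt_r, nt_c)
    else:
        nt_r = max(1, int(np.ceil(n_rows * ratio)))
        nt_c = max(1, int(np.ceil(n_cols * ratio)))
        # target cell centres in source index coordinates
        rr = ((np.arange(nt_r) + 0.5) * target_spacing_mm / h.spacing_mm) - 0.5
        cc = ((np.arange(nt_c) + 0.5) * target_spacing_mm / h.spacing_mm) - 0.5
        R, C = np.meshgrid(rr, cc, indexing="ij")
        coords = np.stack([R.ravel(), C.ravel()])
        grid = map_coordinates(h.grid, coords, order=1, mode="nearest").reshape(nt_r, nt_c)
        vm = map_coordinates(h.valid_mask.astype(float), coords, order=1,
                             mode="constant", cval=0.0).reshape(nt_r, nt_c)
        valid = vm >= 0.5
    grid = np.clip(grid, 0.0, 1.0)
    prov = dict(h.provenance)
    prov.update({"resampled_from_mm": h.spacing_mm, "mode": mode})
    return BurdenHeatmap(grid=grid, spacing_mm=target_spacing_mm,
                         valid_mask=valid, provenance=prov)
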