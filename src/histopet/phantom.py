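"""Seeded synthetic cohort: histology, warps and PET with known truth.

Every stage of the histology-to-PET pipeline gets a ground-truth answer:
a geometric label map stands in for the anatomy (cortical ribbon, deep
white matter, lentiform nucleus, hippocampus); marker masks emulate the
spatial texture of the three stains (clustered p-tau blobs, small ferric
iron puncta, diffuse MAO-B astrocytic staining) with region-controlled
positive fractions; probability maps emulate a pixel classifier's noisy
output; a smooth 2D warp with paired landmarks emulates section-to-
blockface distortion; and the PET volume is a known linear combination
of smoothed burdens plus Gaussian noise — the generative inverse of the
regression model the pipeline fits.

All generators are pure functions of their parameters and an explicit
integer seed; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .registration import LandmarkSet, Volume3D
from .segmentation import ProbabilityMap

__all__ = [
    "LABELS",
    "DEFAULT_DENSITIES",
    "PhantomLabelMap",
    "MarkerGroundTruth",
    "PETGroundTruth",
    "WarpGroundTruth",
    "generate_label_map",
    "upsample_labels",
    "generate_marker_truth",
    "corrupt_to_probability",
    "synthesize_pet",
    "random_smooth_warp",
    "warp_with_landmarks",
]

LABELS = {
    0: "background",
    1: "cortex",
    2: "white_matter",
    3: "lentiform",
    4: "hippocampus",
}
MARKERS = ("ptau", "iron", "maob")

# Plausible per-region positive fractions: cortex/hippocampus-dominant
# tau, lentiform-dominant iron, white-matter-dominant MAO-B.
DEFAULT_DENSITIES = {
    "ptau": {"cortex": 0.30, "white_matter": 0.05, "lentiform": 0.05,
             "hippocampus": 0.35, "background": 0.0},
    "iron": {"cortex": 0.03, "white_matter": 0.02, "lentiform": 0.25,
             "hippocampus": 0.05, "background": 0.0},
    "maob": {"cortex": 0.06, "white_matter": 0.25, "lentiform": 0.10,
             "hippocampus": 0.08, "background": 0.0},
}

DEFAULT_BLOB_SPECS = {
    # length scales in micrometres; chosen to mimic tangle clusters,
    # hemosiderin puncta and diffuse astrocytic texture respectively
    "ptau": {"blob_sigma_um": 80.0, "cluster_sigma_um": 600.0},
    "iron": {"punctum_sigma_um": 15.0},
    "maob": {"texture_sigma_um": 400.0},
}


@dataclass
class PhantomLabelMap:
    """Integer anatomy labels on a metric grid (2D section or 3D stack)."""

    grid: np.ndarray
    spacing_mm: tuple[float, ...]
    labels: dict[int, str] = field(default_factory=lambda: dict(LABELS))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim not in (2, 3):
            raise ValueError("label grid must be 2D or 3D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != self.grid.ndim:
            raise ValueError("one spacing per axis required")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        present = set(np.unique(self.grid).tolist())
        if not present <= set(self.labels):
            raise ValueError("grid contains labels missing from the legend")

    @property
    def name_to_label(self) -> dict[str, int]:
        return {v: k for k, v in self.labels.items()}

    def region_mask(self, name: str) -> np.ndarray:
        return self.grid == self.name_to_label[name]

    def slice2d(self, k: int) -> "PhantomLabelMap":
        if self.grid.ndim != 3:
            raise ValueError("slice2d requires a 3D label map")
        return PhantomLabelMap(self.grid[k].copy(), self.spacing_mm[1:],
                               dict(self.labels))


@dataclass
class MarkerGroundTruth:
    """Ground-truth positive-pixel mask for one marker at histology pitch."""

    marker: str
    mask: np.ndarray
    pixel_size_um: float
    region_density: dict[str, float]

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker: {self.marker!r}")
        self.mask = np.asarray(self.mask)
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        self.mask = self.mask.astype(np.uint8)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class PETGroundTruth:
    """Generative coefficients of the synthetic PET volume.

    SUVR(v) = beta0 + sum_m beta_m * burden_m(v) + N(0, noise_sd).
    """

    beta0: float
    betas: dict[str, float]
    noise_sd: float
    pet_fwhm_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pet_fwhm_mm <= 0:
            raise ValueError("pet_fwhm_mm must be > 0")
        unknown = set(self.betas) - set(MARKERS)
        if unknown:
            raise ValueError(f"unknown markers in betas: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {"beta0": self.beta0, "betas": dict(self.betas),
                "noise_sd": self.noise_sd, "pet_fwhm_mm": self.pet_fwhm_mm,
                "seed": self.seed}


def generate_label_map(
    shape: tuple[int, ...], spacing_mm: float | tuple[float, ...] = 1.0,
    seed: int = 0,
) -> PhantomLabelMap:
    """Generate the geometric anatomy phantom (2D section or 3D stack).

    The tissue is an ellipse/ellipsoid with a cortical ribbon along its
    boundary, white matter inside, and two compact interior blobs
    (lentiform nucleus and hippocampus).  Geometry is jittered slightly
    by the seed so different seeds give different phantoms; a given seed
    is fully deterministic.
    """
    shape = tuple(int(s) for s in shape)
    ndim = len(shape)
    if ndim not in (2, 3):
        raise ValueError("shape must be 2D or 3D")
    in_plane = shape if ndim == 2 else shape[1:]
    if min(in_plane) < 32:
        raise ValueError(
            "in-plane grid too small to host all regions "
            "(need >= 32 cells per axis; failing region: lentiform)"
        )
    if ndim == 3 and shape[0] < 1:
        raise ValueError("need at least one slice")
    spacing = np.atleast_1d(np.asarray(spacing_mm, dtype=float))
    if spacing.size == 1:
        spacing = np.full(ndim, spacing[0])
    if spacing.size != ndim or np.any(spacing <= 0):
        raise ValueError("spacing must be positive, scalar or per-axis")

    rng = np.random.default_rng(seed)
    dims = np.asarray(shape, dtype=float)
    centre = dims / 2.0 * (1.0 + rng.uniform(-0.02, 0.02, size=ndim))
    radii = dims * 0.44 * (1.0 + rng.uniform(-0.04, 0.04, size=ndim))
    if ndim == 3:
        radii[0] = dims[0] * 0.62  # keep every slice inside the tissue

    coords = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                         indexing="ij")

    def ellipsoid_rho(c, r):
        acc = np.zeros(shape, dtype=float)
        for ax in range(ndim):
            acc += ((coords[ax] - c[ax]) / r[ax]) ** 2
        return np.sqrt(acc)

    rho = ellipsoid_rho(centre, radii)
    tissue = rho <= 1.0
    ribbon_frac = 0.18
    inner = rho <= (1.0 - ribbon_frac)

    grid = np.zeros(shape, dtype=np.int16)
    grid[tissue & ~inner] = 1     # cortex
    grid[inner] = 2               # white matter

    def blob(rel_centre, rel_radius, jitter=0.02):
        c = centre + dims * (np.asarray(rel_centre)
                             + rng.uniform(-jitter, jitter, size=ndim))
        r = dims * np.asarray(rel_radius)
        return ellipsoid_rho(c, r) <= 1.0

    if ndim == 2:
        lent = blob((-0.06, -0.13), (0.11, 0.11))
        hipp = blob((0.12, 0.11), (0.08, 0.08))
    else:
        lent = blob((0.0, -0.06, -0.13), (0.30, 0.11, 0.11))
        hipp = blob((0.0, 0.12, 0.11), (0.26, 0.08, 0.08))
    grid[lent & inner] = 3
    grid[hipp & inner] = 4

    lm = PhantomLabelMap(grid=grid, spacing_mm=tuple(spacing))
    present = set(np.unique(grid).tolist())
    for lab, name in LABELS.items():
        if lab not in present:
            raise ValueError(f"grid too small to host region '{name}'")
    return lm


def upsample_labels(label_map: PhantomLabelMap, pixel_size_um: float) -> np.ndarray:
    """Nearest-neighbour upsampling of a 2D label map to histology pitch."""
    if label_map.grid.ndim != 2:
        raise ValueError("upsample_labels needs a 2D label map")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    px_mm = pixel_size_um / 1000.0
    sp_r, sp_c = label_map.spacing_mm
    n_rows = max(1, int(round(label_map.grid.shape[0] * sp_r / px_mm)))
    n_cols = max(1, int(round(label_map.grid.shape[1] * sp_c / px_mm)))
    row_cell = np.minimum(((np.arange(n_rows) + 0.5) * px_mm / sp_r).astype(int),
                          label_map.grid.shape[0] - 1)
    col_cell = np.minimum(((np.arange(n_cols) + 0.5) * px_mm / sp_c).astype(int),
                          label_map.grid.shape[1] - 1)
    return label_map.grid[np.ix_(row_cell, col_cell)]


def _texture_field(marker: str, shape: tuple[int, int], pixel_size_um: float,
                   blob_spec: dict | None, rng: np.random.Generator) -> np.ndarray:
    """Marker-specific continuous texture used to place positive pixels."""
    spec = dict(DEFAULT_BLOB_SPECS[marker])
    if blob_spec:
        spec.update(blob_spec)
    noise = rng.standard_normal(shape)

    def smooth_unit(n, sigma_um):
        sigma_px = max(sigma_um / pixel_size_um, 0.5)
        f = gaussian_filter(n, sigma=sigma_px, mode="wrap")
        sd = f.std()
        return f / sd if sd > 0 else f

    if marker == "ptau":
        fine = smooth_unit(noise, spec["blob_sigma_um"])
        coarse = smooth_unit(rng.standard_normal(shape), spec["cluster_sigma_um"])
        return fine + 0.8 * coarse
    if marker == "iron":
        return smooth_unit(noise, spec["punctum_sigma_um"])
    if marker == "maob":
        return smooth_unit(noise, spec["texture_sigma_um"])
    raise ValueError(f"unknown marker: {marker!r}")


def generate_marker_truth(
    label_map: PhantomLabelMap,
    marker: str,
    pixel_size_um: float = 10.0,
    density_spec: dict[str, float] | None = None,
    blob_spec: dict | None = None,
    seed: int = 0,
) -> MarkerGroundTruth:
    """Generate a ground-truth positive mask for one marker.

    The label map (2D) is upsampled to histology pitch; within each
    region the pixels whose marker texture is largest are set positive
    until the region's target fraction is met exactly (up to pixel
    discretization), so empirical densities match ``density_spec`` by
    construction while keeping marker-specific spatial texture.
    """
    if marker not in MARKERS:
        raise ValueError(f"unknown marker: {marker!r}")
    if label_map.grid.ndim != 2:
        raise ValueError("generate_marker_truth needs a 2D label map "
                         "(use PhantomLabelMap.slice2d on stacks)")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    densities = dict(DEFAULT_DENSITIES[marker])
    if density_spec is not None:
        unknown = set(density_spec) - set(label_map.name_to_label)
        if unknown:
            raise ValueError(f"unknown regions in density_spec: {sorted(unknown)}")
        densities.update(density_spec)
    for name, rho in densities.items():
        if not 0.0 <= rho <= 1.0:
            raise ValueError(f"density for {name!r} outside [0, 1]: {rho}")

    pixel_labels = upsample_labels(label_map, pixel_size_um)
    n_rows, n_cols = pixel_labels.shape

    rng = np.random.default_rng(seed)
    fld = _texture_field(marker, (n_rows, n_cols), pixel_size_um, blob_spec, rng)
    mask = np.zeros((n_rows, n_cols), dtype=np.uint8)
    flat_field = fld.ravel()
    flat_labels = pixel_labels.ravel()
    flat_mask = mask.ravel()
    for name, lab in label_map.name_to_label.items():
        rho = densities.get(name, 0.0)
        idx = np.flatnonzero(flat_labels == lab)
        if idx.size == 0 or rho == 0.0:
            continue
        k = int(round(rho * idx.size))
        if k == 0:
            continue
        if k >= idx.size:
            flat_mask[idx] = 1
            continue
        order = np.argpartition(flat_field[idx], idx.size - k)[idx.size - k:]
        flat_mask[idx[order]] = 1
    return MarkerGroundTruth(marker=marker, mask=mask,
                             pixel_size_um=pixel_size_um,
                             region_density=densities)


def _draw_unit_interval(rng, params, size) -> np.ndarray:
    """Sample from a [0,1]-supported spec: Beta(a, b) tuple or a constant."""
    if np.isscalar(params):
        val = float(params)
        if not 0.0 <= val <= 1.0:
            raise ValueError("constant probability value has mass outside [0, 1]")
        return np.full(size, val)
    a, b = params
    if a <= 0 or b <= 0:
        raise ValueError("Beta parameters must be positive")
    return rng.beta(a, b, size=size)


def corrupt_to_probability(
    truth: MarkerGroundTruth,
    pos_params=(5.0, 2.0),
    neg_params=(2.0, 5.0),
    seed: int = 0,
) -> ProbabilityMap:
    """Emulate a pixel classifier's probability map from the truth mask.

    Positive and background pixels draw from separate [0,1]-supported
    distributions (Beta by default, or degenerate constants); the default
    parameters give clearly separated but overlapping classes, like a
    well-trained but imperfect classifier.
    """
    rng = np.random.default_rng(seed)
    mask = truth.mask.astype(bool)
    p = np.empty(mask.shape, dtype=float)
    p[mask] = _draw_unit_interval(rng, pos_params, int(mask.sum()))
    p[~mask] = _draw_unit_interval(rng, neg_params, int((~mask).sum()))
    return ProbabilityMap(p, truth.pixel_size_um)


def synthesize_pet(
    burdens: dict[str, Volume3D | np.ndarray], gt: PETGroundTruth,
) -> Volume3D:
    """Build the SUVR volume as a linear combination of burdens plus noise.

    Voxelwise SUVR = beta0 + sum_m beta_m * burden_m + N(0, noise_sd),
    the generative inverse of the full regression model the statistics
    layer fits.  Markers absent from ``burdens`` contribute nothing.
    """
    arrays, spacing = {}, None
    for name, vol in burdens.items():
        arr = vol.data if isinstance(vol, Volume3D) else np.asarray(vol, float)
        arrays[name] = arr
        if isinstance(vol, Volume3D):
            spacing = vol.spacing_mm
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) > 1:
        raise ValueError(f"burden volumes have mismatched shapes: {sorted(shapes)}")
    shape = shapes.pop()
    suvr = np.full(shape, gt.beta0, dtype=float)
    for marker, beta in gt.betas.items():
        if marker in arrays and beta != 0.0:
            suvr = suvr + beta * arrays[marker]
    if gt.noise_sd > 0:
        rng = np.random.default_rng(gt.seed)
        suvr = suvr + rng.normal(0.0, gt.noise_sd, size=shape)
    if spacing is None:
        spacing = (1.0, 1.0, 1.0)
    return Volume3D(data=suvr, spacing_mm=spacing)


@dataclass
class WarpGroundTruth:
    """Known smooth 2D warp between section and blockface frames.

    The forward map T(x) = x + D(x) carries section coordinates into the
    reference (blockface) frame, with D a sum of Gaussian radial bumps
    at the control points.  ``landmark_src`` holds reference-frame
    points, ``landmark_dst`` the true corresponding section points;
    reported pairs add Gaussian placement jitter of ``landmark_jitter_sd``
    (mm) to the section side.
    """

    control_points: np.ndarray        # (n, 2) mm, section frame
    control_displacements: np.ndarray  # (n, 2) mm
    scale_mm: float
    landmark_src: np.ndarray          # (m, 2) reference frame
    landmark_dst: np.ndarray          # (m, 2) section frame
    landmark_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        self.control_points = np.atleast_2d(np.asarray(self.control_points, float))
        self.control_displacements = np.atleast_2d(
            np.asarray(self.control_displacements, float))
        self.landmark_src = np.atleast_2d(np.asarray(self.landmark_src, float))
        self.landmark_dst = np.atleast_2d(np.asarray(self.landmark_dst, float))
        if not np.isfinite(self.control_displacements).all():
            raise ValueError("control displacements must be finite")
        if self.landmark_src.shape[0] < 3:
            raise ValueError("need at least 3 landmark pairs")
        centered = self.landmark_src - self.landmark_src.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
            raise ValueError("landmark pairs are collinear")
        if self.landmark_jitter_sd < 0:
            raise ValueError("landmark_jitter_sd must be >= 0")
        if self.scale_mm <= 0:
            raise ValueError("scale_mm must be positive")

    def displacement(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        if self.control_points.shape[0] == 0:
            return np.zeros_like(pts)
        d2 = ((pts[:, None, :] - self.control_points[None, :, :]) ** 2).sum(axis=2)
        w = np.exp(-d2 / (2.0 * self.scale_mm**2))
        return w @ self.control_displacements

    def transform(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return pts + self.displacement(pts)

    def max_displacement(self, extent_mm: tuple[float, float],
                         n_probe: int = 25) -> float:
        xs = np.linspace(0, extent_mm[1], n_probe)
        ys = np.linspace(0, extent_mm[0], n_probe)
        X, Y = np.meshgrid(xs, ys)
        d = self.displacement(np.stack([X.ravel(), Y.ravel()], axis=1))
        return float(np.linalg.norm(d, axis=1).max())


def random_smooth_warp(
    extent_mm: tuple[float, float],
    max_disp_mm: float = 2.0,
    scale_mm: float | None = None,
    n_controls: int = 6,
    n_landmarks: int = 12,
    landmark_jitter_sd: float = 0.1,
    seed: int = 0,
) -> WarpGroundTruth:
    """Draw a random smooth warp with paired landmarks.

    Displacement bumps are rescaled so the peak displacement over the
    field of view equals ``max_disp_mm``; landmarks are placed on a
    jittered grid inside the central 80% of the extent so warped
    positions stay within the image.
    """
    h_mm, w_mm = extent_mm
    rng = np.random.default_rng(seed)
    if scale_mm is None:
        scale_mm = 0.35 * min(h_mm, w_mm)
    ctrl = rng.uniform([0.1 * w_mm, 0.1 * h_mm], [0.9 * w_mm, 0.9 * h_mm],
                       size=(n_controls, 2))
    disp = rng.normal(0.0, 1.0, size=(n_controls, 2))

    # landmark section points on a jittered grid in the central region
    n_side = max(2, int(np.ceil(np.sqrt(n_landmarks))))
    gx = np.linspace(0.15 * w_mm, 0.85 * w_mm, n_side)
    gy = np.linspace(0.15 * h_mm, 0.85 * h_mm, n_side)
    GX, GY = np.meshgrid(gx, gy)
    pts = np.stack([GX.ravel(), GY.ravel()], axis=1)
    take = rng.permutation(pts.shape[0])[:n_landmarks]
    q = pts[take] + rng.normal(0.0, 0.02 * min(h_mm, w_mm), size=(n_landmarks, 2))

    warp = WarpGroundTruth(
        control_points=ctrl, control_displacements=disp, scale_mm=scale_mm,
        landmark_src=q, landmark_dst=q, landmark_jitter_sd=landmark_jitter_sd,
    )
    if max_disp_mm > 0:
        peak = warp.max_displacement((h_mm, w_mm))
        scale = max_disp_mm / peak if peak > 0 else 0.0
        warp.control_displacements = warp.control_displacements * scale
    else:
        warp.control_displacements = warp.control_displacements * 0.0
    warp.landmark_src = warp.transform(q)
    warp.landmark_dst = q
    return warp


def warp_with_landmarks(
    image: np.ndarray,
    warp: WarpGroundTruth,
    seed: int = 0,
    spacing_mm: float = 1.0,
    interpolation: str = "linear",
) -> tuple[np.ndarray, LandmarkSet]:
    """Distort a reference image into section space under the true warp.

    The section image is produced by inverse-mapping resampling:
    section(x) = reference(T(x)) with T the true section-to-reference
    map.  Returns the warped image and the landmark pairs
    (src = reference frame, dst = section frame) with Gaussian placement
    jitter of ``warp.landmark_jitter_sd`` added to the section side.
    """
    if interpolation not in ("nearest", "linear"):
        raise ValueError(f"unknown interpolation mode: {interpolation!r}")
    image = np.asarray(image, dtype=float)
    n_r, n_c = image.shape
    extent = ((n_r - 1) * spacing_mm, (n_c - 1) * spacing_mm)
    fov = max(extent)
    max_d = warp.max_displacement(extent)
    if fov > 0 and max_d >= 0.10 * fov:
        raise ValueError(
            f"warp displacement {max_d:.2f} mm exceeds 10% of the field of "
            f"view ({fov:.1f} mm)"
        )
    xs = np.arange(n_c) * spacing_mm
    ys = np.arange(n_r) * spacing_mm
    X, Y = np.meshgrid(xs, ys)
    mapped = warp.transform(np.stack([X.ravel(), Y.ravel()], axis=1))
    col = mapped[:, 0] / spacing_mm
    row = mapped[:, 1] / spacing_mm
    order = 0 if interpolation == "nearest" else 1
    warped = map_coordinates(image, np.stack([row, col]), order=order,
                             mode="constant", cval=0.0).reshape(n_r, n_c)

    out_of_image = []
    for k, (x, y) in enumerate(warp.landmark_dst):
        if not (0 <= x <= (n_c - 1) * spacing_mm and 0 <= y <= (n_r - 1) * spacing_mm):
            out_of_image.append((k, float(x), float(y)))
    for k, (x, y) in enumerate(warp.landmark_src):
        if not (0 <= x <= (n_c - 1) * spacing_mm and 0 <= y <= (n_r - 1) * spacing_mm):
            out_of_image.append((k, float(x), float(y)))
    if out_of_image:
        raise ValueError(f"landmarks fall outside the image: {out_of_image}")

    rng = np.random.default_rng(seed)
    dst = warp.landmark_dst.copy()
    if warp.landmark_jitter_sd > 0:
        dst = dst + rng.normal(0.0, warp.landmark_jitter_sd, size=dst.shape)
    return warped, LandmarkSet(warp.landmark_src.copy(), dst)
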