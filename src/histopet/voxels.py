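"""SUVR normalization, PET-positivity ROIs and the voxel table.

The PET activity volume is normalized to a reference region (inferior
cerebellar gray matter on real data) to give the standardized uptake
value ratio (SUVR); tracer-positive regions of interest keep voxels with
SUVR strictly greater than a cutoff (1.2 by default, with 1.3/1.4 as
sensitivity settings); and the co-registered burdens are gathered into a
one-row-per-voxel table, the unit of all downstream statistics.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .phantom import PhantomLabelMap
from .registration import Volume3D

__all__ = [
    "compute_suvr",
    "build_roi_mask",
    "extract_voxel_table",
    "hexbin_counts",
]

MARKER_COLUMNS = ("ptau", "iron", "maob")


def _vol_data(v) -> np.ndarray:
    return v.data if isinstance(v, Volume3D) else np.asarray(v)


def compute_suvr(activity: Volume3D, reference_mask) -> Volume3D:
    """Divide voxel activity by the mean activity in the reference region."""
    act = _vol_data(activity).astype(float)
    ref = _vol_data(reference_mask).astype(bool)
    if act.shape != ref.shape:
        raise ValueError("activity and reference mask must share geometry")
    if not ref.any():
        raise ValueError("reference mask is empty")
    ref_mean = float(act[ref].mean())
    if ref_mean <= 0:
        raise ValueError(f"non-positive reference mean activity: {ref_mean}")
    spacing = activity.spacing_mm if isinstance(activity, Volume3D) else (1.0, 1.0, 1.0)
    return Volume3D(data=act / ref_mean, spacing_mm=spacing)


def build_roi_mask(
    suvr: Volume3D,
    threshold: float,
    anatomical_mask,
    label_map: PhantomLabelMap | None = None,
    structure_labels: list[str] | None = None,
) -> np.ndarray:
    """Binary ROI: SUVR strictly above threshold inside the anatomy.

    A voxel exactly at the threshold is excluded.  If structure names are
    given, the ROI is additionally restricted to those label-map regions.
    An empty result warns (it is a legitimate outcome at high cutoffs)
    rather than raising.
    """
    if threshold <= 0:
        raise ValueError("SUVR threshold must be positive")
    s = _vol_data(suvr)
    anat = _vol_data(anatomical_mask).astype(bool)
    if s.shape != anat.shape:
        raise ValueError("SUVR and anatomical mask must share geometry")
    roi = (s > threshold) & anat
    if structure_labels:
        if label_map is None:
            raise ValueError("structure_labels requires a label_map")
        if label_map.grid.shape != s.shape:
            raise ValueError("label map must share the SUVR geometry")
        keep = np.zeros_like(roi)
        for name in structure_labels:
            keep |= label_map.region_mask(name)
        roi &= keep
    if not roi.any():
        warnings.warn(
            f"ROI at SUVR > {threshold} is empty", RuntimeWarning
        )
    return roi


def extract_voxel_table(
    suvr: Volume3D,
    burdens: dict[str, Volume3D | np.ndarray],
    roi_mask,
    label_map: PhantomLabelMap | None = None,
) -> pd.DataFrame:
    """One row per ROI voxel: SUVR, per-marker burden, region label.

    Markers absent for a case (e.g. p-tau in a non-tauopathy) are
    recorded as missing (NaN columns), never as zero burden.
    """
    s = _vol_data(suvr)
    roi = _vol_data(roi_mask).astype(bool)
    if roi.shape != s.shape:
        raise ValueError("ROI mask must share the SUVR geometry")
    for name, vol in burdens.items():
        if _vol_data(vol).shape != s.shape:
            raise ValueError(f"burden volume {name!r} does not share the SUVR geometry")
    if label_map is not None and label_map.grid.shape != s.shape:
        raise ValueError("label map must share the SUVR geometry")
    idx = np.argwhere(roi)
    table = {
        "voxel_i": idx[:, 0],
        "voxel_j": idx[:, 1],
        "voxel_k": idx[:, 2],
        "suvr": s[roi],
    }
    for marker in MARKER_COLUMNS:
        if marker in burdens:
            table[marker] = _vol_data(burdens[marker])[roi].astype(float)
        else:
            table[marker] = np.full(idx.shape[0], np.nan)
    if label_map is not None:
        labs = label_map.grid[roi]
        table["region"] = pd.Categorical(
            [label_map.labels[int(v)] for v in labs],
            categories=list(label_map.labels.values()),
        )
    else:
        table["region"] = pd.Categorical(["unknown"] * idx.shape[0])
    return pd.DataFrame(table)


def hexbin_counts(
    table: pd.DataFrame,
    marker: str,
    n_bins: int = 20,
    stratum: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel counts over a rectangular (burden, SUVR) binning.

    A fast-to-assert stand-in for the hexbin voxel-density figures:
    counts, not rendering, are the contract.  Returns
    (counts[n_bins, n_bins], burden_edges, suvr_edges); total count
    equals the number of rows in the stratum.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if marker not in table.columns:
        raise ValueError(f"unknown marker column: {marker!r}")
    rows = table
    if stratum is not None:
        rows = table[table["region"].isin(stratum)]
    rows = rows.dropna(subset=[marker, "suvr"])
    if rows.empty:
        raise ValueError("empty stratum: no voxels to bin")
    x = rows[marker].to_numpy(float)
    y = rows["suvr"].to_numpy(float)
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=n_bins)
    return counts.astype(int), x_edges, y_edges
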