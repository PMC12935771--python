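"""End-to-end orchestration: simulate -> segment -> quantify -> register
-> resolution-match -> ROI -> statistics.

A single :class:`RunConfig` drives the whole synthetic run.  The phantom
is a stack of coronal sections: ground-truth marker masks live in the
blockface (reference) frame; each section is distorted by a known smooth
warp into "section" space with jittered paired landmarks, mirroring the
distortion that immunohistochemistry processing inflicts on real
sections.  The generative PET is synthesized from the ground-truth
burden heatmaps after resolution matching, so in the noiseless limit
the analysis path recovers the generative coefficients exactly.

A master seed deterministically spawns per-stage sub-seeds; a fixed
config yields bit-identical reports (timestamps aside), and each stage
reads only the state its predecessors produced, so stages can be re-run
in isolation from a cached state bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pickle
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import io as hio
from .heatmap import BurdenHeatmap, blur_to_fwhm, estimate_fwhm, percent_positive_heatmap
from .models import SuvrModelSuite, wilcoxon_rank_sum
from .phantom import (
    DEFAULT_DENSITIES,
    MARKERS,
    PETGroundTruth,
    PhantomLabelMap,
    corrupt_to_probability,
    generate_label_map,
    generate_marker_truth,
    random_smooth_warp,
    synthesize_pet,
    upsample_labels,
    warp_with_landmarks,
)
from .registration import (
    Volume3D,
    apply_transform_2d,
    dice_coefficient,
    fit_tps,
    stack_sections,
)
from .segmentation import (
    BinaryMask,
    ProbabilityMap,
    binarize_probability,
    threshold_performance,
)
from .voxels import build_roi_mask, compute_suvr, extract_voxel_table

__all__ = [
    "RunConfig",
    "validate_config",
    "run_pipeline",
    "report_hash",
    "simulate_voxel_case",
    "parameter_recovery",
    "STAGE_ORDER",
]

# per-marker probability corruption emulating the operating
# characteristics of the trained segmenters at their published
# thresholds (the iron classifier is binarized at 0.93, so its synthetic
# stand-in concentrates positive-class probability near 1)
DEFAULT_CORRUPTION = {
    "ptau": {"pos": (12.0, 1.0), "neg": (1.0, 12.0)},
    "iron": {"pos": (60.0, 1.0), "neg": (1.0, 60.0)},
    "maob": {"pos": (12.0, 1.0), "neg": (1.0, 12.0)},
}

STAGE_ORDER = ("simulate", "segment", "quantify", "register",
               "resolution_match", "statistics")


@dataclass
class RunConfig:
    """All knobs of a synthetic run; fixed study settings as defaults."""

    seed: int = 0
    # phantom geometry
    n_sections: int = 6
    section_cells: int = 32          # in-plane cells (1 cell = tile_mm)
    slice_spacing_mm: float = 4.0
    pixel_size_um: float = 40.0
    densities: dict = field(default_factory=lambda: {
        m: dict(DEFAULT_DENSITIES[m]) for m in MARKERS})
    # segmentation
    prob_thresholds: dict = field(default_factory=lambda: {
        "ptau": 0.7, "iron": 0.93, "maob": 0.7})
    corruption: dict = field(default_factory=lambda: {
        m: {k: tuple(v) for k, v in DEFAULT_CORRUPTION[m].items()}
        for m in MARKERS})
    # quantification / resolution
    tile_mm: float = 1.0
    min_coverage: float = 0.5
    pet_fwhm_mm: float = 5.0
    fwhm_tolerance: float = 0.02
    # registration
    warp_max_disp_mm: float = 2.0
    n_landmarks: int = 12
    landmark_jitter_sd: float = 0.1
    tps_lambda: float = 0.0
    dice_bar: float = 0.8
    # PET generative model
    beta0: float = 1.1
    betas: dict = field(default_factory=lambda: {
        "ptau": 0.7, "iron": 0.4, "maob": 0.0})
    noise_sd: float = 0.1
    reference_activity: float = 2.0
    # statistics
    suvr_thresholds: tuple = (1.2, 1.3, 1.4)
    standardize: bool = False
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["suvr_thresholds"] = list(self.suvr_thresholds)
        return d

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "suvr_thresholds" in d:
            d["suvr_thresholds"] = tuple(d["suvr_thresholds"])
        if "corruption" in d:
            d["corruption"] = {
                m: {k: (tuple(v) if isinstance(v, (list, tuple)) else v)
                    for k, v in spec.items()}
                for m, spec in d["corruption"].items()}
        return cls(**d)

    @classmethod
    def from_json(cls, text_or_path) -> "RunConfig":
        p = Path(str(text_or_path))
        if p.exists():
            return cls.from_dict(json.loads(p.read_text()))
        return cls.from_dict(json.loads(text_or_path))

    @property
    def section_mm(self) -> float:
        return self.section_cells * self.tile_mm


def validate_config(config: RunConfig) -> list[str]:
    """Check every module precondition implied by the config.

    Returns a list of human-readable violations (empty when valid);
    violations are data, not exceptions.
    """
    v = []
    if config.n_sections < 1:
        v.append("n_sections: need at least 1 section")
    if config.section_cells < 32:
        v.append("section_cells: phantom needs >= 32 cells per in-plane axis")
    if config.slice_spacing_mm <= 0:
        v.append("slice_spacing_mm: must be positive")
    if config.pixel_size_um <= 0:
        v.append("pixel_size_um: must be positive")
    if config.tile_mm < config.pixel_size_um / 1000.0:
        v.append("tile_mm: tile must be at least one pixel")
    if not 0 < config.min_coverage <= 1:
        v.append("min_coverage: must lie in (0, 1]")
    for m, t in config.prob_thresholds.items():
        if not 0 <= t <= 1:
            v.append(f"prob_thresholds[{m}]: threshold {t} outside the [0, 1] bound")
    for m, dens in config.densities.items():
        for region, rho in dens.items():
            if not 0 <= rho <= 1:
                v.append(f"densities[{m}][{region}]: fraction {rho} outside [0, 1]")
    if config.pet_fwhm_mm <= 0:
        v.append("pet_fwhm_mm: must be positive")
    if not 0 < config.fwhm_tolerance < 1:
        v.append("fwhm_tolerance: must lie in (0, 1)")
    if config.warp_max_disp_mm < 0:
        v.append("warp_max_disp_mm: must be >= 0")
    if config.warp_max_disp_mm >= 0.10 * config.section_mm:
        v.append("warp_max_disp_mm: displacement must stay below 10% of the field of view")
    if config.n_landmarks < 3:
        v.append("n_landmarks: thin-plate spline needs >= 3 landmarks")
    if config.landmark_jitter_sd < 0:
        v.append("landmark_jitter_sd: must be >= 0")
    if config.tps_lambda < 0:
        v.append("tps_lambda: must be >= 0")
    if not 0 <= config.dice_bar <= 1:
        v.append("dice_bar: must lie in [0, 1]")
    if config.noise_sd < 0:
        v.append("noise_sd: must be >= 0")
    if config.reference_activity <= 0:
        v.append("reference_activity: must be positive")
    for t in config.suvr_thresholds:
        if t <= 0:
            v.append(f"suvr_thresholds: cutoff {t} must be positive")
    unknown = set(config.betas) - set(MARKERS)
    if unknown:
        v.append(f"betas: unknown markers {sorted(unknown)}")
    return v


def _stage_seeds(seed: int, n: int = 16) -> list[int]:
    """Spawn deterministic per-stage sub-seeds (kept below 2^31)."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


def _heatmap_stack(masks: list[BinaryMask], config: RunConfig) -> list[BurdenHeatmap]:
    return [percent_positive_heatmap(m, config.tile_mm, config.min_coverage)
            for m in masks]


def _match_and_stack(heatmaps: list[BurdenHeatmap], config: RunConfig):
    """In-plane FWHM matching per section, then stacking to a volume."""
    smoothed, flags, estimates = [], [], []
    for h in heatmaps:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                s, est, ok = blur_to_fwhm(
                    h.grid, h.spacing_mm, config.pet_fwhm_mm,
                    mask=h.valid_mask, tolerance=config.fwhm_tolerance,
                )
            flags.append("ok" if ok else "max_iter")
            estimates.append(est.fwhm_mm)
        except ValueError:
            # intrinsically smoother than the target: cannot sharpen;
            # proceed unsmoothed with a warning flag
            s = h.grid.copy()
            flags.append("cannot_sharpen")
            try:
                estimates.append(
                    estimate_fwhm(h.grid, h.spacing_mm, h.valid_mask).fwhm_mm)
            except ValueError:
                estimates.append((float("nan"), float("nan")))
        s = np.where(h.valid_mask, np.clip(s, 0.0, 1.0), 0.0)
        smoothed.append(s)
    vol = stack_sections(smoothed, config.slice_spacing_mm, config.tile_mm)
    return vol, flags, estimates


# ---------------------------------------------------------------------------
# pipeline stages (each reads/extends a shared state dict)
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig) -> dict:
    """Generate the synthetic case: phantom, sections, warps, PET."""
    seeds = _stage_seeds(config.seed)
    S = config.section_cells
    label3d = generate_label_map(
        (config.n_sections, S, S),
        (config.slice_spacing_mm, config.tile_mm, config.tile_mm),
        seed=seeds[0],
    )
    px_mm = config.pixel_size_um / 1000.0
    sections = []
    for k in range(config.n_sections):
        lab2d = label3d.slice2d(k)
        sec_seed = _stage_seeds(seeds[1] + k, 8)
        truths, probs = {}, {}
        for j, marker in enumerate(MARKERS):
            truths[marker] = generate_marker_truth(
                lab2d, marker, config.pixel_size_um,
                config.densities[marker], seed=sec_seed[j],
            )
            spec = config.corruption[marker]
            probs[marker] = corrupt_to_probability(
                truths[marker], spec["pos"], spec["neg"], seed=sec_seed[3 + j],
            )
        tissue_ref = upsample_labels(lab2d, config.pixel_size_um) > 0
        warp = random_smooth_warp(
            (config.section_mm, config.section_mm),
            max_disp_mm=config.warp_max_disp_mm,
            n_landmarks=config.n_landmarks,
            landmark_jitter_sd=config.landmark_jitter_sd,
            seed=sec_seed[6],
        )
        tissue_sec, landmarks = warp_with_landmarks(
            tissue_ref.astype(float), warp, seed=sec_seed[7],
            spacing_mm=px_mm, interpolation="nearest",
        )
        probs_sec, truth_sec = {}, {}
        for marker in MARKERS:
            # nearest: section pixels carry their stain probability intact;
            # linear blending would erase single-pixel puncta at this pitch
            img, _ = warp_with_landmarks(
                probs[marker].grid, warp, seed=sec_seed[7],
                spacing_mm=px_mm, interpolation="nearest",
            )
            probs_sec[marker] = ProbabilityMap(np.clip(img, 0, 1),
                                               config.pixel_size_um)
            tmask, _ = warp_with_landmarks(
                truths[marker].mask.astype(float), warp, seed=sec_seed[7],
                spacing_mm=px_mm, interpolation="nearest",
            )
            truth_sec[marker] = tmask.astype(np.uint8)
        sections.append({
            "lab2d": lab2d, "truths": truths,
            "tissue_ref": tissue_ref, "tissue_sec": tissue_sec.astype(bool),
            "probs_sec": probs_sec, "truth_sec": truth_sec,
            "landmarks": landmarks,
        })

    # generative path: truth masks -> heatmaps -> FWHM match -> PET
    gen_volumes = {}
    for marker in MARKERS:
        masks = [BinaryMask(sec["truths"][marker].mask, config.pixel_size_um)
                 for sec in sections]
        vol, _, _ = _match_and_stack(_heatmap_stack(masks, config), config)
        gen_volumes[marker] = vol
    gt = PETGroundTruth(beta0=config.beta0, betas=dict(config.betas),
                        noise_sd=config.noise_sd,
                        pet_fwhm_mm=config.pet_fwhm_mm, seed=seeds[2])
    suvr_model = synthesize_pet(gen_volumes, gt)
    tissue_vol = label3d.grid > 0
    activity = np.where(tissue_vol,
                        config.reference_activity * suvr_model.data,
                        config.reference_activity)
    state = {
        "label3d": label3d,
        "sections": sections,
        "gen_volumes": gen_volumes,
        "gt": gt,
        "activity": Volume3D(activity, suvr_model.spacing_mm),
        "tissue_vol": tissue_vol,
        "reference_mask": ~tissue_vol,
        "report_simulate": {
            "n_sections": config.n_sections,
            "label_counts": {name: int(label3d.region_mask(name).sum())
                             for name in label3d.labels.values()},
            "pet_ground_truth": gt.to_dict(),
        },
    }
    return state


def stage_segment(state: dict, config: RunConfig) -> None:
    """Binarize section probability maps at the per-marker thresholds."""
    sections = state["sections"]
    seg_masks = {m: [] for m in MARKERS}
    seg_qc = {}
    for marker in MARKERS:
        thr = config.prob_thresholds[marker]
        for sec in sections:
            seg_masks[marker].append(
                binarize_probability(sec["probs_sec"][marker], thr))
        curve = threshold_performance(
            sections[0]["probs_sec"][marker], sections[0]["truth_sec"][marker],
            thresholds=np.linspace(0, 1, 101),
        )
        row = curve.table.iloc[(curve.table["threshold"] - thr).abs().argmin()]
        seg_qc[marker] = {
            "threshold": thr,
            "auc_roc": curve.auc_roc,
            "precision_at_threshold": float(row["precision"]),
            "recall_at_threshold": float(row["recall"]),
            "f1_at_threshold": float(row["f1"]),
        }
    state["seg_masks"] = seg_masks
    state["report_segment"] = seg_qc


def stage_quantify(state: dict, config: RunConfig) -> None:
    """Percent-positive heatmaps of the segmented section masks."""
    heat_sec = {m: _heatmap_stack(state["seg_masks"][m], config)
                for m in MARKERS}
    state["heat_sec"] = heat_sec
    state["report_quantify"] = {
        "tile_mm": config.tile_mm,
        "mean_burden": {
            m: float(np.mean([h.grid[h.valid_mask].mean() for h in heat_sec[m]]))
            for m in MARKERS},
    }


def stage_register(state: dict, config: RunConfig) -> None:
    """TPS-register section heatmaps and tissue masks to the reference."""
    sections = state["sections"]
    S = config.section_cells
    px_mm = config.pixel_size_um / 1000.0
    n_px = sections[0]["tissue_ref"].shape[0]
    dice_values = []
    heat_reg = {m: [] for m in MARKERS}
    for k, sec in enumerate(sections):
        tps = fit_tps(sec["landmarks"], lam=config.tps_lambda)
        for marker in MARKERS:
            h = state["heat_sec"][marker][k]
            res = apply_transform_2d(
                h.grid, tps, (S, S), config.tile_mm,
                input_spacing_mm=h.spacing_mm, interpolation="linear")
            heat_reg[marker].append(BurdenHeatmap(
                np.clip(res.grid, 0, 1), config.tile_mm,
                res.valid_mask, provenance={"section": k, "marker": marker}))
        tissue_back = apply_transform_2d(
            sec["tissue_sec"].astype(float), tps, (n_px, n_px), px_mm,
            interpolation="nearest")
        d = dice_coefficient(tissue_back.grid > 0.5, sec["tissue_ref"],
                             qc_bar=config.dice_bar)
        dice_values.append(d.value)
    state["heat_reg"] = heat_reg
    state["dice_values"] = dice_values
    state["report_register"] = {
        "dice_per_section": dice_values,
        "dice_min": float(min(dice_values)),
        "dice_qc_pass": bool(min(dice_values) >= config.dice_bar),
    }


def stage_resolution_match(state: dict, config: RunConfig) -> None:
    """Blur registered heatmaps to the PET FWHM and stack into volumes."""
    ana_volumes, fwhm_flags, fwhm_est = {}, {}, {}
    for marker in MARKERS:
        vol, flags, estimates = _match_and_stack(state["heat_reg"][marker], config)
        ana_volumes[marker] = vol
        fwhm_flags[marker] = flags
        fwhm_est[marker] = [list(map(float, e)) for e in estimates]
    state["ana_volumes"] = ana_volumes
    state["report_resolution_match"] = {
        "target_fwhm_mm": config.pet_fwhm_mm,
        "flags": fwhm_flags,
        "in_plane_fwhm_mm": fwhm_est,
    }


def stage_statistics(state: dict, config: RunConfig) -> None:
    """SUVR, thresholded ROIs, voxel tables and the model suite."""
    suvr = compute_suvr(state["activity"], state["reference_mask"])
    label3d = state["label3d"]
    stats_out, roi_counts, tables = {}, {}, {}
    for thr in config.suvr_thresholds:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            roi = build_roi_mask(suvr, thr, state["tissue_vol"])
        roi_counts[str(thr)] = int(roi.sum())
        table = extract_voxel_table(suvr, state["ana_volumes"], roi, label3d)
        tables[thr] = table
        try:
            suite = SuvrModelSuite(table, standardize=config.standardize).fit()
            stats_out[str(thr)] = json.loads(suite.to_json())
        except ValueError as exc:
            stats_out[str(thr)] = {"skipped": str(exc)}
    main_thr = config.suvr_thresholds[0]
    main_table = tables[main_thr]
    wm = main_table["region"] == "white_matter"
    if wm.any() and (~wm).any():
        w = wilcoxon_rank_sum(main_table.loc[wm, "maob"],
                              main_table.loc[~wm, "maob"])
        wilcox = {"u_statistic": w.u_statistic, "rank_sum": w.rank_sum,
                  "p_value": w.p_value, "n_in_wm": w.n1, "n_out_wm": w.n2}
    else:
        wilcox = {"skipped": "no white-matter contrast in ROI"}
    state["suvr"] = suvr
    state["tables"] = tables
    state["report_statistics"] = {
        "roi_voxels_per_threshold": roi_counts,
        "model_suite_per_threshold": stats_out,
        "maob_wilcoxon_wm": wilcox,
    }


def _assemble_report(state: dict, config: RunConfig) -> dict:
    report: dict = {"config": config.to_dict(), "stages": {}, "qc": {},
                    "statistics": {}, "ground_truth_recovery": {}}
    for stage in STAGE_ORDER:
        key = f"report_{stage}"
        if key in state:
            report["stages"][stage] = state[key]
    if "report_register" in state:
        report["qc"]["dice"] = state["report_register"]
    if "report_resolution_match" in state:
        report["qc"]["fwhm"] = state["report_resolution_match"]
    if "report_statistics" in state:
        report["statistics"] = state["report_statistics"]
        main_thr = str(config.suvr_thresholds[0])
        main = state["report_statistics"]["model_suite_per_threshold"].get(
            main_thr, {})
        if "fits" in main:
            ref = main["reference"]
            fit0 = main["fits"][ref]
            beta_err = {
                m: {"true": config.betas.get(m, 0.0),
                    "estimate": fit0["params"].get(m),
                    "error": fit0["params"].get(m) - config.betas.get(m, 0.0)}
                for m in fit0["predictors"]
            }
            report["ground_truth_recovery"] = {
                "beta_recovery": beta_err,
                "intercept": {"true": config.beta0,
                              "estimate": fit0["params"].get("const")},
                "dice_min": state["report_register"]["dice_min"],
                "fwhm_flags": state["report_resolution_match"]["flags"],
            }
    return report


_STAGE_FUNCS = {
    "segment": stage_segment,
    "quantify": stage_quantify,
    "register": stage_register,
    "resolution_match": stage_resolution_match,
    "statistics": stage_statistics,
}


def run_pipeline(config: RunConfig, out_dir: str | None = None) -> dict:
    """Execute the full synthetic pipeline and return the run report.

    Stages run in order (simulate, segment, quantify, register,
    resolution-match, ROI/statistics); a stage failure raises with the
    stage name attached.  With ``out_dir`` set, artifacts (volumes,
    voxel table, landmark CSVs, report JSON) are written there.  The
    report is a plain dict, deterministic given the config (hash it with
    :func:`report_hash`).
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    t0 = time.time()
    stage = "simulate"
    try:
        state = stage_simulate(config)
        for stage in STAGE_ORDER[1:]:
            _STAGE_FUNCS[stage](state, config)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    report = _assemble_report(state, config)
    report["runtime_s"] = time.time() - t0
    report["created"] = time.strftime("%Y-%m-%dT%H:%M:%S")

    if out_dir is None:
        out_dir = config.out_dir
    if out_dir is not None:
        write_artifacts(state, config, report, out_dir)
    return report


def write_artifacts(state: dict, config: RunConfig, report: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    hio.save_json(report, out / "report.json")
    if "suvr" in state:
        hio.save_volume_nifti(state["suvr"], out / "suvr.nii.gz")
    label3d = state["label3d"]
    hio.save_volume_nifti(Volume3D(label3d.grid.astype(np.float32),
                                   label3d.spacing_mm), out / "labels.nii.gz")
    for marker in MARKERS:
        if "ana_volumes" in state:
            hio.save_volume_nifti(state["ana_volumes"][marker],
                                  out / f"burden_{marker}.nii.gz")
    for k, sec in enumerate(state["sections"]):
        sec["landmarks"].to_csv(out / f"landmarks_section{k:02d}.csv")
        for marker in MARKERS:
            hio.save_image_tiff(sec["probs_sec"][marker].grid,
                                out / f"prob_{marker}_section{k:02d}.tif")
    if "tables" in state:
        state["tables"][config.suvr_thresholds[0]].to_csv(
            out / "voxel_table.csv", index=False)


def save_state(state: dict, path) -> None:
    """Cache the pipeline state bundle (binary scratch artifact)."""
    with open(path, "wb") as fh:
        pickle.dump(state, fh)


def load_state(path) -> dict:
    with open(path, "rb") as fh:
        return pickle.load(fh)


_VOLATILE_KEYS = {"created", "runtime_s", "out_dir"}


def _strip_volatile(obj):
    if isinstance(obj, dict):
        return {k: _strip_volatile(v) for k, v in obj.items()
                if k not in _VOLATILE_KEYS}
    if isinstance(obj, list):
        return [_strip_volatile(v) for v in obj]
    return obj


def report_hash(report: dict) -> str:
    """SHA-256 of the canonicalized report, timestamps stripped."""
    clean = _strip_volatile(report)
    blob = json.dumps(clean, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# PET-grid synthetic case: the parameter-recovery experiment
# ---------------------------------------------------------------------------

def simulate_voxel_case(
    seed: int,
    beta0: float = 1.1,
    betas: dict | None = None,
    noise_sd: float = 0.1,
    shape: tuple[int, int, int] = (10, 36, 36),
    spacing_mm: tuple[float, float, float] = (4.0, 2.0, 2.0),
    densities: dict | None = None,
    suvr_threshold: float = 1.2,
    burden_noise_sd: float = 0.06,
    burden_smooth_cells: float = 1.5,
) -> tuple[pd.DataFrame, PETGroundTruth, PhantomLabelMap]:
    """Generate one synthetic voxel case directly at the PET grid.

    Burden volumes carry region-dependent means plus spatially smooth
    variation; the SUVR volume is their known linear combination plus
    Gaussian noise.  The ROI is thresholded on the *noiseless* SUVR so
    that voxel selection is independent of the outcome noise (selecting
    on the observed outcome would bias a recovery experiment), then the
    voxel table pairs the noisy SUVR with the burdens.
    """
    if betas is None:
        betas = {"ptau": 0.7, "iron": 0.4, "maob": 0.0}
    if densities is None:
        densities = {m: dict(DEFAULT_DENSITIES[m]) for m in MARKERS}
    seeds = _stage_seeds(seed, 8)
    label3d = generate_label_map(shape, spacing_mm, seed=seeds[0])
    rng = np.random.default_rng(seeds[1])
    tissue = label3d.grid > 0
    burdens = {}
    for marker in MARKERS:
        base = np.zeros(shape, dtype=float)
        for name, lab in label3d.name_to_label.items():
            base[label3d.grid == lab] = densities[marker].get(name, 0.0)
        noise = gaussian_filter(rng.standard_normal(shape),
                                sigma=burden_smooth_cells, mode="wrap")
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
        vol = np.clip(base + burden_noise_sd * noise, 0.0, 1.0)
        vol[~tissue] = 0.0
        burdens[marker] = Volume3D(vol, spacing_mm)
    gt_clean = PETGroundTruth(beta0=beta0, betas=dict(betas), noise_sd=0.0,
                              seed=seeds[2])
    clean = synthesize_pet(burdens, gt_clean)
    gt = PETGroundTruth(beta0=beta0, betas=dict(betas), noise_sd=noise_sd,
                        seed=seeds[2])
    noisy = synthesize_pet(burdens, gt)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        roi = build_roi_mask(clean, suvr_threshold, tissue)
    table = extract_voxel_table(noisy, burdens, roi, label3d)
    return table, gt, label3d


def parameter_recovery(
    n_replicates: int = 50,
    seed: int = 1,
    beta0: float = 1.1,
    betas: dict | None = None,
    noise_sd: float = 0.1,
    true_model: str = "m1",
    **case_kwargs,
) -> pd.DataFrame:
    """Repeat the synthetic voxel case and summarise coefficient recovery.

    One row per replicate: per-coefficient estimate, standard error,
    |error| <= 3 SE flag, 95% CI coverage flag, ROI size, and the AIC
    gap of the true generative model to the best model of the suite.
    """
    if betas is None:
        betas = {"ptau": 0.7, "iron": 0.4, "maob": 0.0}
    child = [int(s & 0x7FFFFFFF)
             for s in np.random.SeedSequence(seed).generate_state(n_replicates)]
    truth = {"const": beta0, **betas}
    rows = []
    for r, s in enumerate(child):
        table, gt, _ = simulate_voxel_case(
            s, beta0=beta0, betas=betas, noise_sd=noise_sd, **case_kwargs)
        res = SuvrModelSuite(table).fit()
        fit0 = res.fits[res.reference]
        row = {"replicate": r, "seed": s, "n_roi": fit0.n,
               "best_model": res.best_model,
               "true_model_delta_to_best": res.fits[true_model].aic
               - res.fits[res.best_model].aic}
        for name in fit0.params.index:
            est = fit0.params[name]
            se = fit0.bse[name]
            lo, hi = fit0.conf_int.loc[name]
            tr = truth.get(name, 0.0)
            row[f"beta_{name}"] = est
            row[f"se_{name}"] = se
            row[f"within3se_{name}"] = bool(abs(est - tr) <= 3 * se)
            row[f"cover_{name}"] = bool(lo <= tr <= hi)
        rows.append(row)
    return pd.DataFrame(rows)
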