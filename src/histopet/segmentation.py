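"""Pixel-level segmentation of stain images and its evaluation.

Stained sections (or their classifier probability maps) are reduced to
binary positive-pixel masks.  The operating threshold is chosen from the
precision--recall curve; receiver-operating-characteristic (ROC) area
summarises classifier quality.  A small regularized logistic pixel
classifier stands in for the heavyweight CNN / Weka segmenters used on
real slides: it operates on per-pixel intensity plus a multiscale
local-mean feature bank, which is the class of feature the interactive
tools use by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

__all__ = [
    "ProbabilityMap",
    "BinaryMask",
    "ThresholdCurve",
    "PixelClassifier",
    "fit_pixel_classifier",
    "predict_probability",
    "binarize_probability",
    "threshold_performance",
    "select_operating_threshold",
]

DEFAULT_THRESHOLD_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


@dataclass
class ProbabilityMap:
    """Per-pixel positive-class probability at micrometre pitch."""

    grid: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("probability grid must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        finite = self.grid[np.isfinite(self.grid)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass
class BinaryMask:
    """Binary positive-pixel mask with the threshold that produced it."""

    grid: np.ndarray
    pixel_size_um: float
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ValueError("mask grid must be 2D")
        if not np.isin(grid, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        self.grid = grid.astype(np.uint8)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.threshold_used is not None and not 0 <= self.threshold_used <= 1:
            raise ValueError("threshold_used must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def positive_count(self) -> int:
        return int(self.grid.sum())


@dataclass
class ThresholdCurve:
    """Confusion-matrix sweep over probability thresholds.

    ``table`` has one row per threshold with columns
    (threshold, tp, fp, fn, tn, precision, recall, f1, tpr, fpr);
    ``auc_roc`` is the exact ROC area over the full sweep of distinct
    probability values (equal to the rank statistic), independent of the
    threshold grid requested.
    """

    table: pd.DataFrame
    auc_roc: float

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["auc_roc"] = self.auc_roc
        out.to_csv(path, index=False)


@dataclass
class PixelClassifier:
    """Serializable state of the logistic stand-in pixel classifier."""

    coef: np.ndarray          # weights over the feature bank
    intercept: float
    smooth_sigmas: tuple[float, ...]
    feature_mean: np.ndarray
    feature_std: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {
            "coef": self.coef.tolist(),
            "intercept": float(self.intercept),
            "smooth_sigmas": list(self.smooth_sigmas),
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PixelClassifier":
        return cls(
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            smooth_sigmas=tuple(d["smooth_sigmas"]),
            feature_mean=np.asarray(d["feature_mean"], dtype=float),
            feature_std=np.asarray(d["feature_std"], dtype=float),
            seed=int(d["seed"]),
        )


def _feature_stack(image: np.ndarray, sigmas: Sequence[float]) -> np.ndarray:
    """Per-pixel feature bank: raw intensity + Gaussian local means."""
    image = np.asarray(image, dtype=float)
    feats = [image]
    for s in sigmas:
        feats.append(gaussian_filter(image, sigma=s, mode="nearest"))
    return np.stack([f.ravel() for f in feats], axis=1)


def fit_pixel_classifier(
    training_images: Sequence[np.ndarray],
    training_labels: Sequence[BinaryMask | np.ndarray],
    *,
    C: float = 1.0,
    smooth_sigmas: tuple[float, ...] = (1.0, 4.0),
    max_pixels: int = 50_000,
    seed: int = 0,
) -> PixelClassifier:
    """Fit the logistic pixel classifier on labelled image/mask pairs.

    Pixels are pooled over all training images and subsampled
    deterministically (at most ``max_pixels``) before the fit.  Raises if
    the training labels contain a single class, since the probability
    output could not be calibrated.
    """
    if len(training_images) < 1:
        raise ValueError("need at least one labeled training image")
    if len(training_images) != len(training_labels):
        raise ValueError("training images and labels must pair up")
    X_parts, y_parts = [], []
    for img, lab in zip(training_images, training_labels):
        lab_grid = lab.grid if isinstance(lab, BinaryMask) else np.asarray(lab)
        img = np.asarray(img, dtype=float)
        if img.shape != lab_grid.shape:
            raise ValueError("labels must align pixelwise with features")
        X_parts.append(_feature_stack(img, smooth_sigmas))
        y_parts.append(lab_grid.ravel().astype(int))
    X = np.concatenate(X_parts, axis=0)
    y = np.concatenate(y_parts, axis=0)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class; cannot calibrate")
    rng = np.random.default_rng(seed)
    if X.shape[0] > max_pixels:
        idx = rng.choice(X.shape[0], size=max_pixels, replace=False)
        idx.sort()
        X, y = X[idx], y[idx]
        if np.unique(y).size < 2:
            raise ValueError("subsampled training labels contain a single class")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xs = (X - mean) / std
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=1000)
    clf.fit(Xs, y)
    return PixelClassifier(
        coef=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        smooth_sigmas=tuple(smooth_sigmas),
        feature_mean=mean,
        feature_std=std,
        seed=seed,
    )


def predict_probability(
    state: PixelClassifier, image: np.ndarray, pixel_size_um: float = 1.0
) -> ProbabilityMap:
    """Apply a fitted pixel classifier to a new image."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    X = _feature_stack(image, state.smooth_sigmas)
    if X.shape[1] != state.coef.shape[0]:
        raise ValueError("feature dimension mismatch with classifier state")
    Xs = (X - state.feature_mean) / state.feature_std
    z = Xs @ state.coef + state.intercept
    p = 1.0 / (1.0 + np.exp(-z))
    return ProbabilityMap(p.reshape(image.shape), pixel_size_um)


def binarize_probability(p: ProbabilityMap, threshold: float) -> BinaryMask:
    """Threshold a probability map; probability >= threshold is positive."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    grid = (p.grid >= threshold).astype(np.uint8)
    return BinaryMask(grid, p.pixel_size_um, threshold_used=threshold)


def threshold_performance(
    p: ProbabilityMap,
    truth: BinaryMask | np.ndarray,
    thresholds: Sequence[float] | None = None,
) -> ThresholdCurve:
    """Sweep confusion counts, precision/recall/F1 and TPR/FPR over thresholds.

    Counts are exhaustive over pixels.  precision = TP/(TP+FP) is marked
    missing (NaN) when no pixel is called positive; recall = TP/(TP+FN) =
    TPR.  ``auc_roc`` is the exact trapezoidal ROC area over the full
    sweep of distinct probability values regardless of the requested
    threshold grid.
    """
    truth_grid = truth.grid if isinstance(truth, BinaryMask) else np.asarray(truth)
    if not np.isin(truth_grid, (0, 1)).all():
        raise ValueError("truth mask must be binary")
    if truth_grid.shape != p.grid.shape:
        raise ValueError("probability map and truth must align pixelwise")
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLD_GRID
    thr = np.asarray(thresholds, dtype=float)
    if thr.ndim != 1 or thr.size == 0:
        raise ValueError("thresholds must be a non-empty 1D sequence")
    if np.any(np.diff(thr) <= 0):
        thr = np.unique(thr)
    if thr.min() < 0 or thr.max() > 1:
        raise ValueError("thresholds must lie in [0, 1]")

    pv = p.grid.ravel()
    tv = truth_grid.ravel().astype(bool)
    pos = np.sort(pv[tv])
    neg = np.sort(pv[~tv])
    n_pos, n_neg = pos.size, neg.size
    # pixels >= t among each class, vectorized over the grid
    tp = n_pos - np.searchsorted(pos, thr, side="left")
    fp = n_neg - np.searchsorted(neg, thr, side="left")
    fn = n_pos - tp
    tn = n_neg - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
        recall = tp / n_pos if n_pos else np.full_like(thr, np.nan)
        f1 = np.where(
            np.isnan(precision) | ((precision + recall) == 0),
            np.nan,
            2 * precision * recall / np.where(precision + recall == 0, 1, precision + recall),
        )
        fpr = fp / n_neg if n_neg else np.full_like(thr, np.nan)
    table = pd.DataFrame(
        {
            "threshold": thr,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "tpr": recall,
            "fpr": fpr,
        }
    )
    if n_pos and n_neg:
        auc = float(roc_auc_score(tv.astype(int), pv))
    else:
        auc = float("nan")
    return ThresholdCurve(table=table, auc_roc=auc)


def select_operating_threshold(curve: ThresholdCurve, criterion: str = "max_f1") -> float:
    """Pick the operating threshold maximizing the criterion (ties -> larger).

    Rows with undefined F1 (no positive calls) are excluded.  Ties are
    broken toward the larger threshold because over-calling background is
    the costlier error for burden quantification.
    """
    if criterion != "max_f1":
        raise ValueError(f"unknown criterion: {criterion!r}")
    tab = curve.table
    defined = tab[np.isfinite(tab["f1"])]
    if defined.empty:
        raise ValueError("no threshold has a defined F1 score")
    best = defined["f1"].max()
    winners = defined[defined["f1"] == best]
    return float(winners["threshold"].max())
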