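"""Voxel-wise statistics: correlations, rank tests and the model suite.

The central question — how much of the flortaucipir PET signal is
explained by each histological substrate — is answered with a fixed
suite of nested ordinary-least-squares models of voxel SUVR on the
co-registered burdens:

    m0: suvr ~ ptau + iron + maob        (full model, the reference)
    m1: suvr ~ ptau + iron
    m2: suvr ~ ptau + maob
    m3: suvr ~ iron + maob
    m4: suvr ~ ptau
    m5: suvr ~ iron
    m6: suvr ~ maob

Models are compared by AIC relative to the full model (ΔAIC = AIC(m) −
AIC(m0)); collinearity of the full model's predictors is screened with
variance inflation factors (VIF = 1/(1−R²_j)).  When a marker is absent
for a case (no detectable p-tau in a non-tauopathy), the suite shrinks
to the models whose predictors are available (m3/m5/m6) and ΔAIC is
taken against the fullest available model.  Monotonic association per
marker is summarised by Spearman's ρ, and distributional contrasts
(e.g. MAO-B inside versus outside white matter) by the Wilcoxon
rank-sum test.

``SuvrModelSuite`` is the model object; its :meth:`SuvrModelSuite.fit`
returns a :class:`SuvrSuiteResults` carrying per-model estimates,
standard errors, AIC/AICc, ΔAIC, VIF and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "MODEL_FORMULAS",
    "CorrelationResult",
    "RankSumResult",
    "ModelFit",
    "SuvrModelSuite",
    "SuvrSuiteResults",
    "spearman_corr",
    "wilcoxon_rank_sum",
]

MODEL_FORMULAS: dict[str, tuple[str, ...]] = {
    "m0": ("ptau", "iron", "maob"),
    "m1": ("ptau", "iron"),
    "m2": ("ptau", "maob"),
    "m3": ("iron", "maob"),
    "m4": ("ptau",),
    "m5": ("iron",),
    "m6": ("maob",),
}


class CorrelationResult(NamedTuple):
    rho: float
    p_value: float
    n: int


class RankSumResult(NamedTuple):
    u_statistic: float
    rank_sum: float
    p_value: float
    n1: int
    n2: int


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman's ρ with average ranks for ties; p from the t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must pair up")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero variance in ranks; correlation undefined")
    res = stats.spearmanr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), n)


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum with tie-corrected normal approximation.

    Returns the Mann–Whitney U of the first group, the equivalent
    rank-sum W = U + n1(n1+1)/2, and the two-sided p value (continuity
    corrected, as in R's wilcox.test).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    u1 = float(res.statistic)
    w = u1 + a.size * (a.size + 1) / 2.0
    return RankSumResult(u1, w, float(res.pvalue), a.size, b.size)


@dataclass
class ModelFit:
    """Estimates and fit indices for one model of the suite.

    AIC uses the least-squares form n·ln(RSS/n) + 2k with k = p + 2
    (intercept and error variance both count as parameters); AICc adds
    the small-sample correction 2k(k+1)/(n−k−1).  Constant terms of the
    Gaussian log-likelihood are omitted — they cancel in every ΔAIC.
    """

    model_id: str
    predictors: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    r_squared: float
    rss: float
    aic: float
    aicc: float
    n: int
    k: int

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "predictors": list(self.predictors),
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "r_squared": self.r_squared,
            "rss": self.rss,
            "aic": self.aic,
            "aicc": self.aicc,
            "n": self.n,
            "k": self.k,
        }


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


class SuvrModelSuite:
    """Nested OLS suite of voxel SUVR on histological burdens.

    Parameters
    ----------
    data:
        Voxel table with a ``suvr`` column and burden columns among
        ``ptau``, ``iron``, ``maob``.  Markers that are entirely missing
        shrink the suite to the applicable models.
    markers:
        Restrict the available markers explicitly (default: every burden
        column with at least one finite value).
    standardize:
        If True, z-score outcome and predictors so betas are reported in
        standard-deviation units for cross-case comparison.  Off by
        default: burdens already share the 0–1 fraction scale.

    All models are fitted on the identical pairwise-complete row set so
    their AIC values are comparable.
    """

    def __init__(self, data: pd.DataFrame, markers: Sequence[str] | None = None,
                 standardize: bool = False):
        if "suvr" not in data.columns:
            raise ValueError("data must contain a 'suvr' column")
        if markers is None:
            markers = [m for m in ("ptau", "iron", "maob")
                       if m in data.columns and np.isfinite(
                           data[m].to_numpy(float)).any()]
        else:
            markers = [m for m in ("ptau", "iron", "maob") if m in markers]
        if not markers:
            raise ValueError("no available markers to model")
        self.markers = tuple(markers)
        cols = ["suvr", *self.markers]
        rows = data[cols].dropna()
        self.data = rows.reset_index(drop=True)
        self.standardize = bool(standardize)
        self.model_ids = tuple(
            mid for mid, preds in MODEL_FORMULAS.items()
            if set(preds) <= set(self.markers)
        )
        # reference = fullest available model: m0 with all three markers,
        # m3 when ptau is missing, and in general the model whose
        # predictor set equals the available markers
        ref = [mid for mid in self.model_ids
               if set(MODEL_FORMULAS[mid]) == set(self.markers)]
        if not ref:
            raise ValueError("available markers support no reference model")
        self.reference = ref[0]
        max_k = max(len(MODEL_FORMULAS[m]) for m in self.model_ids) + 2
        if len(self.data) <= max_k + 2:
            raise ValueError(
                f"too few complete voxels (n={len(self.data)}) for the suite"
            )

    @classmethod
    def from_voxel_table(cls, table: pd.DataFrame, **kwargs) -> "SuvrModelSuite":
        return cls(table, **kwargs)

    def _design(self) -> pd.DataFrame:
        df = self.data.copy()
        if self.standardize:
            for c in ("suvr", *self.markers):
                sd = df[c].std(ddof=1)
                if sd == 0:
                    raise ValueError(f"column {c!r} is constant; cannot standardize")
                df[c] = (df[c] - df[c].mean()) / sd
        return df

    def _fit_one(self, model_id: str, df: pd.DataFrame) -> ModelFit:
        preds = MODEL_FORMULAS[model_id]
        X = sm.add_constant(df[list(preds)], has_constant="add")
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError(
                f"rank-deficient design in {model_id}: collinear predictors {preds}"
            )
        res = sm.OLS(df["suvr"], X).fit()
        n = int(res.nobs)
        rss = float(res.ssr)
        k = len(preds) + 2
        aic = n * np.log(rss / n) + 2 * k if rss > 0 else -np.inf
        aicc = aic + 2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.inf
        ci = res.conf_int(alpha=0.05)
        ci.columns = ["low", "high"]
        return ModelFit(
            model_id=model_id,
            predictors=preds,
            params=res.params,
            bse=res.bse,
            pvalues=res.pvalues,
            conf_int=ci,
            r_squared=float(res.rsquared),
            rss=rss,
            aic=float(aic),
            aicc=float(aicc),
            n=n,
            k=k,
        )

    def fit(self) -> "SuvrSuiteResults":
        df = self._design()
        fits = {mid: self._fit_one(mid, df) for mid in self.model_ids}
        ref_aic = fits[self.reference].aic
        delta_aic = {mid: f.aic - ref_aic for mid, f in fits.items()}
        ref_preds = MODEL_FORMULAS[self.reference]
        vif = {}
        for pred in ref_preds:
            others = [p for p in ref_preds if p != pred]
            if not others:
                vif[pred] = 1.0
                continue
            Xo = sm.add_constant(df[others], has_constant="add")
            r2 = sm.OLS(df[pred], Xo).fit().rsquared
            vif[pred] = float(1.0 / (1.0 - r2)) if r2 < 1 else float("inf")
        spearman = {}
        for m in self.markers:
            try:
                spearman[m] = spearman_corr(df[m], df["suvr"])
            except ValueError:
                spearman[m] = None
        best = min(fits, key=lambda mid: fits[mid].aic)
        return SuvrSuiteResults(
            fits=fits, delta_aic=delta_aic, vif=vif, spearman=spearman,
            reference=self.reference, best_model=best, n=len(df),
            markers=self.markers, standardize=self.standardize,
        )


@dataclass
class SuvrSuiteResults:
    """Fitted model suite: estimates, ΔAIC against the reference, VIF."""

    fits: dict[str, ModelFit]
    delta_aic: dict[str, float]
    vif: dict[str, float]
    spearman: dict[str, CorrelationResult | None]
    reference: str
    best_model: str
    n: int
    markers: tuple[str, ...]
    standardize: bool

    def summary(self) -> str:
        """Text table in the shape of the study's headline results table."""
        ref = self.fits[self.reference]
        lines = []
        lines.append(f"SUVR ~ burden model suite  (n = {self.n} voxels, "
                     f"reference {self.reference}"
                     f"{', standardized' if self.standardize else ''})")
        lines.append("-" * 64)
        lines.append("Spearman correlation (rho) with SUVR")
        for m in self.markers:
            c = self.spearman.get(m)
            if c is None:
                lines.append(f"  {m:<12} undefined")
            else:
                lines.append(f"  {m:<12} {c.rho:7.3f} {_stars(c.p_value):>4}")
        lines.append(f"Applied multilinear model: {self.reference}   "
                     f"R-squared {ref.r_squared:.3f}")
        lines.append("Beta coefficients")
        for m in ref.predictors:
            lines.append(
                f"  {m:<12} {ref.params[m]:7.3f} (SE {ref.bse[m]:.3f}) "
                f"{_stars(ref.pvalues[m]):>4}"
            )
        lines.append("VIF (reference-model predictors)")
        for m, v in self.vif.items():
            lines.append(f"  {m:<12} {v:7.3f}")
        lines.append("Delta AIC vs " + self.reference)
        for mid in sorted(self.fits):
            tag = " <- best" if mid == self.best_model else ""
            lines.append(f"  {mid:<4} {self.delta_aic[mid]:10.2f}{tag}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mid, f in sorted(self.fits.items()):
            row = {"model": mid, "n": f.n, "k": f.k, "r_squared": f.r_squared,
                   "aic": f.aic, "aicc": f.aicc,
                   "delta_aic": self.delta_aic[mid]}
            for m in ("ptau", "iron", "maob"):
                if m in f.params.index:
                    row[f"beta_{m}"] = f.params[m]
                    row[f"se_{m}"] = f.bse[m]
                    row[f"p_{m}"] = f.pvalues[m]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        d = {
            "reference": self.reference,
            "best_model": self.best_model,
            "n": self.n,
            "markers": list(self.markers),
            "standardize": self.standardize,
            "delta_aic": self.delta_aic,
            "vif": self.vif,
            "spearman": {
                m: (None if c is None else
                    {"rho": c.rho, "p_value": c.p_value, "n": c.n})
                for m, c in self.spearman.items()
            },
            "fits": {mid: f.to_dict() for mid, f in self.fits.items()},
        }
        s = json.dumps(d, indent=1, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s
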