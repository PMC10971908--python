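"""Causal estimators for two-sample MR summary data.

Implements the Wald ratio, inverse-variance-weighted (IVW) meta-analysis of
Wald ratios (the main estimator, multiplicative random-effects by default),
MR-Egger regression, the weighted median, and Cochran's Q heterogeneity.

All estimators consume an :class:`~mrmediation.instruments.InstrumentSet`
(or its table): per-variant harmonized effects beta_exposure (se_exposure)
and beta_outcome (se_outcome).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MREstimate",
    "EstimationError",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "cochran_q",
    "all_methods",
]

Z95 = stats.norm.ppf(0.975)


class EstimationError(ValueError):
    """The instrument set cannot support the requested estimator."""


@dataclass
class MREstimate:
    """One method's causal estimate with uncertainty and heterogeneity."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    q_statistic: float | None = None
    q_pval: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _table(iv) -> pd.DataFrame:
    return iv.table if hasattr(iv, "table") else iv


def _ratios(t: pd.DataFrame, second_order: bool = False):
    bx = t["beta_exposure"].to_numpy(float)
    by = t["beta_outcome"].to_numpy(float)
    sy = t["se_outcome"].to_numpy(float)
    if np.any(bx == 0):
        raise EstimationError("degenerate instrument: beta_exposure = 0")
    ratio = by / bx
    se = sy / np.abs(bx)
    if second_order:
        sx = t["se_exposure"].to_numpy(float)
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    return ratio, se


def wald_ratio(iv_record, second_order: bool = False) -> MREstimate:
    """Per-variant causal estimate: outcome effect over exposure effect.

    The default standard error is the first-order delta approximation
    se_outcome / |beta_exposure|; ``second_order=True`` adds the
    exposure-uncertainty term.
    """
    t = iv_record if isinstance(iv_record, pd.DataFrame) else pd.DataFrame([dict(iv_record)])
    t = _table(t)
    if len(t) != 1:
        raise EstimationError("wald_ratio expects a single instrument")
    ratio, se = _ratios(t, second_order)
    beta, se = float(ratio[0]), float(se[0])
    z = beta / se
    return MREstimate(
        method="Wald ratio", beta=beta, se=se,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        pval=float(2 * stats.norm.sf(abs(z))), n_snps=1,
    )


def cochran_q(iv_set, pooled_beta: float, second_order: bool = False):
    """Heterogeneity of per-variant ratios about a pooled estimate.

    Q = sum_j w_j (ratio_j - pooled)^2 with inverse-variance weights;
    p from chi-square with k-1 degrees of freedom.
    """
    t = _table(iv_set)
    if len(t) < 2:
        raise EstimationError("Cochran's Q requires at least 2 instruments")
    ratio, se = _ratios(t, second_order)
    w = 1.0 / se**2
    q = float(np.sum(w * (ratio - pooled_beta) ** 2))
    return q, float(stats.chi2.sf(q, len(t) - 1))


def ivw(iv_set, model: str = "random", second_order: bool = False) -> MREstimate:
    """Inverse-variance-weighted meta-analysis of Wald ratios.

    Weights are 1/se_ratio^2; with first-order ratio SEs this is
    algebraically a weighted least-squares fit of beta_outcome on
    beta_exposure through the origin with weights 1/se_outcome^2. Under the
    default multiplicative random-effects model the SE is inflated by
    sqrt(Q/(k-1)) whenever that factor exceeds 1 (never deflated). A single
    instrument falls back to its Wald ratio.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    t = _table(iv_set)
    k = len(t)
    if k == 0:
        raise EstimationError("empty instrument set")
    if k == 1:
        est = wald_ratio(t, second_order)
        est.method = "IVW (single-SNP Wald ratio)"
        return est
    ratio, se_r = _ratios(t, second_order)
    w = 1.0 / se_r**2
    beta = float(np.sum(w * ratio) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (ratio - beta) ** 2))
    q_pval = float(stats.chi2.sf(q, k - 1))
    se = se_fixed
    if model == "random":
        se = se_fixed * max(1.0, np.sqrt(q / (k - 1)))
    z = beta / se
    return MREstimate(
        method=f"IVW ({model} effects)", beta=beta, se=se,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        pval=float(2 * stats.norm.sf(abs(z))), n_snps=k,
        q_statistic=q, q_pval=q_pval,
    )


def mr_egger(iv_set) -> MREstimate:
    """MR-Egger: weighted regression of outcome on exposure effects with intercept.

    The intercept estimates the average directional pleiotropic effect; the
    slope is the causal estimate adjusted for it. Instruments are oriented
    so beta_exposure >= 0 (required for the intercept to be interpretable),
    weights are 1/se_outcome^2, and both coefficient SEs carry the
    multiplicative overdispersion factor max(1, sqrt(Q/(k-2))). P-values use
    the t distribution with k-2 degrees of freedom.
    """
    t = _table(iv_set)
    k = len(t)
    if k < 3:
        raise EstimationError(f"MR-Egger requires >= 3 instruments, got {k}")
    flip = np.sign(t["beta_exposure"].to_numpy(float))
    flip[flip == 0] = 1.0
    x = t["beta_exposure"].to_numpy(float) * flip
    y = t["beta_outcome"].to_numpy(float) * flip
    w = 1.0 / t["se_outcome"].to_numpy(float) ** 2

    sw = np.sum(w)
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - intercept - slope * x
    q = float(np.sum(w * resid**2))
    phi = max(1.0, q / (k - 2))
    slope_se = float(np.sqrt(phi / sxx))
    intercept_se = float(np.sqrt(phi * (1.0 / sw + xbar**2 / sxx)))

    df = k - 2
    slope_p = float(2 * stats.t.sf(abs(slope / slope_se), df))
    intercept_p = float(2 * stats.t.sf(abs(intercept / intercept_se), df))
    tcrit = stats.t.ppf(0.975, df)
    return MREstimate(
        method="MR-Egger", beta=slope, se=slope_se,
        ci_low=slope - tcrit * slope_se, ci_high=slope + tcrit * slope_se,
        pval=slope_p, n_snps=k,
        q_statistic=q, q_pval=float(stats.chi2.sf(q, df)),
        intercept=intercept, intercept_se=intercept_se, intercept_pval=intercept_p,
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    # linear interpolation at cumulative standardized weight 0.5
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    return float(np.interp(0.5, cum, v))


def weighted_median(iv_set, n_boot: int = 1000, seed: int = 0,
                    second_order: bool = False) -> MREstimate:
    """Weighted median of Wald ratios; consistent when valid instruments
    carry a majority of the weight.

    The SE comes from a parametric bootstrap: per-variant exposure and
    outcome effects are redrawn from normal distributions at their reported
    SEs and the weighted median recomputed (default 1,000 draws, seeded).
    """
    t = _table(iv_set)
    k = len(t)
    if k < 3:
        raise EstimationError(f"weighted median requires >= 3 instruments, got {k}")
    ratio, se_r = _ratios(t, second_order)
    w = 1.0 / se_r**2
    beta = _weighted_median(ratio, w)

    rng = np.random.default_rng(seed)
    bx = t["beta_exposure"].to_numpy(float)
    by = t["beta_outcome"].to_numpy(float)
    sx = t["se_exposure"].to_numpy(float)
    sy = t["se_outcome"].to_numpy(float)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs[bxs == 0] = np.finfo(float).tiny
        r = bys / bxs
        sr = sy / np.abs(bxs)
        if second_order:
            sr = np.sqrt(sy**2 / bxs**2 + bys**2 * sx**2 / bxs**4)
        boots[b] = _weighted_median(r, 1.0 / sr**2)
    se = float(np.std(boots, ddof=1))
    z = beta / se
    return MREstimate(
        method="Weighted median", beta=beta, se=se,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        pval=float(2 * stats.norm.sf(abs(z))), n_snps=k,
    )


def all_methods(iv_set, model: str = "random", n_boot: int = 1000,
                seed: int = 0) -> list[MREstimate]:
    """Run every applicable estimator on one instrument set."""
    t = _table(iv_set)
    k = len(t)
    if k == 0:
        raise EstimationError("empty instrument set")
    results = [ivw(iv_set, model=model)]
    if k >= 3:
        results.append(mr_egger(iv_set))
        results.append(weighted_median(iv_set, n_boot=n_boot, seed=seed))
    return results
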