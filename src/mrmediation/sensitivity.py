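"""Sensitivity diagnostics: MR-PRESSO, Steiger directionality, leave-one-out.

MR-PRESSO detects horizontally pleiotropic outlier instruments via a
simulation-based residual test; the Steiger test checks that the instrument
set explains more variance in the exposure than in the outcome; leave-one-out
re-estimates the IVW effect with each instrument excluded in turn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import EstimationError, MREstimate, ivw
from .instruments import InstrumentSet, r2_from_pval_n

__all__ = ["PressoResult", "SteigerResult", "mr_presso", "steiger_test", "leave_one_out"]


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss: float
    global_pval: float
    outlier_variants: list = field(default_factory=list)
    outlier_pvals: dict = field(default_factory=dict)
    distortion_pval: float | None = None
    distortion_pct: float | None = None
    corrected_estimate: MREstimate | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.corrected_estimate is not None:
            d["corrected_estimate"] = self.corrected_estimate.to_dict()
        return d


@dataclass
class SteigerResult:
    """Directionality check: variance explained in exposure vs outcome."""

    r2_exposure: float
    r2_outcome: float
    direction_true: bool
    pval: float

    def to_dict(self) -> dict:
        return asdict(self)


def _loo_slopes(x, y, w):
    """Leave-one-out IVW slopes (weighted regression through the origin)."""
    sxy = np.sum(w * x * y, axis=-1, keepdims=True)
    sxx = np.sum(w * x * x, axis=-1, keepdims=True)
    return (sxy - w * x * y) / (sxx - w * x * x)


def mr_presso(
    iv_set,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """Pleiotropy residual sum and outlier test.

    Global test: the observed weighted residual sum of squares about
    leave-one-out fitted values is ranked against ``n_sim`` parametric
    simulations in which each instrument's effects are redrawn from normal
    distributions centred on its leave-one-out expectation (add-one rule
    for the p-value). Outlier test: each variant's weighted squared
    residual is ranked against its own simulated distribution; variants
    significant after Bonferroni correction over k are flagged. Distortion
    test: the percent change between the all-instrument and outlier-free
    IVW estimates is compared with a null distribution built by removing
    equally many randomly chosen non-outlying instruments.
    """
    t = iv_set.table if hasattr(iv_set, "table") else iv_set
    k = len(t)
    if k < 4:
        raise EstimationError(f"MR-PRESSO requires >= 4 instruments, got {k}")
    rng = np.random.default_rng(seed)
    x = t["beta_exposure"].to_numpy(float)
    y = t["beta_outcome"].to_numpy(float)
    sx = t["se_exposure"].to_numpy(float)
    sy = t["se_outcome"].to_numpy(float)
    w = 1.0 / sy**2

    b_loo = _loo_slopes(x[None, :], y[None, :], w[None, :])[0]
    resid2_obs = w * (y - b_loo * x) ** 2
    rss_obs = float(np.sum(resid2_obs))

    # parametric null: redraw effects around leave-one-out expectations
    xs = rng.normal(x, sx, size=(n_sim, k))
    ys = rng.normal(b_loo * x, sy, size=(n_sim, k))
    b_loo_sim = _loo_slopes(xs, ys, np.broadcast_to(w, (n_sim, k)))
    resid2_sim = w * (ys - b_loo_sim * xs) ** 2
    rss_sim = np.sum(resid2_sim, axis=1)
    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    outlier_p = (1 + np.sum(resid2_sim >= resid2_obs, axis=0)) / (n_sim + 1)
    ids = t["variant_id"].to_numpy()
    is_outlier = outlier_p < outlier_alpha / k
    outliers = list(ids[is_outlier])
    result = PressoResult(
        global_rss=rss_obs,
        global_pval=global_pval,
        outlier_variants=outliers,
        outlier_pvals={v: float(p) for v, p in zip(ids, outlier_p)},
    )
    if not outliers or k - len(outliers) < 1:
        return result

    keep = ~is_outlier
    clean = t.loc[keep].reset_index(drop=True)
    corrected = ivw(clean)
    result.corrected_estimate = corrected
    full = ivw(t)
    if corrected.beta != 0:
        d_obs = 100.0 * (full.beta - corrected.beta) / abs(corrected.beta)
        result.distortion_pct = float(d_obs)
        # null: remove as many randomly chosen non-outliers instead
        n_out = len(outliers)
        idx_clean = np.flatnonzero(keep)
        if len(idx_clean) > n_out:
            d_null = np.empty(n_sim)
            wc = w[idx_clean]
            xc = x[idx_clean]
            yc = y[idx_clean]
            for s in range(n_sim):
                drop = rng.choice(len(idx_clean), size=n_out, replace=False)
                m = np.ones(len(idx_clean), dtype=bool)
                m[drop] = False
                b_sub = np.sum(wc[m] * xc[m] * yc[m]) / np.sum(wc[m] * xc[m] ** 2)
                d_null[s] = 100.0 * (full.beta - b_sub) / abs(b_sub) if b_sub != 0 else np.inf
            result.distortion_pval = float(
                (1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1)
            )
    return result


def steiger_test(iv_set) -> SteigerResult:
    """Directionality test over the whole instrument set.

    Per-variant variance explained is recovered from each association's
    p-value and sample size, summed over instruments separately for the
    exposure and the outcome. The direction is 'true' (exposure->outcome)
    when the instruments explain more variance in the exposure. The p-value
    compares the two correlations with a two-independent-sample Fisher-z
    test at the mean per-study sample sizes.
    """
    t = iv_set.table if hasattr(iv_set, "table") else iv_set
    if len(t) == 0:
        raise EstimationError("empty instrument set")
    r2_exp = float(np.minimum(np.sum(r2_from_pval_n(t["pval_exposure"], t["n_exposure"])), 1.0))
    r2_out = float(np.minimum(np.sum(r2_from_pval_n(t["pval_outcome"], t["n_outcome"])), 1.0))
    n_exp = float(np.mean(t["n_exposure"]))
    n_out = float(np.mean(t["n_outcome"]))
    r_exp = np.sqrt(min(r2_exp, 1.0 - 1e-12))
    r_out = np.sqrt(min(r2_out, 1.0 - 1e-12))
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / np.sqrt(
        1.0 / (n_exp - 3) + 1.0 / (n_out - 3)
    )
    return SteigerResult(
        r2_exposure=r2_exp,
        r2_outcome=r2_out,
        direction_true=bool(r2_exp > r2_out),
        pval=float(2 * stats.norm.sf(abs(z))),
    )


def leave_one_out(iv_set, model: str = "random") -> pd.DataFrame:
    """IVW estimates with each instrument excluded in turn.

    Returns one row per excluded variant plus an 'All' row, flagging any
    exclusion that changes the estimate's sign or moves it outside the
    all-instrument 95% CI.
    """
    t = iv_set.table if hasattr(iv_set, "table") else iv_set
    k = len(t)
    if k < 2:
        raise EstimationError("leave-one-out requires >= 2 instruments")
    full = ivw(t, model=model)
    rows = []
    for j in range(k):
        sub = t.drop(t.index[j]).reset_index(drop=True)
        est = ivw(sub, model=model)
        flagged = (
            np.sign(est.beta) != np.sign(full.beta)
            or not (full.ci_low <= est.beta <= full.ci_high)
            # reduced-set CI excludes the full estimate: that variant alone
            # carried the difference
            or not (est.ci_low <= full.beta <= est.ci_high)
        )
        rows.append({
            "excluded": t["variant_id"].iloc[j],
            "beta": est.beta, "se": est.se,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "pval": est.pval, "flagged": bool(flagged),
        })
    rows.append({
        "excluded": "All", "beta": full.beta, "se": full.se,
        "ci_low": full.ci_low, "ci_high": full.ci_high,
        "pval": full.pval, "flagged": False,
    })
    return pd.DataFrame(rows)
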