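"""Two-step MR mediation: effect decomposition and product-of-coefficients
inference.

The total causal effect of an exposure on an outcome is decomposed into a
direct part and an indirect part carried by a mediator. The indirect effect
is the product of the two step estimates (exposure->mediator times
mediator->outcome); its standard error comes from the first-order delta
method

    se(a*b) = sqrt(a^2 se_b^2 + b^2 se_a^2)

and its confidence interval from either the symmetric delta-method normal
interval or the (generally asymmetric) quantiles of the distribution of the
product of two independent normals, evaluated by seeded Monte Carlo.
Benjamini-Hochberg FDR adjustment is provided for screening the step
estimates before mediation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimators import MREstimate, Z95

__all__ = [
    "PathEstimates",
    "MediationResult",
    "indirect_effect",
    "mediation_ci",
    "proportion_mediated",
    "decompose",
    "bh_fdr",
]


@dataclass
class PathEstimates:
    """The three MR estimates entering one mediation triple."""

    exposure_mediator: MREstimate
    mediator_outcome: MREstimate
    exposure_outcome_total: MREstimate
    exposure: str = "exposure"
    mediator: str = "mediator"
    outcome: str = "outcome"


@dataclass
class MediationResult:
    """Decomposition of a total effect into direct and indirect parts."""

    indirect: float
    indirect_se: float
    ci_low: float
    ci_high: float
    pval: float
    direct: float
    total: float
    proportion_mediated: float  # percent of the total effect
    method: str
    exposure: str = "exposure"
    mediator: str = "mediator"
    outcome: str = "outcome"

    def to_dict(self) -> dict:
        return asdict(self)


def indirect_effect(a: float, se_a: float, b: float, se_b: float,
                    exact: bool = False) -> tuple[float, float]:
    """Product-of-coefficients indirect effect and its delta-method SE.

    ``exact=True`` adds the second-order term se_a^2 * se_b^2 (the exact
    variance of a product of independent normals).
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    est = a * b
    var = a**2 * se_b**2 + b**2 * se_a**2
    if exact:
        var += se_a**2 * se_b**2
    return est, float(np.sqrt(var))


def mediation_ci(
    a: float, se_a: float, b: float, se_b: float,
    method: str = "delta",
    n_draws: int = 1_000_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """95% interval and two-sided p for the indirect effect a*b.

    'delta': symmetric normal interval around a*b at the delta-method SE.
    'product': quantiles of the product of two independent normals
    (Monte-Carlo, seeded), asymmetric in general; the p-value is twice the
    smaller tail probability of the product falling on the far side of 0.
    """
    if method == "delta":
        est, se = indirect_effect(a, se_a, b, se_b)
        if se == 0:  # both point estimates zero: first-order variance collapses
            return est, est, 1.0
        z = stats.norm.ppf(1 - alpha / 2)
        pval = 2 * stats.norm.sf(abs(est) / se)
        return est - z * se, est + z * se, float(pval)
    if method == "product":
        rng = np.random.default_rng(seed)
        prod = rng.normal(a, se_a, n_draws) * rng.normal(b, se_b, n_draws)
        lo, hi = np.quantile(prod, [alpha / 2, 1 - alpha / 2])
        p_low = np.mean(prod <= 0)
        pval = 2 * min(p_low, 1 - p_low)
        return float(lo), float(hi), float(min(pval, 1.0))
    raise ValueError(f"unknown mediation CI method {method!r}")


def proportion_mediated(indirect: float, total: float) -> float:
    """Indirect effect as a percentage of the total effect."""
    if total == 0:
        raise ZeroDivisionError("proportion mediated undefined for zero total effect")
    return 100.0 * indirect / total


def decompose(
    paths: PathEstimates,
    method: str = "delta",
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> MediationResult:
    """Decompose a total effect into direct and indirect parts.

    The indirect effect is the product of the two step estimates; the
    direct effect is total minus indirect (so direct + indirect = total
    exactly); the proportion mediated is indirect/total as a percent.
    """
    a_est = paths.exposure_mediator
    b_est = paths.mediator_outcome
    total = paths.exposure_outcome_total.beta
    est, se = indirect_effect(a_est.beta, a_est.se, b_est.beta, b_est.se)
    lo, hi, pval = mediation_ci(
        a_est.beta, a_est.se, b_est.beta, b_est.se,
        method=method, n_draws=n_draws, seed=seed,
    )
    return MediationResult(
        indirect=est, indirect_se=se, ci_low=lo, ci_high=hi, pval=pval,
        direct=total - est, total=total,
        proportion_mediated=proportion_mediated(est, total) if total != 0 else np.nan,
        method=method,
        exposure=paths.exposure, mediator=paths.mediator, outcome=paths.outcome,
    )


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
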