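"""Synthetic GWAS summary statistics with known causal structure.

Generates two-sample (and three-sample, for mediation) summary statistics
under an exposure -> mediator -> outcome causal chain with an optional
direct exposure -> outcome path and configurable horizontal pleiotropy,
so every downstream estimator can be checked against ground truth.

The generative model works directly at the summary level. For a variant j
with effect-allele frequency f_j and true per-allele effect gamma_j on a
standardized exposure, a GWAS of n individuals reports

    beta_hat_j = beta_true_j + e_j,   e_j ~ N(0, se_j^2),
    se_j = 1 / sqrt(2 f_j (1 - f_j) n),

which is the large-sample variance of a per-allele regression coefficient
for a unit-variance trait. True marginal effects follow the causal diagram:

    variant -> exposure:  gamma_j
    variant -> mediator:  gamma_j * A
    variant -> outcome :  gamma_j * (A*B + C') + alpha_j

where A is the exposure->mediator effect, B the mediator->outcome effect,
C' the direct exposure->outcome effect, and alpha_j a direct
variant->outcome (horizontally pleiotropic) path present only for a
configurable fraction of variants — balanced when its mean is zero,
directional otherwise. The three GWAS draw independent noise
(non-overlapping samples). LD is block-diagonal exchangeable; true effects
are assigned to one index variant per block and tagged by the others in
proportion to the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .sumstats import COLUMNS, write_sumstats, write_ld_matrix

__all__ = ["TruthConfig", "SyntheticStudy", "simulate_study", "ConfigurationError"]

_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                 ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")]


class ConfigurationError(ValueError):
    """A generative parameter is outside its valid range."""


@dataclass
class TruthConfig:
    """Generative causal parameters of a synthetic two-step MR study.

    Defaults describe a well-powered study: 50 independent instruments,
    GWAS of 50,000 individuals per trait, and the causal chain
    A = 0.3 (exposure->mediator), B = 0.2 (mediator->outcome),
    C' = 0.1 (direct exposure->outcome), with no horizontal pleiotropy.
    """

    n_snps: int = 50
    #: additional variants affecting the mediator directly (not via the
    #: exposure); needed for an unconfounded mediator->outcome step
    n_mediator_snps: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)
    #: SD of true per-allele effects on the exposure (exposure-SD units)
    instrument_effect_sd: float = 0.05
    exposure_mediator_effect: float = 0.3   # A
    mediator_outcome_effect: float = 0.2    # B
    exposure_outcome_direct: float = 0.1    # C'
    pleiotropy_fraction: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_exposure: int = 50_000
    n_mediator: int = 50_000
    n_outcome: int = 50_000
    ld_block_size: int = 1
    ld_rho: float = 0.0
    seed: int = 0

    @property
    def total_effect(self) -> float:
        """True total exposure->outcome effect, A*B + C'."""
        return (self.exposure_mediator_effect * self.mediator_outcome_effect
                + self.exposure_outcome_direct)

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError(f"n_snps must be >= 1, got {self.n_snps}")
        if self.n_mediator_snps < 0:
            raise ConfigurationError(
                f"n_mediator_snps must be >= 0, got {self.n_mediator_snps}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        for name in ("n_exposure", "n_mediator", "n_outcome"):
            if getattr(self, name) < 2:
                raise ConfigurationError(f"{name} must be >= 2, got {getattr(self, name)}")
        if not (0.0 <= self.pleiotropy_fraction <= 1.0):
            raise ConfigurationError(f"pleiotropy_fraction must be in [0, 1], got {self.pleiotropy_fraction}")
        if self.pleiotropy_sd < 0:
            raise ConfigurationError(f"pleiotropy_sd must be >= 0, got {self.pleiotropy_sd}")
        if self.instrument_effect_sd < 0:
            raise ConfigurationError(f"instrument_effect_sd must be >= 0, got {self.instrument_effect_sd}")
        if self.ld_block_size < 1:
            raise ConfigurationError(f"ld_block_size must be >= 1, got {self.ld_block_size}")
        if not abs(self.ld_rho) < 1:
            raise ConfigurationError(f"|ld_rho| must be < 1, got {self.ld_rho}")


@dataclass
class SyntheticStudy:
    """Three GWAS summary tables over one variant set, plus the truth.

    ``truth_effects`` records the noise-free per-variant effects actually
    used to generate each table, for parameter-recovery checks.
    """

    exposure_stats: pd.DataFrame
    mediator_stats: pd.DataFrame
    outcome_stats: pd.DataFrame
    ld_matrix: pd.DataFrame
    truth: TruthConfig
    truth_effects: pd.DataFrame | None = None

    def write(self, outdir) -> Path:
        """Export the study as TSV tables plus the truth as YAML."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sumstats(self.exposure_stats, outdir / "exposure.tsv")
        write_sumstats(self.mediator_stats, outdir / "mediator.tsv")
        write_sumstats(self.outcome_stats, outdir / "outcome.tsv")
        write_ld_matrix(self.ld_matrix, outdir / "ld.tsv")
        truth = asdict(self.truth)
        truth["maf_range"] = list(truth["maf_range"])
        (outdir / "truth.yaml").write_text(yaml.safe_dump(truth), encoding="utf-8")
        return outdir


def _gwas_table(ids, ea, oa, freq, beta_true, n, rng) -> pd.DataFrame:
    se = 1.0 / np.sqrt(2.0 * freq * (1.0 - freq) * n)
    beta = beta_true + rng.normal(0.0, se)
    pval = np.maximum(2.0 * stats.norm.sf(np.abs(beta / se)), 1e-300)
    return pd.DataFrame(
        {
            "variant_id": ids,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": freq,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": np.full(len(ids), n, dtype=np.int64),
        },
        columns=COLUMNS,
    )


def simulate_study(config: TruthConfig) -> SyntheticStudy:
    """Simulate a three-GWAS study under the configured causal diagram.

    Deterministic under a fixed ``config.seed``: two calls with the same
    configuration return identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    m_med = config.n_mediator_snps
    m_all = m + m_med

    ids = np.array([f"rs{j + 1:07d}" for j in range(m_all)])
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m_all)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    freq = rng.uniform(config.maf_range[0], config.maf_range[1], size=m_all)

    # True effects on the exposure: drawn per LD block for the index variant
    # and tagged by the rest of the block at r * gamma_index. Mediator-only
    # variants (appended after the exposure instruments) have gamma = 0 and
    # their own direct effects delta on the mediator.
    gamma = np.zeros(m_all)
    gamma[:m] = rng.normal(0.0, config.instrument_effect_sd, size=m)
    block = np.arange(m) // config.ld_block_size
    if config.ld_block_size > 1:
        index_of_block = block * config.ld_block_size
        is_index = np.arange(m) == index_of_block
        gamma[:m] = np.where(is_index, gamma[:m], config.ld_rho * gamma[index_of_block])
    delta = np.zeros(m_all)
    if m_med > 0:
        delta[m:] = rng.normal(0.0, config.instrument_effect_sd, size=m_med)

    n_pleio = int(round(config.pleiotropy_fraction * m))
    alpha = np.zeros(m_all)
    if n_pleio > 0:
        which = rng.choice(m, size=n_pleio, replace=False)
        alpha[which] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n_pleio)

    a_ = config.exposure_mediator_effect
    b_ = config.mediator_outcome_effect
    c_direct = config.exposure_outcome_direct

    # Directional pleiotropy is defined relative to the exposure-increasing
    # allele (allele labels are arbitrary, so a fixed-sign offset on the
    # labelled effect allele would be balanced after orientation).
    alpha_oriented = np.where(gamma < 0, -alpha, alpha)

    beta_exp_true = gamma
    beta_med_true = gamma * a_ + delta
    beta_out_true = gamma * (a_ * b_ + c_direct) + delta * b_ + alpha_oriented

    exposure = _gwas_table(ids, ea, oa, freq, beta_exp_true, config.n_exposure, rng)
    mediator = _gwas_table(ids, ea, oa, freq, beta_med_true, config.n_mediator, rng)
    outcome = _gwas_table(ids, ea, oa, freq, beta_out_true, config.n_outcome, rng)

    ld = np.eye(m_all)
    if config.ld_block_size > 1 and config.ld_rho != 0.0:
        same_block = block[:, None] == block[None, :]
        ld[:m, :m] = np.where(same_block, config.ld_rho, 0.0)
        np.fill_diagonal(ld, 1.0)
    ld_matrix = pd.DataFrame(ld, index=ids, columns=ids)

    truth_effects = pd.DataFrame({
        "variant_id": ids,
        "gamma": gamma, "delta": delta, "alpha": alpha_oriented,
        "beta_exposure_true": beta_exp_true,
        "beta_mediator_true": beta_med_true,
        "beta_outcome_true": beta_out_true,
        "mediator_instrument": np.arange(m_all) >= m,
    })
    return SyntheticStudy(exposure, mediator, outcome, ld_matrix, config, truth_effects)
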