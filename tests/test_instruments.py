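"""Instrument selection: significance, clumping, strength, harmonization,
directionality."""

import numpy as np
import pandas as pd
import pytest

from mrmediation.instruments import (
    ClumpError,
    clump,
    f_statistic,
    filter_significant,
    harmonize,
    r2_from_pval_n,
    select_instruments,
    steiger_filter,
)
from mrmediation.sumstats import COLUMNS
from mrmediation.synthetic import TruthConfig, simulate_study
from tests.conftest import make_iv


def _stats(rows, extra_cols=()):
    cols = COLUMNS + list(extra_cols)
    return pd.DataFrame(rows, columns=cols)


def _row(vid, pval, beta=0.1, se=0.01, ea="A", oa="G", eaf=0.3, n=50000, *extra):
    return (vid, ea, oa, eaf, beta, se, pval, n, *extra)


class TestSignificanceFilter:
    def test_strict_inequality_at_threshold(self):
        df = _stats([_row("a", 1e-9), _row("b", 5e-8), _row("c", 1e-7)])
        kept = filter_significant(df, 5e-8)
        assert list(kept["variant_id"]) == ["a"]

    def test_threshold_one_keeps_all(self):
        df = _stats([_row("a", 0.5), _row("b", 0.999)])
        assert len(filter_significant(df, 1.0)) == 2

    def test_empty_table(self):
        assert len(filter_significant(_stats([]), 5e-8)) == 0


class TestClump:
    def test_identity_ld_keeps_all(self):
        df = _stats([_row("a", 1e-9), _row("b", 1e-8), _row("c", 1e-7)])
        ld = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        kept = clump(df, ld)
        assert sorted(kept["variant_id"]) == ["a", "b", "c"]

    def test_single_clump_keeps_smallest_p(self):
        df = _stats([_row("a", 1e-10), _row("b", 1e-9), _row("c", 1e-8)])
        r = np.sqrt(0.9)
        ld = pd.DataFrame(np.full((3, 3), r), index=list("abc"), columns=list("abc"))
        np.fill_diagonal(ld.values, 1.0)
        kept = clump(df, ld, r2_threshold=0.001)
        assert list(kept["variant_id"]) == ["a"]

    def test_missing_variant_raises_with_name(self):
        df = _stats([_row("a", 1e-10), _row("zz", 1e-9)])
        ld = pd.DataFrame(np.eye(1), index=["a"], columns=["a"])
        with pytest.raises(ClumpError, match="zz"):
            clump(df, ld)

    def test_window_limits_clumping(self):
        # perfectly correlated pair but 20 Mb apart: both kept
        df = pd.DataFrame(
            [_row("a", 1e-10) + (1_000_000,), _row("b", 1e-9) + (21_000_000,)],
            columns=COLUMNS + ["pos"],
        )
        ld = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=["a", "b"], columns=["a", "b"])
        assert len(clump(df, ld, window_kb=10_000)) == 2
        df.loc[1, "pos"] = 2_000_000
        assert len(clump(df, ld, window_kb=10_000)) == 1

    @staticmethod
    def _oracle(df, ld, r2_threshold):
        """Independent re-implementation of the greedy rule."""
        remaining = df.sort_values(["pval", "variant_id"])["variant_id"].tolist()
        kept = []
        while remaining:
            lead = remaining.pop(0)
            kept.append(lead)
            remaining = [
                v for v in remaining if ld.loc[lead, v] ** 2 < r2_threshold
            ]
        return kept

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for trial in range(10):
            m = 50
            ids = [f"v{i}" for i in range(m)]
            a = rng.normal(size=(m, m))
            corr = np.corrcoef(a @ a.T + 5 * np.eye(m))
            ld = pd.DataFrame(corr, index=ids, columns=ids)
            df = _stats([_row(v, p) for v, p in zip(ids, rng.uniform(0, 1e-6, m))])
            got = clump(df, ld, r2_threshold=0.1)["variant_id"].tolist()
            assert got == self._oracle(df, ld, 0.1)

    def test_idempotent(self, rng):
        m = 30
        ids = [f"v{i}" for i in range(m)]
        a = rng.normal(size=(m, m))
        corr = np.corrcoef(a @ a.T + 5 * np.eye(m))
        ld = pd.DataFrame(corr, index=ids, columns=ids)
        df = _stats([_row(v, p) for v, p in zip(ids, rng.uniform(0, 1e-6, m))])
        once = clump(df, ld, r2_threshold=0.2)
        twice = clump(once, ld, r2_threshold=0.2)
        pd.testing.assert_frame_equal(once, twice)


class TestFStatistic:
    def test_direct_formula(self):
        assert f_statistic(0.1, 0.02) == pytest.approx(25.0)
        assert f_statistic(0.0, 0.02) == 0.0

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)

    def test_mean_f_matches_noncentral_expectation(self, rng):
        """For gamma=0.1, n=50,000, maf=0.3 the mean F over replicates is
        1 + n R^2/(1-R^2) with R^2 = 2f(1-f)gamma^2 (standardized trait)."""
        gamma, n, f = 0.1, 50_000, 0.3
        se = 1.0 / np.sqrt(2 * f * (1 - f) * n)
        beta_hat = rng.normal(gamma, se, size=4000)
        r2 = 2 * f * (1 - f) * gamma**2
        expected = 1 + n * r2 / (1 - r2)
        assert np.mean(f_statistic(beta_hat, se)) == pytest.approx(expected, rel=0.1)


class TestHarmonize:
    def _pair(self, exp_row, out_row):
        return _stats([exp_row]), _stats([out_row])

    def test_swapped_alleles_flip_outcome_beta(self):
        exp, out = self._pair(
            _row("rs1", 1e-10, beta=0.1, ea="A", oa="G", eaf=0.3),
            _row("rs1", 0.5, beta=-0.05, ea="G", oa="A", eaf=0.7),
        )
        iv = harmonize(exp, out)
        assert iv.table.loc[0, "beta_outcome"] == pytest.approx(0.05)
        assert iv.table.loc[0, "eaf"] == pytest.approx(0.3)

    def test_strand_complement_aligned(self):
        exp, out = self._pair(
            _row("rs1", 1e-10, beta=0.1, ea="A", oa="G"),
            _row("rs1", 0.5, beta=-0.05, ea="T", oa="C"),
        )
        iv = harmonize(exp, out)
        assert iv.table.loc[0, "beta_outcome"] == pytest.approx(-0.05)

    def test_strand_complement_swapped(self):
        exp, out = self._pair(
            _row("rs1", 1e-10, beta=0.1, ea="A", oa="G"),
            _row("rs1", 0.5, beta=-0.05, ea="C", oa="T"),
        )
        iv = harmonize(exp, out)
        assert iv.table.loc[0, "beta_outcome"] == pytest.approx(0.05)

    def test_palindromic_retained_when_frequencies_agree(self):
        exp, out = self._pair(
            _row("rs1", 1e-10, beta=0.1, ea="A", oa="T", eaf=0.10),
            _row("rs1", 0.5, beta=0.02, ea="A", oa="T", eaf=0.12),
        )
        iv = harmonize(exp, out)
        assert iv.n_snps == 1
        assert iv.table.loc[0, "beta_outcome"] == pytest.approx(0.02)

    def test_palindromic_flipped_when_frequencies_disagree(self):
        exp, out = self._pair(
            _row("rs1", 1e-10, beta=0.1, ea="A", oa="T", eaf=0.10),
            _row("rs1", 0.5, beta=0.02, ea="A", oa="T", eaf=0.88),
        )
        iv = harmonize(exp, out)
        assert iv.table.loc[0, "beta_outcome"] == pytest.approx(-0.02)

    @pytest.mark.parametrize("eaf_exp, eaf_out", [(0.48, 0.3), (0.3, 0.45), (0.58, 0.3)])
    def test_palindromic_near_half_dropped(self, eaf_exp, eaf_out):
        exp, out = self._pair(
            _row("rs1", 1e-10, beta=0.1, ea="A", oa="T", eaf=eaf_exp),
            _row("rs1", 0.5, beta=0.02, ea="A", oa="T", eaf=eaf_out),
        )
        iv = harmonize(exp, out)
        assert iv.n_snps == 0
        assert iv.drops == [("rs1", "ambiguous palindromic")]

    def test_palindromic_missing_eaf_dropped(self):
        exp, out = self._pair(
            _row("rs1", 1e-10, beta=0.1, ea="C", oa="G", eaf=np.nan),
            _row("rs1", 0.5, beta=0.02, ea="C", oa="G", eaf=0.2),
        )
        iv = harmonize(exp, out)
        assert iv.n_snps == 0 and "missing eaf" in iv.drops[0][1]

    def test_incompatible_alleles_dropped_not_raised(self):
        exp, out = self._pair(
            _row("rs1", 1e-10, ea="A", oa="G"),
            _row("rs1", 0.5, ea="A", oa="C"),
        )
        iv = harmonize(exp, out)
        assert iv.n_snps == 0
        assert iv.drops == [("rs1", "incompatible alleles")]

    def test_provenance_counts_reconcile(self, default_study):
        exp = default_study.exposure_stats
        out = default_study.outcome_stats.iloc[5:].reset_index(drop=True)
        iv = harmonize(exp, out)
        assert len(exp) - iv.n_snps == sum(iv.provenance.values())

    def test_orientation_invariance(self, default_study):
        """Flipping every outcome allele, beta sign and eaf leaves the
        harmonized set unchanged."""
        exp = default_study.exposure_stats
        out = default_study.outcome_stats
        flipped = out.copy()
        flipped["effect_allele"] = out["other_allele"]
        flipped["other_allele"] = out["effect_allele"]
        flipped["beta"] = -out["beta"]
        flipped["eaf"] = 1 - out["eaf"]
        pd.testing.assert_frame_equal(
            harmonize(exp, out).table, harmonize(exp, flipped).table
        )


class TestSteiger:
    def test_direction_decides_retention(self):
        iv = make_iv([0.1, 0.1], 0.01, [0.01, 0.5], 0.01)
        # first variant: strong on exposure, null on outcome -> retained
        kept = steiger_filter(iv)
        assert list(kept.table["variant_id"]) == ["rs1"]
        assert kept.provenance["steiger"] == 1

    def test_r2_transform_monotone_in_p(self):
        r2 = r2_from_pval_n([1e-30, 1e-8, 0.5], 40_000)
        assert r2[0] > r2[1] > r2[2] >= 0

    def test_no_pleiotropy_study_retains_most_instruments(self):
        """After the strength filters, the directionality filter removes
        almost nothing when the generative model has no pleiotropy."""
        retained = total = 0
        for s in range(30):
            st = simulate_study(TruthConfig(seed=200 + s))
            before = select_instruments(
                st.exposure_stats, st.outcome_stats, apply_steiger=False)
            kept = steiger_filter(before)
            retained += kept.n_snps
            total += before.n_snps
        assert retained / total >= 0.95


def test_pipeline_order_and_provenance(default_study):
    iv = select_instruments(
        default_study.exposure_stats, default_study.outcome_stats,
        ld=default_study.ld_matrix,
    )
    prov = iv.provenance
    assert set(prov) >= {"not_significant", "clumped", "weak_instrument", "steiger"}
    assert len(default_study.exposure_stats) - iv.n_snps == sum(prov.values())
    # everything retained is genome-wide significant and strong
    assert (iv.table["pval_exposure"] < 5e-8).all()
    assert (iv.table["f_statistic"] > 10).all()
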