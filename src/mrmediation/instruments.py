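"""Instrument selection and harmonization for two-sample MR.

The selection pipeline, in order: genome-wide significance filter
(p < 5e-8), greedy LD clumping (r^2 = 0.001, 10,000 kb window), per-variant
F-statistic filter (F > 10), exposure/outcome allele harmonization, and a
per-variant directionality (Steiger) filter keeping variants that explain
more variance in the exposure than in the outcome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InstrumentSet",
    "ClumpError",
    "filter_significant",
    "clump",
    "f_statistic",
    "harmonize",
    "steiger_filter",
    "select_instruments",
    "r2_from_pval_n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

IV_COLUMNS = [
    "variant_id",
    "beta_exposure", "se_exposure", "pval_exposure", "n_exposure",
    "beta_outcome", "se_outcome", "pval_outcome", "n_outcome",
    "eaf", "f_statistic",
]


class ClumpError(KeyError):
    """A variant required for clumping is missing from the LD matrix."""


@dataclass
class InstrumentSet:
    """Harmonized per-variant exposure/outcome effect pairs.

    ``table`` holds one row per instrument (columns ``IV_COLUMNS``; both
    effects refer to the same effect allele). ``provenance`` counts
    variants removed at each filter stage; ``drops`` lists per-variant
    removal reasons from harmonization and filtering.
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    drops: list = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def __post_init__(self):
        ids = self.table["variant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate instrument variant ID {dup!r}")

    def drop_variants(self, variant_ids, reason: str, stage: str) -> "InstrumentSet":
        """Return a new set without the named variants, recording provenance."""
        mask = self.table["variant_id"].isin(set(variant_ids))
        prov = dict(self.provenance)
        prov[stage] = prov.get(stage, 0) + int(mask.sum())
        drops = self.drops + [(v, reason) for v in self.table.loc[mask, "variant_id"]]
        return InstrumentSet(self.table.loc[~mask].reset_index(drop=True), prov, drops)

    def write(self, path, provenance_path=None) -> Path:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False, float_format="%.12g")
        side = Path(provenance_path) if provenance_path else path.with_suffix(".provenance.json")
        side.write_text(json.dumps(
            {"provenance": self.provenance, "drops": self.drops, "n_retained": self.n_snps},
            indent=2))
        return path


def filter_significant(stats_df: pd.DataFrame, threshold: float = 5e-8) -> pd.DataFrame:
    """Keep rows with p strictly below the significance threshold."""
    return stats_df.loc[stats_df["pval"] < threshold].reset_index(drop=True)


def clump(
    stats_df: pd.DataFrame,
    ld: pd.DataFrame | None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> pd.DataFrame:
    """Greedy LD clumping: retain approximately independent index variants.

    Repeatedly takes the smallest-p remaining variant and discards every
    remaining variant correlated with it at r^2 >= ``r2_threshold`` (and,
    when a ``pos`` column is present, within ``window_kb`` of it; without
    positions all pairs count as in-window). Output is sorted by p-value.

    With ``ld=None`` variants are assumed independent and the input is
    returned sorted by p.
    """
    if len(stats_df) == 0:
        return stats_df.reset_index(drop=True)
    ordered = stats_df.sort_values(["pval", "variant_id"], kind="mergesort").reset_index(drop=True)
    if ld is None:
        return ordered
    missing = set(ordered["variant_id"]) - set(ld.index)
    if missing:
        raise ClumpError(f"variant {sorted(missing)[0]!r} missing from LD matrix")
    sub = ld.loc[ordered["variant_id"], ordered["variant_id"]].to_numpy()
    r2 = sub**2
    pos = ordered["pos"].to_numpy(float) if "pos" in ordered.columns else None
    alive = np.ones(len(ordered), dtype=bool)
    keep = []
    for i in range(len(ordered)):
        if not alive[i]:
            continue
        keep.append(i)
        linked = r2[i] >= r2_threshold
        if pos is not None:
            linked &= np.abs(pos - pos[i]) <= window_kb * 1000.0
        linked[i] = False
        alive &= ~linked
    return ordered.iloc[keep].reset_index(drop=True)


def f_statistic(beta, se):
    """Per-variant instrument-strength statistic, (beta/se)^2."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    return (beta / se) ** 2


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_maf_limit: float = 0.42,
) -> InstrumentSet:
    """Align outcome effects to the exposure's effect allele.

    Variants present in both tables are joined; outcome rows whose alleles
    are swapped relative to the exposure have their beta sign and eaf
    flipped, strand-complemented alleles are complemented then aligned, and
    palindromic variants (A/T, C/G) are oriented by allele-frequency
    agreement — dropped when either frequency is missing or the minor-allele
    frequency reaches ``palindrome_maf_limit`` (too close to 0.5 to call).
    Irreconcilable allele pairs are dropped with a recorded reason, never
    raised.
    """
    exp = exposure.set_index("variant_id", drop=False)
    out = outcome.set_index("variant_id", drop=False)
    shared = [v for v in exp.index if v in out.index]
    provenance = {"not_in_outcome": len(exposure) - len(shared)}
    drops: list = []

    rows = []
    n_incompatible = n_palindromic = 0
    for v in shared:
        e = exp.loc[v]
        o = out.loc[v]
        e_ea, e_oa = e["effect_allele"], e["other_allele"]
        o_ea, o_oa = o["effect_allele"], o["other_allele"]
        beta_o, eaf_o = float(o["beta"]), o["eaf"]
        eaf_o = None if pd.isna(eaf_o) else float(eaf_o)
        eaf_e = None if pd.isna(e["eaf"]) else float(e["eaf"])

        if _is_palindromic(e_ea, e_oa):
            if not _is_palindromic(o_ea, o_oa) or {o_ea, o_oa} != {e_ea, e_oa}:
                drops.append((v, "incompatible alleles"))
                n_incompatible += 1
                continue
            if eaf_e is None or eaf_o is None:
                drops.append((v, "ambiguous palindromic (missing eaf)"))
                n_palindromic += 1
                continue
            maf = max(min(eaf_e, 1 - eaf_e), min(eaf_o, 1 - eaf_o))
            if maf >= palindrome_maf_limit:
                drops.append((v, "ambiguous palindromic"))
                n_palindromic += 1
                continue
            # allele labels cannot orient a palindrome; frequencies decide
            if (eaf_e < 0.5) != (eaf_o < 0.5):
                beta_o, eaf_o = -beta_o, 1 - eaf_o
        else:
            ce_ea, ce_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
            if (o_ea, o_oa) == (e_ea, e_oa) or (ce_ea, ce_oa) == (e_ea, e_oa):
                pass  # aligned (directly or after strand complement)
            elif (o_ea, o_oa) == (e_oa, e_ea) or (ce_ea, ce_oa) == (e_oa, e_ea):
                beta_o = -beta_o
                eaf_o = None if eaf_o is None else 1 - eaf_o
            else:
                drops.append((v, "incompatible alleles"))
                n_incompatible += 1
                continue

        eaf = eaf_e if eaf_e is not None else eaf_o
        rows.append({
            "variant_id": v,
            "beta_exposure": float(e["beta"]), "se_exposure": float(e["se"]),
            "pval_exposure": float(e["pval"]), "n_exposure": int(e["n"]),
            "beta_outcome": beta_o, "se_outcome": float(o["se"]),
            "pval_outcome": float(o["pval"]), "n_outcome": int(o["n"]),
            "eaf": np.nan if eaf is None else eaf,
        })

    provenance["incompatible_alleles"] = n_incompatible
    provenance["ambiguous_palindromic"] = n_palindromic
    table = pd.DataFrame(rows, columns=[c for c in IV_COLUMNS if c != "f_statistic"])
    if len(table):
        table["f_statistic"] = f_statistic(table["beta_exposure"], table["se_exposure"])
    else:
        table["f_statistic"] = pd.Series(dtype=float)
    return InstrumentSet(table.reset_index(drop=True), provenance, drops)


def r2_from_pval_n(pval, n):
    """Variance explained implied by a p-value and sample size.

    Inverts the 1-df F test of a simple regression:
    F = Q_F(p; 1, n-2), r^2 = F / (F + n - 2).
    """
    pval = np.clip(np.asarray(pval, dtype=float), 1e-300, 1.0)
    n = np.asarray(n, dtype=float)
    # F(1, n-2) quantile via the t distribution, which stays finite for
    # extreme p where the incomplete-beta inverse overflows
    tval = stats.t.isf(pval / 2.0, n - 2)
    fval = tval * tval
    return fval / (fval + n - 2)


def steiger_filter(iv_set: InstrumentSet) -> InstrumentSet:
    """Keep instruments whose implied direction of effect is exposure->outcome.

    A variant is retained when it explains more trait variance in the
    exposure than in the outcome (per-variant r^2 from the p/n transform).
    """
    t = iv_set.table
    if len(t) == 0:
        return iv_set
    r2_exp = r2_from_pval_n(t["pval_exposure"], t["n_exposure"])
    r2_out = r2_from_pval_n(t["pval_outcome"], t["n_outcome"])
    wrong = t.loc[r2_exp <= r2_out, "variant_id"]
    return iv_set.drop_variants(wrong, "wrong direction (outcome r2 >= exposure r2)",
                                "steiger")


def select_instruments(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: pd.DataFrame | None = None,
    p_threshold: float = 5e-8,
    clump_r2: float = 0.001,
    clump_kb: float = 10_000,
    f_min: float = 10.0,
    palindrome_maf_limit: float = 0.42,
    apply_steiger: bool = True,
) -> InstrumentSet:
    """Full selection pipeline: significance -> clumping -> F -> harmonization -> direction."""
    n0 = len(exposure)
    sig = filter_significant(exposure, p_threshold)
    clumped = clump(sig, ld, clump_r2, clump_kb)
    fstat = f_statistic(clumped["beta"], clumped["se"])
    strong = clumped.loc[fstat > f_min].reset_index(drop=True)
    iv = harmonize(strong, outcome, palindrome_maf_limit)
    prov = {
        "not_significant": n0 - len(sig),
        "clumped": len(sig) - len(clumped),
        "weak_instrument": len(clumped) - len(strong),
        **iv.provenance,
    }
    iv = InstrumentSet(iv.table, prov, iv.drops)
    if apply_steiger:
        iv = steiger_filter(iv)
    return iv
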