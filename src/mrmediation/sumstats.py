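"""Reading, validating and writing GWAS summary statistics.

The canonical dialect is a UTF-8 tab-separated table with columns
``variant_id, effect_allele, other_allele, eaf, beta, se, pval, n``
('.' decimal separator, missing effect-allele frequency encoded as ``NA``).
Common header synonyms (SNP/rsid, EA/A1, OA/A2, p/pvalue, ...) are accepted
on input and normalised to the canonical names.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStatRecord",
    "SumstatsFormatError",
    "read_sumstats",
    "write_sumstats",
    "validate_sumstats",
    "read_ld_matrix",
    "write_ld_matrix",
    "COLUMNS",
]

COLUMNS = [
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

#: accepted case-insensitive header synonyms -> canonical name
HEADER_SYNONYMS = {
    "snp": "variant_id",
    "rsid": "variant_id",
    "rs_id": "variant_id",
    "id": "variant_id",
    "variant": "variant_id",
    "ea": "effect_allele",
    "a1": "effect_allele",
    "oa": "other_allele",
    "a2": "other_allele",
    "non_effect_allele": "other_allele",
    "freq": "eaf",
    "frq": "eaf",
    "af": "eaf",
    "effect_allele_frequency": "eaf",
    "b": "beta",
    "effect": "beta",
    "stderr": "se",
    "standard_error": "se",
    "p": "pval",
    "pvalue": "pval",
    "p_value": "pval",
    "n_samples": "n",
    "samplesize": "n",
}

_BASES = frozenset("ACGT")


class SumstatsFormatError(ValueError):
    """A summary-statistics file does not conform to the expected dialect."""


@dataclass
class SummaryStatRecord:
    """One variant's association estimate in one GWAS.

    ``eaf`` may be ``None`` (unknown frequency); such records are usable
    everywhere except palindromic-allele resolution during harmonization.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int

    def validation_errors(self) -> list[str]:
        errors = []
        if self.effect_allele not in _BASES:
            errors.append(f"effect allele {self.effect_allele!r} is not a single base")
        if self.other_allele not in _BASES:
            errors.append(f"other allele {self.other_allele!r} is not a single base")
        if self.effect_allele == self.other_allele:
            errors.append("effect and other allele are identical")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            errors.append(f"eaf {self.eaf} outside (0, 1)")
        if not np.isfinite(self.beta):
            errors.append("non-finite beta")
        if not (np.isfinite(self.se) and self.se > 0):
            errors.append("non-positive SE")
        if not (0.0 < self.pval <= 1.0):
            errors.append(f"pval {self.pval} outside (0, 1]")
        if not (self.n == int(self.n) and self.n > 0):
            errors.append(f"sample size {self.n} not a positive integer")
        return errors


def _normalise_header(columns) -> dict:
    mapping = {}
    for col in columns:
        key = str(col).strip().lower()
        mapping[col] = HEADER_SYNONYMS.get(key, key)
    return mapping


def validate_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Split a raw table into valid records and per-row rejection reasons.

    Returns the validated table (canonical column order, original row order)
    and a list of ``(row_index, reason)`` pairs for rejected rows.
    """
    rejected: list[tuple[int, str]] = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            eaf = row.eaf
            eaf = None if eaf is None or (isinstance(eaf, float) and np.isnan(eaf)) else float(eaf)
            rec = SummaryStatRecord(
                variant_id=str(row.variant_id),
                effect_allele=str(row.effect_allele).upper(),
                other_allele=str(row.other_allele).upper(),
                eaf=eaf,
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                n=int(row.n),
            )
        except (TypeError, ValueError) as exc:
            rejected.append((i, f"unreadable numeric field: {exc}"))
            keep[i] = False
            continue
        errors = rec.validation_errors()
        if errors:
            rejected.append((i, "; ".join(errors)))
            keep[i] = False
    out = df.loc[keep, COLUMNS].reset_index(drop=True)
    out["effect_allele"] = out["effect_allele"].str.upper()
    out["other_allele"] = out["other_allele"].str.upper()
    out["n"] = out["n"].astype(np.int64)
    return out, rejected


def read_sumstats(path, on_invalid: str = "drop") -> pd.DataFrame:
    """Read a summary-statistics TSV into a validated DataFrame.

    Parameters
    ----------
    path : file path
    on_invalid : 'drop' rejects offending rows (reasons in ``df.attrs['rejected']``),
        'raise' raises on the first invalid row.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA"])
    df = df.rename(columns=_normalise_header(df.columns))
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    df["variant_id"] = df["variant_id"].astype(str)
    valid, rejected = validate_sumstats(df)
    if rejected and on_invalid == "raise":
        idx, reason = rejected[0]
        raise SumstatsFormatError(f"{path}: row {idx}: {reason}")
    valid.attrs["rejected"] = rejected
    return valid


def write_sumstats(df: pd.DataFrame, path) -> Path:
    """Write a summary-statistics table in the canonical TSV dialect.

    Numeric fields are written with 12 significant digits, so a write/read
    round trip reproduces the table to that precision.
    """
    path = Path(path)
    out = df.loc[:, COLUMNS].copy()
    buf = io.StringIO()
    buf.write("\t".join(COLUMNS) + "\n")
    for row in out.itertuples(index=False):
        eaf = "NA" if row.eaf is None or (isinstance(row.eaf, float) and np.isnan(row.eaf)) else f"{row.eaf:.12g}"
        buf.write(
            f"{row.variant_id}\t{row.effect_allele}\t{row.other_allele}\t{eaf}\t"
            f"{row.beta:.12g}\t{row.se:.12g}\t{row.pval:.12g}\t{int(row.n)}\n"
        )
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_ld_matrix(path) -> pd.DataFrame:
    """Read a dense LD correlation matrix (TSV, header row of variant IDs)."""
    ld = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    ld.index = ld.index.astype(str)
    ld.columns = ld.columns.astype(str)
    if list(ld.index) != list(ld.columns):
        raise SumstatsFormatError(f"{path}: LD matrix row/column variant IDs differ")
    return ld


def write_ld_matrix(ld: pd.DataFrame, path) -> Path:
    path = Path(path)
    ld.to_csv(path, sep="\t", float_format="%.12g")
    return path
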