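"""Study orchestration: run the full MR + mediation graph from a config.

A :class:`StudyConfig` names summary-statistics files for exposures,
mediators and outcomes, the exposure-outcome pairs and mediation triples to
run, and every selection/estimation threshold. :func:`run_pipeline`
executes instrument selection -> harmonization -> MR (all methods) ->
BH-FDR -> sensitivity suite -> mediation, and writes a reproducible report
bundle (results TSV, sensitivity JSON, mediation TSV, run log).
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import EstimationError, all_methods, ivw, mr_egger
from .instruments import select_instruments
from .mediation import PathEstimates, bh_fdr, decompose
from .sensitivity import leave_one_out, mr_presso, steiger_test
from .sumstats import read_ld_matrix, read_sumstats

logger = logging.getLogger("mrmediation")

__all__ = ["StudyConfig", "run_pipeline", "analyze_pair", "two_step_mr"]


@dataclass
class StudyConfig:
    """Everything needed to run one study end to end."""

    #: trait name -> summary-statistics TSV path
    traits: dict = field(default_factory=dict)
    #: (exposure, outcome) pairs to estimate
    pairs: list = field(default_factory=list)
    #: (exposure, mediator, outcome) mediation triples
    triples: list = field(default_factory=list)
    #: optional trait name -> LD matrix TSV path (for clumping the exposure)
    ld: dict = field(default_factory=dict)
    #: optional pair -> FDR family label; default family is the exposure
    fdr_families: dict = field(default_factory=dict)
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    f_min: float = 10.0
    palindrome_maf: float = 0.42
    fdr_alpha: float = 0.05
    mediation_method: str = "delta"
    presso_n_sim: int = 1000
    n_boot: int = 1000
    seed: int = 0
    outdir: str = "mr_output"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        cfg.pairs = [tuple(p) for p in cfg.pairs]
        cfg.triples = [tuple(t) for t in cfg.triples]
        return cfg

    def validate(self) -> None:
        for name, p in self.traits.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"summary statistics for {name!r} not found: {p}")
        for pair in self.pairs:
            for trait in pair:
                if trait not in self.traits:
                    raise KeyError(f"pair {pair} references unknown trait {trait!r}")
        for triple in self.triples:
            for trait in triple:
                if trait not in self.traits:
                    raise KeyError(f"triple {triple} references unknown trait {trait!r}")
        if not (0 < self.fdr_alpha < 1):
            raise ValueError(f"fdr_alpha must be in (0, 1), got {self.fdr_alpha}")


def analyze_pair(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: pd.DataFrame | None = None,
    config: StudyConfig | None = None,
) -> dict:
    """Instrument selection, all MR estimators and the sensitivity suite
    for one exposure-outcome pair. Returns a dict of in-memory results."""
    cfg = config or StudyConfig()
    iv = select_instruments(
        exposure, outcome, ld=ld,
        p_threshold=cfg.p_threshold, clump_r2=cfg.clump_r2, clump_kb=cfg.clump_kb,
        f_min=cfg.f_min, palindrome_maf_limit=cfg.palindrome_maf,
    )
    out = {"instruments": iv, "estimates": [], "sensitivity": {}}
    if iv.n_snps == 0:
        return out
    out["estimates"] = all_methods(iv, n_boot=cfg.n_boot, seed=cfg.seed)
    sens = {"steiger": steiger_test(iv).to_dict()}
    if iv.n_snps >= 3:
        egger = mr_egger(iv)
        sens["egger_intercept"] = {
            "intercept": egger.intercept, "se": egger.intercept_se,
            "pval": egger.intercept_pval,
        }
    if iv.n_snps >= 4:
        sens["presso"] = mr_presso(
            iv, n_sim=cfg.presso_n_sim, seed=cfg.seed
        ).to_dict()
    if iv.n_snps >= 2:
        sens["leave_one_out"] = leave_one_out(iv).to_dict(orient="records")
    out["sensitivity"] = sens
    return out


def two_step_mr(
    exposure: pd.DataFrame,
    mediator: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: pd.DataFrame | None = None,
    config: StudyConfig | None = None,
    method: str | None = None,
    labels: tuple[str, str, str] = ("exposure", "mediator", "outcome"),
):
    """Two-step MR mediation from three raw summary-statistics tables.

    Step 1 (exposure->mediator) and the total effect (exposure->outcome)
    use instruments selected from the exposure GWAS; step 2
    (mediator->outcome) uses instruments selected from the mediator GWAS,
    excluding variants genome-wide significant for the exposure — such
    variants affect the outcome through exposure paths other than the
    mediator and would confound the mediator->outcome step.

    Returns ``(PathEstimates, MediationResult)``.
    """
    cfg = config or StudyConfig()
    kw = dict(p_threshold=cfg.p_threshold, clump_r2=cfg.clump_r2,
              clump_kb=cfg.clump_kb, f_min=cfg.f_min,
              palindrome_maf_limit=cfg.palindrome_maf)
    iv_total = select_instruments(exposure, outcome, ld=ld, **kw)
    iv_step1 = select_instruments(exposure, mediator, ld=ld, **kw)
    exposure_hits = set(
        exposure.loc[exposure["pval"] < cfg.p_threshold, "variant_id"]
    )
    mediator_clean = mediator.loc[~mediator["variant_id"].isin(exposure_hits)]
    iv_step2 = select_instruments(mediator_clean, outcome, ld=ld, **kw)
    paths = PathEstimates(
        exposure_mediator=ivw(iv_step1),
        mediator_outcome=ivw(iv_step2),
        exposure_outcome_total=ivw(iv_total),
        exposure=labels[0], mediator=labels[1], outcome=labels[2],
    )
    result = decompose(paths, method=method or cfg.mediation_method, seed=cfg.seed)
    return paths, result


def _estimates_frame(pair_results: dict) -> pd.DataFrame:
    rows = []
    for (exp, outc), res in pair_results.items():
        for est in res["estimates"]:
            rows.append({"exposure": exp, "outcome": outc, **est.to_dict()})
    return pd.DataFrame(rows)


def run_pipeline(config: StudyConfig) -> dict:
    """Execute the configured study graph and write the report bundle.

    Mediation triples are only evaluated when both step MR estimates
    (exposure->mediator and mediator->outcome, IVW) remain significant
    after BH-FDR adjustment within their family. Stage errors are logged
    with the pair context and the pipeline continues for unaffected pairs.
    Identical config and seeds produce an identical bundle.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {name: read_sumstats(path) for name, path in config.traits.items()}
    ld_mats = {name: read_ld_matrix(path) for name, path in config.ld.items()}

    all_pairs = list(dict.fromkeys(
        list(config.pairs)
        + [(e, m) for e, m, _ in config.triples]
        + [(m, o) for _, m, o in config.triples]
        + [(e, o) for e, _, o in config.triples]
    ))
    pair_results: dict = {}
    for exp, outc in all_pairs:
        try:
            res = analyze_pair(
                tables[exp], tables[outc], ld=ld_mats.get(exp), config=config
            )
        except (EstimationError, ValueError) as exc:
            logger.error("pair %s -> %s failed: %s", exp, outc, exc)
            continue
        pair_results[(exp, outc)] = res
        res["instruments"].write(outdir / f"instruments_{exp}__{outc}.tsv")

    # BH-FDR on the IVW p-values, within families (default: per exposure)
    ivw_rows = [
        (pair, res["estimates"][0])
        for pair, res in pair_results.items()
        if res["estimates"]
    ]
    families: dict = {}
    for pair, est in ivw_rows:
        fam = config.fdr_families.get(pair, pair[0])
        families.setdefault(fam, []).append((pair, est))
    qvals: dict = {}
    for fam, members in families.items():
        adj = bh_fdr([est.pval for _, est in members])
        for (pair, _), q in zip(members, adj):
            qvals[pair] = float(q)

    mr_table = _estimates_frame(pair_results)
    if len(mr_table):
        mr_table["fdr_qval"] = [
            qvals.get((r.exposure, r.outcome), np.nan) for r in mr_table.itertuples()
        ]
        mr_table.to_csv(outdir / "mr_results.tsv", sep="\t", index=False,
                        float_format="%.12g")

    sens_report = {
        f"{exp}__{outc}": res["sensitivity"] for (exp, outc), res in pair_results.items()
    }
    (outdir / "sensitivity.json").write_text(json.dumps(sens_report, indent=2))

    mediation_rows = []
    skipped = []
    for exp, med, outc in config.triples:
        step1 = pair_results.get((exp, med), {}).get("estimates") or None
        step2 = pair_results.get((med, outc), {}).get("estimates") or None
        total = pair_results.get((exp, outc), {}).get("estimates") or None
        if step1 is None or step2 is None or total is None:
            skipped.append({"triple": [exp, med, outc], "reason": "a step MR failed"})
            continue
        q1 = qvals.get((exp, med), 1.0)
        q2 = qvals.get((med, outc), 1.0)
        if q1 >= config.fdr_alpha or q2 >= config.fdr_alpha:
            skipped.append({
                "triple": [exp, med, outc],
                "reason": f"step MR not significant after FDR (q1={q1:.3g}, q2={q2:.3g})",
            })
            logger.info("skipping mediation %s -> %s -> %s: FDR gate", exp, med, outc)
            continue
        _, med_res = two_step_mr(
            tables[exp], tables[med], tables[outc],
            ld=ld_mats.get(exp), config=config, labels=(exp, med, outc),
        )
        mediation_rows.append(med_res.to_dict())
    if mediation_rows:
        pd.DataFrame(mediation_rows).to_csv(
            outdir / "mediation.tsv", sep="\t", index=False, float_format="%.12g"
        )

    run_log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config": {k: (v if not isinstance(v, dict) or all(isinstance(kk, str) for kk in v)
                       else {str(kk): vv for kk, vv in v.items()})
                   for k, v in asdict(config).items()},
        "pairs_run": [list(p) for p in pair_results],
        "mediation_skipped": skipped,
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))

    return {
        "pairs": pair_results,
        "fdr": qvals,
        "mediation": mediation_rows,
        "skipped": skipped,
        "outdir": outdir,
    }
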