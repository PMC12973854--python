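"""Orchestration of the three analysis strategies.

* ``prs_2sls`` — one-sample MR: within-cohort exposure GWAS, significance
  filter + LD clumping, joint stage-1 weights, PRS, 2SLS, tertile table.
* ``one_sample_summary`` — summary MR with exposure and outcome GWAS from
  the same cohort.
* ``two_sample_summary`` — summary MR with exposure and outcome GWAS from
  two independent cohorts.

Every run writes a ``run_meta.json`` stamped with the package version,
seed, and a hash of the configuration, and logs instrument counts at each
filtering step so the audit trail reconstructs retained + dropped = input.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import InstrumentSet
from .instruments import filter_by_pvalue, greedy_ld_clump, harmonize_instruments
from .io import (
    RunConfig,
    read_genotype_matrix,
    read_phenotypes,
    read_summary_stats,
    write_instrument_set,
    write_summary_stats,
)
from .onesample import tertile_descriptives, two_stage_ls
from .summary_mr import MrReport, mr_report
from .synthetic import gwas_summary

__all__ = ["run_pipeline", "write_report", "report_to_dict"]

logger = logging.getLogger(__name__)


def _stamp(cfg: RunConfig, out: Path, extra: Optional[dict] = None) -> None:
    payload = {
        "strategy": cfg.strategy,
        "seed": cfg.seed,
        "version": __version__,
        "files": cfg.files,
        "config_hash": hashlib.sha256(
            json.dumps(
                {"strategy": cfg.strategy, "seed": cfg.seed, "files": cfg.files,
                 "options": cfg.options},
                sort_keys=True,
            ).encode()
        ).hexdigest(),
    }
    if extra:
        payload.update(extra)
    (out / "run_meta.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def report_to_dict(report: MrReport) -> dict:
    """JSON-serializable view of a summary-MR report."""
    d = {
        "ratio_orientation": report.ratio_orientation,
        "estimates": {k: v.to_dict() for k, v in report.estimates.items()},
        "egger_intercept": {
            "value": report.egger.intercept,
            "se": report.egger.intercept_se,
            "pval": report.egger.intercept_pval,
        },
        "i2_gx": report.egger.i2_gx,
        "egger_valid": report.egger.valid,
        "outliers": report.sensitivity.outlier_snp_ids,
        "outlier_rule_applicable": report.sensitivity.outlier_rule_applicable,
        "excluded_ratios": report.ratios.excluded.to_dict(orient="records"),
    }
    if report.excluding_outliers:
        d["excluding_outliers"] = {
            k: v.to_dict() for k, v in report.excluding_outliers.items()
        }
    return d


def write_report(report: MrReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(report_to_dict(report), indent=2, sort_keys=True, default=float) + "\n"
    )
    with open(out / "estimates.jsonl", "w") as fh:
        for est in report.estimates.values():
            fh.write(json.dumps(est.to_dict(), default=float) + "\n")
    report.headline().to_csv(out / "estimates.tsv", sep="\t", index=False)
    report.forest.to_csv(out / "forest.tsv", sep="\t", index=False)
    report.sensitivity.funnel.to_csv(out / "funnel.tsv", sep="\t", index=False)
    report.sensitivity.leave_one_out.to_csv(out / "leave_one_out.tsv", sep="\t", index=False)


def _summary_strategy(cfg: RunConfig, out: Path) -> dict:
    exp_path = cfg.files.get("exposure_stats")
    outc_path = cfg.files.get("outcome_stats")
    if not exp_path or not outc_path:
        raise ValueError("summary strategies need [files] exposure_stats and outcome_stats")
    exposure, err_e = read_summary_stats(exp_path)
    outcome, err_o = read_summary_stats(outc_path)
    logger.info(
        "read %d exposure / %d outcome records (%d/%d rejected)",
        len(exposure), len(outcome), len(err_e), len(err_o),
    )
    selected = filter_by_pvalue(exposure, cfg.clump.gwas_threshold)
    logger.info(
        "significance filter p < %g: %d -> %d SNPs",
        cfg.clump.gwas_threshold, len(exposure), len(selected),
    )
    ref_path = cfg.files.get("ref_genotypes")
    if ref_path:
        ref = read_genotype_matrix(ref_path)
        clumped = greedy_ld_clump(selected, ref, cfg.clump, missing_snp="drop")
        logger.info("LD clumping: %d -> %d index SNPs", len(selected), len(clumped))
    else:
        clumped = selected
        logger.info("no reference panel supplied; clumping skipped")
    iset = harmonize_instruments(clumped, outcome)
    logger.info("harmonization: %d -> %d instruments", len(clumped), iset.k)
    write_instrument_set(iset, out / "instruments.tsv", out / "harmonization_audit.tsv")
    n_boot = int(cfg.options.get("n_boot", 1000))
    report = mr_report(iset, n_boot=n_boot, seed=cfg.seed)
    write_report(report, out)
    return {"k_instruments": iset.k, "report": report_to_dict(report)}


def _prs_strategy(cfg: RunConfig, out: Path) -> dict:
    geno_path = cfg.files.get("genotypes")
    pheno_path = cfg.files.get("phenotypes")
    if not geno_path or not pheno_path:
        raise ValueError("prs_2sls needs [files] genotypes and phenotypes")
    fmt = "vcf" if str(geno_path).endswith(".vcf") else "tsv_dosage"
    G = read_genotype_matrix(geno_path, format=fmt)
    P = read_phenotypes(pheno_path)
    exposure_col = cfg.options.get("exposure_column", "exposure_binary")
    exposure = np.asarray(getattr(P, exposure_col), dtype=float)
    outcome = np.asarray(P.outcome, dtype=float)
    if cfg.options.get("flip_outcome", "false").lower() in ("1", "true", "yes"):
        logger.info("flip_outcome: negating the outcome variable")
        outcome = -outcome

    stats = gwas_summary(G, exposure, trait_label="exposure")
    write_summary_stats(stats, out / "exposure_gwas.tsv")
    selected = filter_by_pvalue(stats, cfg.clump.gwas_threshold)
    logger.info(
        "significance filter p < %g: %d -> %d SNPs",
        cfg.clump.gwas_threshold, len(stats), len(selected),
    )
    clumped = greedy_ld_clump(selected, G, cfg.clump)
    logger.info("LD clumping: %d -> %d index SNPs", len(selected), len(clumped))
    if not clumped:
        raise ValueError("no instruments survive selection; relax gwas_threshold")
    G_sel = G.subset([s.snp_id for s in clumped])

    rounding = cfg.options.get("rounding_dp")
    rounding_dp = int(rounding) if rounding not in (None, "", "none") else None
    estimate, stage1 = two_stage_ls(
        G_sel, exposure, outcome, rounding_dp=rounding_dp
    )
    tertiles = tertile_descriptives(stage1.fitted_prs, P)
    with open(out / "estimates.jsonl", "w") as fh:
        fh.write(json.dumps(estimate.to_dict(), default=float) + "\n")
    tert_df = pd.concat(
        [tertiles.continuous.assign(kind="continuous"),
         tertiles.discrete.assign(kind="discrete")]
    )
    tert_df.to_csv(out / "tertile_table.tsv", sep="\t")
    return {
        "k_instruments": G_sel.m,
        "beta": estimate.beta,
        "ci_low": estimate.ci_low,
        "ci_high": estimate.ci_high,
        "f_statistic": stage1.f_statistic,
        "weak_instrument": stage1.weak_instrument,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute one strategy end to end; returns a result summary dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.strategy in ("one_sample_summary", "two_sample_summary"):
        result = _summary_strategy(cfg, out)
    elif cfg.strategy == "prs_2sls":
        result = _prs_strategy(cfg, out)
    else:  # pragma: no cover - guarded by RunConfig
        raise ValueError(f"unknown strategy {cfg.strategy!r}")
    _stamp(cfg, out, extra={"result_keys": sorted(result)})
    return result


def harmonize_from_iset_report(iset: InstrumentSet, out: Path, seed: int,
                               n_boot: int = 1000) -> dict:
    """Report-only entry point for a pre-harmonized instrument TSV."""
    report = mr_report(iset, n_boot=n_boot, seed=seed)
    write_report(report, out)
    return report_to_dict(report)
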