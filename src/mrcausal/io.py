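"""File formats: summary-statistic TSV, dosage TSV, minimal VCF, phenotype
CSV, instrument-set TSV, and the flat key-value run configuration.

The summary-statistic dialect is a tab-separated table with required
columns SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N (an optional TRAIT
column carries the trait label) and '.' for missing values; reading a
canonical file and writing it back is the identity.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    INSTRUMENT_COLUMNS,
    ClumpParams,
    GenotypeMatrix,
    InstrumentSet,
    PhenotypeTable,
    SnpSpec,
    SummaryStat,
)

__all__ = [
    "SUMMARY_COLUMNS",
    "read_summary_stats",
    "write_summary_stats",
    "read_genotype_matrix",
    "write_genotype_tsv",
    "write_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "read_instrument_set",
    "write_instrument_set",
    "RunConfig",
    "read_run_config",
]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]


def write_summary_stats(stats: Sequence[SummaryStat], path: str | Path) -> None:
    """Write records in the canonical tab-separated dialect."""
    rows = []
    for s in stats:
        rows.append(
            {
                "SNP": s.snp_id,
                "CHR": s.chrom,
                "POS": s.pos_bp,
                "EA": s.effect_allele,
                "OA": s.other_allele,
                "EAF": repr(s.eaf),
                "BETA": repr(s.beta),
                "SE": repr(s.se),
                "P": repr(s.pval),
                "N": s.n,
                "TRAIT": s.trait_label or ".",
                "FLAG": s.flag or ".",
            }
        )
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS + ["TRAIT", "FLAG"]).to_csv(
        path, sep="\t", index=False
    )


def read_summary_stats(
    path: str | Path, strict: bool = False
) -> tuple[list[SummaryStat], list[tuple[int, str]]]:
    """Read and validate a summary-statistics table.

    Returns (records, errors) where each error is (1-based data line
    number, reason).  A missing required column is a hard error naming the
    column and file.  With ``strict=True`` any invalid row raises instead.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    colmap = {c.upper(): c for c in df.columns}
    for col in SUMMARY_COLUMNS:
        if col not in colmap:
            raise ValueError(f"missing required column {col!r} in {path}")
    records: list[SummaryStat] = []
    errors: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        line = int(i) + 1

        def val(col: str):
            return row[colmap[col]] if col in colmap else None

        try:
            se = float(val("SE"))
            flag = str(val("FLAG")) if "FLAG" in colmap and pd.notna(val("FLAG")) else ""
            if se <= 0 and not flag:
                raise ValueError(f"SE must be positive, got {se}")
            pval = float(val("P"))
            if not (0.0 < pval <= 1.0):
                raise ValueError(f"P must be in (0, 1], got {pval}")
            eaf = float(val("EAF"))
            if not (0.0 <= eaf <= 1.0):
                raise ValueError(f"EAF must be in [0, 1], got {eaf}")
            trait = str(val("TRAIT")) if "TRAIT" in colmap and pd.notna(val("TRAIT")) else ""
            records.append(
                SummaryStat(
                    snp_id=str(val("SNP")),
                    chrom=str(val("CHR")),
                    pos_bp=int(val("POS")),
                    effect_allele=str(val("EA")),
                    other_allele=str(val("OA")),
                    eaf=eaf,
                    beta=float(val("BETA")),
                    se=se,
                    pval=pval,
                    n=int(val("N")),
                    trait_label=trait,
                    flag=flag,
                )
            )
        except (TypeError, ValueError) as exc:
            if strict:
                raise ValueError(f"{path} line {line}: {exc}") from exc
            errors.append((line, str(exc)))
    if errors:
        logger.warning("%s: rejected %d invalid rows", path, len(errors))
    return records, errors


def write_genotype_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    """Dosage TSV: SAMPLE_ID column then one integer column per SNP ('.' missing)."""
    df = G.to_dataframe()
    out = df.map(lambda v: "." if np.isnan(v) else str(int(v)))
    out.insert(0, "SAMPLE_ID", G.sample_ids)
    out.to_csv(path, sep="\t", index=False)


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF v4.2 with unphased GT only; ALT is the effect allele."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in G.panel):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.sample_ids) + "\n")
        order = sorted(range(G.m), key=lambda j: (G.panel[j].chrom, G.panel[j].pos_bp))
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in order:
            spec = G.panel[j]
            gts = [
                "./." if np.isnan(d) else gt_map[d] for d in G.dosages[:, j]
            ]
            fh.write(
                f"{spec.chrom}\t{spec.pos_bp}\t{spec.snp_id}\t{spec.other_allele}\t"
                f"{spec.effect_allele}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    panel: list[SnpSpec] = []
    cols: list[np.ndarray] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(var.gt_types, dtype=float)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        eaf = float(np.nanmean(dos) / 2.0) if np.isfinite(dos).any() else 0.25
        panel.append(
            SnpSpec(
                snp_id=var.ID or f"{var.CHROM}:{var.POS}",
                chrom=str(var.CHROM),
                pos_bp=int(var.POS),
                effect_allele=str(var.ALT[0]),
                other_allele=str(var.REF),
                maf=min(max(eaf, 1e-6), 0.5) if eaf <= 0.5 else min(1.0 - eaf + 1e-6, 0.5),
            )
        )
        cols.append(dos)
    if n_multi:
        logger.warning("skipped %d multi-allelic VCF records", n_multi)
    dosages = np.column_stack(cols) if cols else np.zeros((len(samples), 0))
    return GenotypeMatrix(sample_ids=samples, panel=panel, dosages=dosages)


def read_genotype_matrix(
    path: str | Path,
    format: str = "tsv_dosage",
    panel: Optional[Sequence[SnpSpec]] = None,
) -> GenotypeMatrix:
    """Read dosages from a dosage TSV or a VCF (GT field, ALT = effect allele).

    For the TSV format, per-variant metadata is taken from ``panel`` when
    supplied (matched by snp_id) and filled with neutral placeholders
    otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "vcf":
        return _read_vcf(path)
    if format != "tsv_dosage":
        raise ValueError(f"unknown genotype format {format!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    if "SAMPLE_ID" not in df.columns:
        raise ValueError(f"dosage TSV {path} missing SAMPLE_ID column")
    sample_ids = df["SAMPLE_ID"].astype(str).tolist()
    snp_ids = [c for c in df.columns if c != "SAMPLE_ID"]
    raw = df[snp_ids]
    bad = raw.stack().dropna().loc[lambda s: ~s.isin(["0", "1", "2"])]
    if len(bad):
        raise ValueError(f"non-integer dosage values in {path}: {sorted(set(bad))[:5]}")
    dosages = raw.astype(float).to_numpy()
    by_id = {s.snp_id: s for s in panel} if panel else {}
    specs = []
    for j, sid in enumerate(snp_ids):
        if sid in by_id:
            specs.append(by_id[sid])
        else:
            col = dosages[:, j]
            eaf = float(np.nanmean(col) / 2.0) if np.isfinite(col).any() else 0.25
            maf = eaf if eaf <= 0.5 else 1.0 - eaf
            specs.append(
                SnpSpec(sid, chrom="0", pos_bp=j + 1, effect_allele="A",
                        other_allele="G", maf=float(min(max(maf, 1e-6), 0.5)))
            )
    return GenotypeMatrix(sample_ids=sample_ids, panel=specs, dosages=dosages)


def write_phenotypes(P: PhenotypeTable, path: str | Path) -> None:
    P.to_dataframe().to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path)
    required = ["SAMPLE_ID", "EXPOSURE", "OUTCOME", "AGE", "SEX", "EDU"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"phenotype CSV {path} missing column {col!r}")
    liability = df["LIABILITY"] if "LIABILITY" in df.columns else pd.Series(
        np.full(len(df), np.nan)
    )
    return PhenotypeTable(
        sample_ids=df["SAMPLE_ID"].astype(str).tolist(),
        exposure_binary=df["EXPOSURE"].to_numpy(),
        exposure_liability=liability.to_numpy(dtype=float),
        outcome=df["OUTCOME"].to_numpy(dtype=float),
        age=df["AGE"].to_numpy(dtype=float),
        sex=df["SEX"].to_numpy(),
        education=df["EDU"].to_numpy(),
    )


def write_instrument_set(iset: InstrumentSet, path: str | Path,
                         audit_path: Optional[str | Path] = None) -> None:
    iset.table.to_csv(path, sep="\t", index=False)
    if audit_path is not None:
        iset.audit.to_csv(audit_path, sep="\t", index=False)


def read_instrument_set(path: str | Path) -> InstrumentSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in INSTRUMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"instrument TSV {path} missing columns: {missing}")
    return InstrumentSet(table=df[INSTRUMENT_COLUMNS])


@dataclass
class RunConfig:
    """A pipeline run: strategy, inputs, thresholds, estimator options."""

    strategy: str
    seed: int
    out_dir: str
    files: dict
    clump: ClumpParams
    options: dict

    VALID_STRATEGIES = ("prs_2sls", "one_sample_summary", "two_sample_summary")

    def __post_init__(self) -> None:
        if self.strategy not in self.VALID_STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")


def read_run_config(path: str | Path) -> RunConfig:
    """Parse the flat sectioned key-value configuration file.

    Sections: [run] (strategy, seed, out_dir), [files] (stage inputs),
    [clump] (ClumpParams overrides), [options] (estimator options).
    Referenced files must exist.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    cp = configparser.ConfigParser()
    cp.read(path)
    if "run" not in cp:
        raise ValueError(f"config {path} missing [run] section")
    run = cp["run"]
    files = dict(cp["files"]) if "files" in cp else {}
    for key, fpath in files.items():
        if not Path(fpath).exists():
            raise FileNotFoundError(f"config {path}: [files] {key} -> {fpath} does not exist")
    clump_kwargs = {}
    if "clump" in cp:
        for key in ("window_kb",):
            if key in cp["clump"]:
                clump_kwargs[key] = cp["clump"].getint(key)
        for key in ("r2_threshold", "p_index", "p_secondary", "gwas_threshold"):
            if key in cp["clump"]:
                clump_kwargs[key] = cp["clump"].getfloat(key)
    options = dict(cp["options"]) if "options" in cp else {}
    return RunConfig(
        strategy=run.get("strategy", "two_sample_summary"),
        seed=run.getint("seed", 0),
        out_dir=run.get("out_dir", "mr_out"),
        files=files,
        clump=ClumpParams(**clump_kwargs),
        options=options,
    )
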