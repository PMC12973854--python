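"""Instrument selection: significance filtering, PLINK-style greedy LD
clumping against a reference dosage panel, and allele harmonization of
exposure against outcome summary statistics.
"""

from __future__ import annotations

import logging
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    INSTRUMENT_COLUMNS,
    ClumpParams,
    GenotypeMatrix,
    InstrumentSet,
    SummaryStat,
)

__all__ = [
    "filter_by_pvalue",
    "pairwise_r2",
    "greedy_ld_clump",
    "harmonize_instruments",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def filter_by_pvalue(stats: Sequence[SummaryStat], threshold: float) -> list[SummaryStat]:
    """Keep records with p strictly below ``threshold``; order preserved."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    return [s for s in stats if s.pval < threshold]


def pairwise_r2(G: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of two dosage columns.

    Computed over pairwise-complete individuals.  A constant column makes
    r^2 undefined; NaN is returned (clumping treats it as 0) and the case
    is logged.
    """
    a = G.column(snp_a)
    b = G.column(snp_b)
    keep = ~(np.isnan(a) | np.isnan(b))
    if keep.sum() < 2:
        raise ValueError(f"fewer than 2 pairwise-complete individuals for {snp_a}, {snp_b}")
    a, b = a[keep], b[keep]
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        logger.warning("r2(%s, %s) undefined: constant dosage column", snp_a, snp_b)
        return float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def greedy_ld_clump(
    stats: Sequence[SummaryStat],
    ref: GenotypeMatrix,
    params: Optional[ClumpParams] = None,
    missing_snp: Literal["error", "drop"] = "error",
) -> list[SummaryStat]:
    """PLINK-style greedy clumping; returns index SNPs in genomic order.

    Candidates are the records with p < ``p_index``, visited in ascending
    p (ties by position then snp_id).  Each visit retains the best
    remaining SNP and removes every other candidate with p <
    ``p_secondary`` on the same chromosome within +/- ``window_kb``
    (endpoints inclusive) whose dosage r^2 with the index reaches
    ``r2_threshold``.  Undefined r^2 (constant column) never clumps.
    """
    params = params or ClumpParams()
    records = list(stats)
    in_ref = set(ref.snp_ids)
    absent = [s.snp_id for s in records if s.snp_id not in in_ref]
    if absent:
        if missing_snp == "error":
            raise KeyError(f"SNPs absent from reference panel: {absent}")
        records = [s for s in records if s.snp_id in in_ref]
        logger.warning("dropped %d SNPs absent from reference panel", len(absent))

    candidates = [s for s in records if s.pval < params.p_index]
    order = sorted(candidates, key=lambda s: (s.pval, s.pos_bp, s.snp_id))
    remaining = {s.snp_id: s for s in order}
    retained: list[SummaryStat] = []
    window_bp = params.window_kb * 1000
    for s in order:
        if s.snp_id not in remaining:
            continue
        retained.append(s)
        del remaining[s.snp_id]
        for other_id in list(remaining):
            o = remaining[other_id]
            if o.chrom != s.chrom or abs(o.pos_bp - s.pos_bp) > window_bp:
                continue
            if o.pval >= params.p_secondary:
                continue
            r2 = pairwise_r2(ref, s.snp_id, o.snp_id)
            if np.isnan(r2):
                continue
            if r2 >= params.r2_threshold:
                del remaining[other_id]
    retained.sort(key=lambda s: (s.chrom, s.pos_bp, s.snp_id))
    return retained


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def harmonize_instruments(
    exposure_stats: Sequence[SummaryStat],
    outcome_stats: Sequence[SummaryStat],
    palindrome_policy: Literal["drop_intermediate", "drop_all", "keep"] = "drop_intermediate",
    ambiguity_band: tuple[float, float] = (0.42, 0.58),
) -> InstrumentSet:
    """Align outcome records to the exposure's coded alleles.

    For each SNP present in both inputs the outcome record is matched to
    the exposure's effect/other alleles directly, by swapping (beta sign
    flipped, EAF complemented), by strand complementation (A<->T, C<->G),
    or by both.  Palindromic SNPs (A/T or G/C) cannot be resolved by
    strand, so under the default policy they are aligned by allele
    frequency and dropped when the outcome EAF is inside the ambiguity
    band; ``drop_all`` removes them unconditionally and ``keep`` trusts
    the allele labels as written.  Every decision lands in the audit
    table.
    """
    for name, group in (("exposure", exposure_stats), ("outcome", outcome_stats)):
        ids = [s.snp_id for s in group]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate snp_id in {name} stats: {dupes}")
    outcome_by_id = {s.snp_id: s for s in outcome_stats}
    if not set(s.snp_id for s in exposure_stats) & set(outcome_by_id):
        raise ValueError("no snp_id overlap between exposure and outcome stats")

    rows: list[dict] = []
    audit: list[dict] = []

    def drop(snp_id: str, reason: str) -> None:
        audit.append({"snp_id": snp_id, "action": "dropped", "reason": reason})

    for exp in exposure_stats:
        out = outcome_by_id.get(exp.snp_id)
        if out is None:
            drop(exp.snp_id, "missing_in_outcome")
            continue
        if exp.degenerate or out.degenerate:
            drop(exp.snp_id, "degenerate_association")
            continue
        if exp.se <= 0 or out.se <= 0:
            drop(exp.snp_id, "nonpositive_se")
            continue

        ea_e, oa_e = exp.effect_allele, exp.other_allele
        flipped = strand = False
        aligned = None
        if _is_palindromic(ea_e, oa_e):
            if palindrome_policy == "drop_all":
                drop(exp.snp_id, "palindromic")
                continue
            if {out.effect_allele, out.other_allele} != {ea_e, oa_e}:
                drop(exp.snp_id, "allele_mismatch")
                continue
            if palindrome_policy == "keep":
                flipped = out.effect_allele != ea_e
                aligned = out.flipped() if flipped else out
            else:  # drop_intermediate: align by frequency, drop ambiguous
                lo, hi = ambiguity_band
                if lo <= out.eaf <= hi or lo <= exp.eaf <= hi:
                    drop(exp.snp_id, "palindromic_ambiguous")
                    continue
                same_orientation = (exp.eaf - 0.5) * (out.eaf - 0.5) > 0
                flipped = not same_orientation
                aligned = out.flipped() if flipped else out
                if aligned.effect_allele != ea_e:
                    # frequency orientation disagrees with labels: relabel
                    # onto the exposure's strand, flag as strand swap
                    strand = True
        else:
            out_ea, out_oa = out.effect_allele, out.other_allele
            if (out_ea, out_oa) == (ea_e, oa_e):
                aligned = out
            elif (out_ea, out_oa) == (oa_e, ea_e):
                flipped, aligned = True, out.flipped()
            elif (_COMPLEMENT.get(out_ea), _COMPLEMENT.get(out_oa)) == (ea_e, oa_e):
                strand, aligned = True, out
            elif (_COMPLEMENT.get(out_ea), _COMPLEMENT.get(out_oa)) == (oa_e, ea_e):
                strand, flipped, aligned = True, True, out.flipped()
            else:
                drop(exp.snp_id, "allele_mismatch")
                continue

        rows.append(
            {
                "snp_id": exp.snp_id,
                "effect_allele": ea_e,
                "other_allele": oa_e,
                "gamma": exp.beta,
                "se_gamma": exp.se,
                "big_gamma": aligned.beta,
                "se_big_gamma": aligned.se,
                "eaf_exposure": exp.eaf,
                "eaf_outcome": aligned.eaf,
                "flipped": flipped,
                "strand_swapped": strand,
            }
        )
        action = "kept"
        if flipped and strand:
            action = "strand_flipped"
        elif flipped:
            action = "flipped"
        elif strand:
            action = "strand"
        audit.append({"snp_id": exp.snp_id, "action": action, "reason": ""})

    table = pd.DataFrame(rows, columns=INSTRUMENT_COLUMNS)
    return InstrumentSet(table=table, audit=pd.DataFrame(audit, columns=["snp_id", "action", "reason"]))
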