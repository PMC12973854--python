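"""Seeded cohort simulator: LD-structured genotypes, a liability-threshold
binary exposure, a bounded continuous outcome, and single-variant GWAS
summary statistics.

The generator provides everything the MR pipeline consumes without any
external data: biallelic dosages with tunable within-block linkage
disequilibrium, a migraine-like binary exposure driven by many small
per-allele effects on a standard-normal liability, an MMSE-like outcome
with a configurable causal effect of the exposure liability, optional
confounding, and optional horizontal pleiotropy (direct SNP-to-outcome
effects).  Every function is a pure function of its inputs and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CohortConfig, GenotypeMatrix, PhenotypeTable, SnpSpec, SummaryStat

__all__ = [
    "simulate_genotypes",
    "add_missingness",
    "simulate_phenotypes",
    "simulate_cohort",
    "gwas_summary",
    "simulate_two_sample_study",
    "TwoSampleTruth",
    "study_like_panel",
    "apply_pleiotropy",
]


def simulate_genotypes(
    panel: Sequence[SnpSpec], n: int, rho: float, seed: int
) -> GenotypeMatrix:
    """Draw ``n`` individuals' dosages for ``panel``.

    Each genotype is the sum of two independent haplotypes.  Within an
    ``ld_block``, haplotype alleles come from a latent equicorrelated
    Gaussian (pairwise correlation ``rho``) thresholded at the MAF
    quantile, which preserves Hardy-Weinberg proportions per SNP while
    inducing positive pairwise r^2; blocks are mutually independent.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("panel must be nonempty")
    if n < 0:
        raise ValueError("n must be >= 0")
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must be in [0, 1)")
    ids = [s.snp_id for s in panel]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate snp_id in panel: {dupes}")

    rng = np.random.default_rng(seed)
    m = len(panel)
    dosages = np.zeros((n, m))
    # group columns by block, preserving panel order within each block
    blocks: dict[int, list[int]] = {}
    for j, spec in enumerate(panel):
        blocks.setdefault(spec.ld_block, []).append(j)
    # singleton blocks have no within-block correlation; batch their draws
    singles = [cols[0] for cols in blocks.values() if len(cols) == 1]
    multis = [cols for cols in blocks.values() if len(cols) > 1]
    if singles:
        thresholds = stats.norm.ppf([panel[j].maf for j in singles])
        for _hap in range(2):
            z = rng.standard_normal((n, len(singles)))
            dosages[:, singles] += z < thresholds
    for block_cols in multis:
        thresholds = stats.norm.ppf([panel[j].maf for j in block_cols])
        b = len(block_cols)
        for _hap in range(2):
            z_common = rng.standard_normal((n, 1))
            z_indiv = rng.standard_normal((n, b))
            z = math.sqrt(rho) * z_common + math.sqrt(1.0 - rho) * z_indiv
            dosages[:, block_cols] += z < thresholds
    return GenotypeMatrix(
        sample_ids=[f"S{i:06d}" for i in range(n)], panel=panel, dosages=dosages
    )


def add_missingness(G: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set dosages to missing completely at random at the given rate."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    dos = G.dosages.copy()
    dos[rng.random(dos.shape) < rate] = np.nan
    return GenotypeMatrix(list(G.sample_ids), list(G.panel), dos)


def _imputed(dosages: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per SNP (columns all-missing become 0)."""
    if not np.isnan(dosages).any():
        return dosages
    col_mean = np.nanmean(np.where(np.isnan(dosages).all(axis=0), 0.0, dosages), axis=0)
    col_mean = np.nan_to_num(col_mean)
    return np.where(np.isnan(dosages), col_mean, dosages)


def simulate_phenotypes(
    G: GenotypeMatrix, cfg: CohortConfig, rng: Optional[np.random.Generator] = None
) -> PhenotypeTable:
    """Generate exposure and outcome for the individuals in ``G``.

    Liability: ``L = sum_j gamma_j (G_j - 2 maf_j) + c_x C + eps``, with the
    residual scaled so the empirical variance of L is 1.  The binary
    exposure thresholds L at the ``1 - prevalence_k`` normal quantile.
    Outcome: ``Y = mu0 + causal_beta L + sum_j alpha_j G_j + c_y C + noise``,
    optionally clipped to the score bounds and rounded to integers.
    """
    if G.n == 0:
        raise ValueError("cohort is empty")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    dos = _imputed(G.dosages)
    gamma = np.array([s.gamma_true for s in G.panel])
    alpha = np.array([s.alpha_true for s in G.panel])
    maf = np.array([s.maf for s in G.panel])

    genetic = (dos - 2.0 * maf) @ gamma
    confounder = rng.normal(0.0, cfg.confounder_sd, G.n)
    systematic = genetic + cfg.confounder_effect_x * confounder
    var_sys = float(systematic.var())
    if var_sys >= 1.0:
        raise ValueError(
            f"systematic liability variance {var_sys:.3f} >= 1; "
            "reduce gamma_true or the confounder effect"
        )
    liability = systematic + rng.normal(0.0, math.sqrt(1.0 - var_sys), G.n)
    threshold = stats.norm.ppf(1.0 - cfg.prevalence_k)
    exposure = (liability > threshold).astype(int)

    outcome = (
        cfg.mu0
        + cfg.causal_beta * liability
        + dos @ alpha
        + cfg.confounder_effect_y * confounder
        + rng.normal(0.0, cfg.noise_sd_y, G.n)
    )
    if cfg.clip_outcome:
        outcome = np.clip(outcome, cfg.outcome_floor, cfg.outcome_ceiling)
    if cfg.round_outcome:
        outcome = np.rint(outcome)

    age = np.clip(rng.normal(50.0, 11.0, G.n), 20.0, 70.0)
    sex = rng.integers(0, 2, G.n)
    education = rng.integers(1, 8, G.n)  # ordinal schooling bands
    return PhenotypeTable(
        sample_ids=list(G.sample_ids),
        exposure_binary=exposure,
        exposure_liability=liability,
        outcome=outcome,
        age=age,
        sex=sex,
        education=education,
    )


def simulate_cohort(
    panel: Sequence[SnpSpec], cfg: CohortConfig
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Genotypes and phenotypes for one cohort from a single seed.

    Two independent child streams are spawned from ``cfg.seed`` so the
    genotype and phenotype draws never share random state.
    """
    ss = np.random.SeedSequence(cfg.seed)
    geno_ss, pheno_ss = ss.spawn(2)
    G = simulate_genotypes(
        panel, cfg.n_individuals, cfg.within_block_rho, seed=geno_ss
    )
    if cfg.missing_rate > 0:
        miss_ss = ss.spawn(1)[0]
        G = add_missingness(G, cfg.missing_rate, seed=miss_ss)
    P = simulate_phenotypes(G, cfg, rng=np.random.default_rng(pheno_ss))
    return G, P


def _linear_single_snp(
    g: np.ndarray, y: np.ndarray, X_cov: Optional[np.ndarray]
) -> tuple[float, float, str]:
    """OLS slope and SE of y on one dosage column (plus covariates)."""
    if X_cov is None:
        n = len(g)
        gc = g - g.mean()
        sxx = float(gc @ gc)
        beta = float(gc @ (y - y.mean())) / sxx
        resid = (y - y.mean()) - beta * gc
        rss = float(resid @ resid)
        if rss <= 1e-12 * max(1.0, float(y.var()) * n):
            return beta, math.sqrt(max(rss, 1e-300) / (n - 2) / sxx), "perfect_fit"
        se = math.sqrt(rss / (n - 2) / sxx)
        return beta, se, ""
    X = np.column_stack([np.ones(len(g)), g, X_cov])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(g) - X.shape[1]
    rss = float(resid @ resid)
    xtx_inv = np.linalg.pinv(X.T @ X)
    if rss <= 1e-12 * max(1.0, float(y.var()) * len(g)):
        return float(coef[1]), math.sqrt(max(rss, 1e-300) / max(dof, 1) * xtx_inv[1, 1]), "perfect_fit"
    se = math.sqrt(rss / dof * xtx_inv[1, 1])
    return float(coef[1]), se, ""


def gwas_summary(
    G: GenotypeMatrix,
    trait: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    family: Literal["linear", "logistic"] = "linear",
    trait_label: str = "",
) -> list[SummaryStat]:
    """Single-SNP regressions of ``trait`` on each dosage column.

    Returns one :class:`SummaryStat` per SNP with beta, SE and a two-sided
    normal p-value.  Missing dosages are dropped casewise per SNP; the
    effect-allele frequency is computed from non-missing dosages.
    Monomorphic columns and perfect fits are flagged rather than dropped,
    so the selection stage can audit them.
    """
    trait = np.asarray(trait, dtype=float)
    if trait.shape[0] != G.n:
        raise ValueError(f"trait length {trait.shape[0]} != {G.n} individuals")
    if family not in ("linear", "logistic"):
        raise ValueError(f"unknown family {family!r}")
    X_cov = None
    if covariates is not None:
        X_cov = np.asarray(covariates, dtype=float)

    has_missing = np.isnan(G.dosages).any()
    out: list[SummaryStat] = []

    # vectorised fast path: linear, no covariates, no missing data
    if family == "linear" and X_cov is None and not has_missing:
        n = G.n
        dos = G.dosages
        gc = dos - dos.mean(axis=0)
        yc = trait - trait.mean()
        sxx = (gc * gc).sum(axis=0)
        mono = sxx <= 0
        sxx_safe = np.where(mono, 1.0, sxx)
        beta = (gc.T @ yc) / sxx_safe
        rss = float(yc @ yc) - beta**2 * sxx_safe
        rss = np.maximum(rss, 0.0)
        perfect = rss <= 1e-12 * max(1.0, float(trait.var()) * n)
        se = np.sqrt(np.maximum(rss, 1e-300) / (n - 2) / sxx_safe)
        z = np.where(se > 0, beta / se, np.inf)
        pval = 2.0 * stats.norm.sf(np.abs(z))
        eaf = dos.mean(axis=0) / 2.0
        for j, spec in enumerate(G.panel):
            flag = "monomorphic" if mono[j] else ("perfect_fit" if perfect[j] else "")
            out.append(
                SummaryStat(
                    snp_id=spec.snp_id,
                    chrom=spec.chrom,
                    pos_bp=spec.pos_bp,
                    effect_allele=spec.effect_allele,
                    other_allele=spec.other_allele,
                    eaf=float(eaf[j]),
                    beta=0.0 if mono[j] else float(beta[j]),
                    se=0.0 if mono[j] else float(se[j]),
                    pval=1.0 if mono[j] else float(max(pval[j], 5e-324)),
                    n=n,
                    trait_label=trait_label,
                    flag=flag,
                )
            )
        return out

    import statsmodels.api as sm

    for j, spec in enumerate(G.panel):
        g = G.dosages[:, j]
        keep = ~np.isnan(g)
        g_j, y_j = g[keep], trait[keep]
        cov_j = X_cov[keep] if X_cov is not None else None
        n_j = int(keep.sum())
        eaf = float(g_j.mean() / 2.0) if n_j else float("nan")
        if n_j < 3 or np.ptp(g_j) == 0:
            out.append(
                SummaryStat(
                    spec.snp_id, spec.chrom, spec.pos_bp, spec.effect_allele,
                    spec.other_allele, eaf, 0.0, 0.0, 1.0, n_j, trait_label,
                    flag="monomorphic",
                )
            )
            continue
        if family == "linear":
            beta, se, flag = _linear_single_snp(g_j, y_j, cov_j)
        else:
            X = np.column_stack([np.ones(n_j), g_j]) if cov_j is None else np.column_stack(
                [np.ones(n_j), g_j, cov_j]
            )
            try:
                fit = sm.Logit(y_j, X).fit(disp=0, maxiter=100)
                converged = bool(fit.mle_retvals.get("converged", True))
                beta, se = float(fit.params[1]), float(fit.bse[1])
                flag = "" if converged and np.isfinite(se) else "nonconverged"
            except Exception:
                beta, se, flag = 0.0, 0.0, "nonconverged"
        if flag or se <= 0 or not np.isfinite(se):
            pval = 1.0 if flag in ("monomorphic", "nonconverged") else 0.0
        else:
            pval = float(max(2.0 * stats.norm.sf(abs(beta / se)), 5e-324))
        out.append(
            SummaryStat(
                spec.snp_id, spec.chrom, spec.pos_bp, spec.effect_allele,
                spec.other_allele, eaf, beta, se, pval, n_j, trait_label, flag=flag,
            )
        )
    return out


@dataclass
class TwoSampleTruth:
    """Generating parameters retained for estimator-recovery tests."""

    causal_beta: float
    gamma_true: dict[str, float]
    alpha_true: dict[str, float]


def simulate_two_sample_study(
    panel: Sequence[SnpSpec],
    cfg_exposure_cohort: CohortConfig,
    cfg_outcome_cohort: CohortConfig,
    exposure_scale: Literal["liability", "binary"] = "liability",
) -> tuple[list[SummaryStat], list[SummaryStat], TwoSampleTruth]:
    """Two independent cohorts; exposure GWAS in A, outcome GWAS in B.

    With ``exposure_scale='liability'`` the per-SNP Wald ratio estimand is
    exactly ``causal_beta`` in the no-pleiotropy limit.  The binary scale
    reproduces the attenuation a case-control exposure GWAS induces (all
    gammas shrink by a common liability-to-probability factor, inflating
    the ratio by its inverse).
    """
    if cfg_exposure_cohort.seed == cfg_outcome_cohort.seed:
        raise ValueError(
            "exposure and outcome cohorts share a seed; two-sample MR requires "
            "independent cohorts"
        )
    if cfg_exposure_cohort.causal_beta != cfg_outcome_cohort.causal_beta:
        raise ValueError("both cohort configs must share causal_beta")
    G_a, P_a = simulate_cohort(panel, cfg_exposure_cohort)
    G_b, P_b = simulate_cohort(panel, cfg_outcome_cohort)
    trait_a = (
        P_a.exposure_liability if exposure_scale == "liability" else P_a.exposure_binary
    )
    exposure_stats = gwas_summary(G_a, trait_a, trait_label="exposure")
    outcome_stats = gwas_summary(G_b, P_b.outcome, trait_label="outcome")
    truth = TwoSampleTruth(
        causal_beta=cfg_exposure_cohort.causal_beta,
        gamma_true={s.snp_id: s.gamma_true for s in panel},
        alpha_true={s.snp_id: s.alpha_true for s in panel},
    )
    return exposure_stats, outcome_stats, truth


_BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def study_like_panel(
    k: int = 18,
    seed: int = 0,
    gamma_range: tuple[float, float] = (0.05, 0.15),
    maf_range: tuple[float, float] = (0.1, 0.5),
    snps_per_block: int = 1,
) -> list[SnpSpec]:
    """A panel of ``k`` independent small-effect instruments.

    Mirrors the study conditions: 18 variants each contributing a small
    effect (0.05-0.15 liability SD per allele) to a polygenic binary
    exposure.  With ``snps_per_block > 1`` extra correlated neighbours are
    added to each block, giving the clumping stage LD to act on.
    """
    rng = np.random.default_rng(seed)
    panel: list[SnpSpec] = []
    pos = 1_000_000
    for b in range(k):
        chrom = str(b % 22 + 1)
        for s in range(snps_per_block):
            ea, oa = rng.choice(_BASES, size=2, replace=False)
            # avoid palindromic pairs so harmonization keeps every SNP
            while _COMPLEMENT[ea] == oa:
                ea, oa = rng.choice(_BASES, size=2, replace=False)
            panel.append(
                SnpSpec(
                    snp_id=f"rs{b + 1:04d}{s:02d}",
                    chrom=chrom,
                    pos_bp=pos + s * 25_000,
                    effect_allele=str(ea),
                    other_allele=str(oa),
                    maf=float(rng.uniform(*maf_range)),
                    ld_block=b,
                    gamma_true=float(rng.uniform(*gamma_range)) if s == 0 else 0.0,
                    alpha_true=0.0,
                )
            )
        pos += 5_000_000
    return panel


def apply_pleiotropy(
    panel: Sequence[SnpSpec],
    preset: Literal["none", "balanced", "directional"],
    fraction: float = 0.3,
    mean: float = 0.05,
    sd: float = 0.01,
    seed: int = 0,
) -> list[SnpSpec]:
    """Return a copy of ``panel`` with direct SNP-to-outcome effects planted.

    ``balanced`` draws alpha ~ Normal(0, sd) (pleiotropy averages out;
    the Egger intercept stays near zero); ``directional`` draws
    alpha ~ Normal(mean, sd) (systematic bias; the Egger intercept
    estimates the average planted effect).  Effects are applied to a
    ``fraction`` of SNPs chosen at random.
    """
    if preset == "none":
        return [replace(s, alpha_true=0.0) for s in panel]
    if preset not in ("balanced", "directional"):
        raise ValueError(f"unknown pleiotropy preset {preset!r}")
    rng = np.random.default_rng(seed)
    n_invalid = int(round(fraction * len(panel)))
    invalid = set(rng.choice(len(panel), size=n_invalid, replace=False).tolist())
    mu = 0.0 if preset == "balanced" else mean
    out = []
    for i, s in enumerate(panel):
        alpha = float(rng.normal(mu, sd)) if i in invalid else 0.0
        out.append(replace(s, alpha_true=alpha))
    return out
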