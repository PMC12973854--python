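"""Core containers shared across the pipeline.

The analysis moves between three representations of genetic association
data: individual-level dosages (:class:`GenotypeMatrix` with a
:class:`PhenotypeTable`), per-variant summary statistics
(:class:`SummaryStat`), and harmonized instrument sets
(:class:`InstrumentSet`) feeding the summary MR estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpSpec",
    "CohortConfig",
    "GenotypeMatrix",
    "PhenotypeTable",
    "SummaryStat",
    "InstrumentSet",
    "MrEstimate",
    "ClumpParams",
]


@dataclass(frozen=True)
class SnpSpec:
    """A biallelic variant and its true per-allele effects.

    ``gamma_true`` acts on the latent exposure liability (liability SD
    units per effect allele); ``alpha_true`` is a direct effect on the
    outcome, i.e. horizontal pleiotropy bypassing the exposure.
    ``ld_block`` labels the equicorrelated haplotype block the variant
    belongs to; variants in distinct blocks are generated independently.
    """

    snp_id: str
    chrom: str
    pos_bp: int
    effect_allele: str
    other_allele: str
    maf: float
    ld_block: int = 0
    gamma_true: float = 0.0
    alpha_true: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf must be in (0, 0.5], got {self.maf}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if self.pos_bp < 1:
            raise ValueError(f"{self.snp_id}: pos_bp must be >= 1")


@dataclass
class CohortConfig:
    """Parameters of one simulated cohort.

    ``prevalence_k`` is the population prevalence of the binary exposure
    under the liability-threshold model.  ``causal_beta`` is the effect of
    one liability SD of exposure on the outcome (outcome units).  The
    outcome is bounded like an MMSE score (0 worst to 30 best); clipping
    and integer rounding are off by default because they break the exact
    linear identities the estimators rely on, and can be switched on for
    realism.
    """

    n_individuals: int = 20_000
    prevalence_k: float = 0.15
    causal_beta: float = 2.4
    confounder_sd: float = 1.0
    confounder_effect_x: float = 0.0
    confounder_effect_y: float = 0.0
    noise_sd_y: float = 3.0
    within_block_rho: float = 0.0
    outcome_floor: float = 0.0
    outcome_ceiling: float = 30.0
    outcome_mean: Optional[float] = None
    clip_outcome: bool = False
    round_outcome: bool = False
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.outcome_floor < self.outcome_ceiling:
            raise ValueError("outcome_floor must be < outcome_ceiling")
        if not (0.0 < self.prevalence_k < 1.0):
            raise ValueError("prevalence_k must be in (0, 1)")
        if not (0.0 <= self.within_block_rho < 1.0):
            raise ValueError("within_block_rho must be in [0, 1)")
        if self.noise_sd_y < 0:
            raise ValueError("noise_sd_y must be >= 0")

    @property
    def mu0(self) -> float:
        """Outcome intercept; defaults near the top of the scale (27 on 0-30)."""
        if self.outcome_mean is not None:
            return self.outcome_mean
        return self.outcome_floor + 0.9 * (self.outcome_ceiling - self.outcome_floor)


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage table (effect-allele counts).

    ``dosages`` is an ``(n, m)`` float array with values in {0, 1, 2} or
    NaN for missing.  Column order matches ``panel``.
    """

    sample_ids: list[str]
    panel: list[SnpSpec]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape if self.dosages.ndim == 2 else (len(self.dosages), 0)
        if n != len(self.sample_ids) or m != len(self.panel):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.panel)} variants"
            )
        ids = [s.snp_id for s in self.panel]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in panel")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def m(self) -> int:
        return len(self.panel)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.panel]

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_ids.index(snp_id)]

    def subset(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            panel=[self.panel[i] for i in idx],
            dosages=self.dosages[:, idx].copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.snp_ids)


@dataclass
class PhenotypeTable:
    """Per-individual exposure, outcome and covariates.

    The latent ``exposure_liability`` used to generate the binary trait is
    retained: it is the scale on which ``causal_beta`` acts, so estimator
    recovery checks regress on it rather than the thresholded indicator.
    """

    sample_ids: list[str]
    exposure_binary: np.ndarray
    exposure_liability: np.ndarray
    outcome: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    education: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for name in ("exposure_binary", "exposure_liability", "outcome", "age", "sex", "education"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != {n} samples")
            setattr(self, name, arr)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SAMPLE_ID": self.sample_ids,
                "EXPOSURE": self.exposure_binary,
                "LIABILITY": self.exposure_liability,
                "OUTCOME": self.outcome,
                "AGE": self.age,
                "SEX": self.sex,
                "EDU": self.education,
            }
        )


@dataclass
class SummaryStat:
    """One variant's association with a trait.

    ``flag`` is empty for a clean record; non-empty values
    (``monomorphic``, ``perfect_fit``, ``nonconverged``) mark degenerate
    fits that downstream stages exclude.
    """

    snp_id: str
    chrom: str
    pos_bp: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int
    trait_label: str = ""
    flag: str = ""

    @property
    def degenerate(self) -> bool:
        return self.flag != ""

    def flipped(self) -> "SummaryStat":
        """The same association expressed on the opposite coded allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=-self.beta,
        )


#: canonical column order of the harmonized-instrument table
INSTRUMENT_COLUMNS = [
    "snp_id",
    "effect_allele",
    "other_allele",
    "gamma",
    "se_gamma",
    "big_gamma",
    "se_big_gamma",
    "eaf_exposure",
    "eaf_outcome",
    "flipped",
    "strand_swapped",
]


@dataclass
class InstrumentSet:
    """Harmonized per-SNP exposure (gamma) and outcome (Gamma) associations.

    ``table`` has one row per retained instrument with columns
    ``INSTRUMENT_COLUMNS``; ``audit`` records every input SNP with the
    action taken (kept / flipped / strand / dropped) and a reason code.
    """

    table: pd.DataFrame
    audit: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "action", "reason"])
    )

    def __post_init__(self) -> None:
        missing = [c for c in INSTRUMENT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"instrument table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        if self.table["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in instrument set")
        if len(self.table) and not (
            (self.table["se_gamma"] > 0).all() and (self.table["se_big_gamma"] > 0).all()
        ):
            raise ValueError("instrument SEs must be positive")

    @property
    def k(self) -> int:
        return len(self.table)

    def drop(self, snp_ids: Sequence[str]) -> "InstrumentSet":
        keep = ~self.table["snp_id"].isin(list(snp_ids))
        return InstrumentSet(self.table.loc[keep].copy(), self.audit.copy())


@dataclass
class MrEstimate:
    """A causal-effect estimate with a 95% normal CI.

    ``valid`` is False when a method-specific diagnostic (weak-instrument
    F, Egger I2_GX gate) disqualifies the estimate from headline use; the
    numbers are still reported.
    """

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    valid: bool = True
    notes: dict = field(default_factory=dict)

    @property
    def ci_low(self) -> float:
        return self.beta - 1.96 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + 1.96 * self.se

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "n_snps": self.n_snps,
            "valid": self.valid,
            **{f"note_{k}": v for k, v in self.notes.items()},
        }


@dataclass
class ClumpParams:
    """PLINK-style clumping thresholds.

    Defaults mirror common GWAS practice: genome-wide significance for
    instrument selection, a 10,000 kb window and r^2 < 0.001 for
    independence, and 1e-5 for both index and secondary SNPs.
    """

    window_kb: int = 10_000
    r2_threshold: float = 0.001
    p_index: float = 1e-5
    p_secondary: float = 1e-5
    gwas_threshold: float = 5e-8

    def __post_init__(self) -> None:
        for name in ("r2_threshold", "p_index", "p_secondary", "gwas_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
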