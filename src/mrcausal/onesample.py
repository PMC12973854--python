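"""One-sample MR with a polygenic risk score as the single instrument.

Stage 1 regresses the exposure jointly on the instrument dosages to get
per-SNP weights ``gamma_j`` and a fitted PRS ``sum_j gamma_j G_ij``; stage
2 regresses the outcome on the fitted PRS, so the stage-2 slope is the
two-stage least-squares causal estimate.  Instrument strength is the
F-statistic of the exposure-on-PRS regression, with F < 10 flagging weak
instruments.  Descriptives by PRS tertile (ANOVA, chi-squared,
trend/Cochran-Armitage tests) reproduce the standard cohort table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .datatypes import GenotypeMatrix, MrEstimate, PhenotypeTable
from .synthetic import _imputed

__all__ = [
    "PrsWeights",
    "Stage1Fit",
    "fit_instrument_weights",
    "compute_prs",
    "two_stage_ls",
    "instrument_f",
    "tertile_assign",
    "tertile_descriptives",
    "cochran_armitage",
]

logger = logging.getLogger(__name__)


@dataclass
class PrsWeights:
    """Per-SNP PRS weights from the joint stage-1 regression."""

    snp_ids: list[str]
    weights: np.ndarray
    intercept: float
    n: int
    r_squared: float
    family: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isfinite(self.weights).all():
            raise ValueError("non-finite PRS weights")


@dataclass
class Stage1Fit:
    """Fitted PRS and the instrument-strength diagnostic."""

    fitted_prs: np.ndarray
    f_statistic: float
    rounding_dp: Optional[int] = None
    degenerate: bool = False

    @property
    def weak_instrument(self) -> bool:
        return self.f_statistic < 10.0


def _collinear_columns(X: np.ndarray, snp_ids: Sequence[str]) -> list[str]:
    """Names of dosage columns that are exactly linearly dependent."""
    Xc = X - X.mean(axis=0)
    _, r, piv = linalg.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 1.0)
    rank = int((diag > tol).sum())
    if rank == X.shape[1]:
        return []
    dependent = sorted(piv[rank:].tolist())
    # a dependent column is collinear with the retained ones; report both
    # sides of any exact duplicate pair for a usable message
    names = {snp_ids[j] for j in dependent}
    for j in dependent:
        for i in range(X.shape[1]):
            if i != j and np.allclose(Xc[:, i], Xc[:, j]):
                names.add(snp_ids[i])
    return sorted(names)


def fit_instrument_weights(
    G: GenotypeMatrix,
    exposure: np.ndarray,
    family: Literal["linear", "logistic"] = "linear",
    covariates: Optional[np.ndarray] = None,
) -> PrsWeights:
    """Joint multiple regression of the exposure on all instrument dosages.

    The default is a linear(-probability) fit even for a binary exposure:
    the additive PRS construction and the 2SLS consistency argument both
    presuppose a linear first stage.  Logistic weights are offered for
    exploration; the resulting PRS is on the log-odds scale and the 2SLS
    slope is then per log-odds unit, not per liability unit.
    """
    exposure = np.asarray(exposure, dtype=float)
    if np.isnan(exposure).any():
        raise ValueError("exposure contains missing values")
    if G.m >= G.n:
        raise ValueError(f"need more individuals ({G.n}) than SNPs ({G.m})")
    dos = _imputed(G.dosages)
    bad = _collinear_columns(dos, G.snp_ids)
    if bad:
        raise ValueError(f"exactly collinear dosage columns: {bad}")
    ncov = 0
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        ncov = covariates.shape[1]
        X = np.column_stack([np.ones(G.n), dos, covariates])
    else:
        X = np.column_stack([np.ones(G.n), dos])

    if family == "linear":
        coef, _, _, _ = np.linalg.lstsq(X, exposure, rcond=None)
        fitted = X @ coef
        ss_res = float(((exposure - fitted) ** 2).sum())
        ss_tot = float(((exposure - exposure.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    elif family == "logistic":
        import statsmodels.api as sm

        fit = sm.Logit(exposure, X).fit(disp=0, maxiter=200)
        coef = np.asarray(fit.params)
        r2 = float(fit.prsquared)
    else:
        raise ValueError(f"unknown family {family!r}")
    return PrsWeights(
        snp_ids=list(G.snp_ids),
        weights=coef[1 : 1 + G.m],
        intercept=float(coef[0]),
        n=G.n,
        r_squared=r2,
        family=family,
    )


def compute_prs(
    G: GenotypeMatrix, weights: PrsWeights, rounding_dp: Optional[int] = None
) -> np.ndarray:
    """PRS_i = sum_j weight_j * G_ij over the weighted SNPs.

    Missing dosages are mean-imputed per SNP (logged).  ``rounding_dp``
    rounds each score half-even to that many decimals, mirroring analyses
    that carry the fitted PRS at limited precision.
    """
    missing = [s for s in weights.snp_ids if s not in G.snp_ids]
    if missing:
        raise KeyError(f"weights refer to SNPs absent from genotypes: {missing}")
    sub = G.subset(weights.snp_ids)
    if np.isnan(sub.dosages).any():
        logger.info("mean-imputing missing dosages for PRS")
    prs = _imputed(sub.dosages) @ weights.weights
    if rounding_dp is not None:
        prs = np.round(prs, rounding_dp)
    return prs


def _simple_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept, slope SE, residual SS of y ~ 1 + x."""
    n = len(x)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ZeroDivisionError("regressor has no variation")
    slope = float(xc @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - intercept - slope * x
    rss = float(resid @ resid)
    se = math.sqrt(rss / max(n - 2, 1) / sxx)
    return slope, intercept, se, rss


def two_stage_ls(
    G: GenotypeMatrix,
    exposure: np.ndarray,
    outcome: np.ndarray,
    family_stage1: Literal["linear", "logistic"] = "linear",
    se_mode: Literal["naive", "iv_robust"] = "naive",
    rounding_dp: Optional[int] = None,
    covariates: Optional[np.ndarray] = None,
) -> tuple[MrEstimate, Stage1Fit]:
    """Two-stage least squares with the fitted PRS as the single instrument.

    The headline ``naive`` SE is the stage-2 OLS standard error of the
    outcome-on-PRS slope (the manual two-regression procedure); the
    conventional IV sandwich SE, which plugs the observed exposure into
    the residual, is always computed alongside and reported in the notes.
    Rows with a missing exposure or outcome are dropped casewise.
    """
    exposure = np.asarray(exposure, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    keep = ~(np.isnan(exposure) | np.isnan(outcome))
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("two_stage_ls: dropped %d incomplete cases", n_drop)
        G = GenotypeMatrix(
            [sid for sid, k in zip(G.sample_ids, keep) if k], list(G.panel), G.dosages[keep]
        )
        exposure, outcome = exposure[keep], outcome[keep]
        if covariates is not None:
            covariates = np.asarray(covariates)[keep]

    weights = fit_instrument_weights(G, exposure, family=family_stage1, covariates=covariates)
    prs = compute_prs(G, weights, rounding_dp=rounding_dp)
    if prs.var() == 0:
        raise ValueError("instrument has no variation")

    n = len(prs)
    slope, intercept, se_naive, rss2 = _simple_ols(prs, outcome)

    # conventional just-identified IV sandwich: residuals use the observed
    # exposure, variance scaled by instrument variation
    prs_c = prs - prs.mean()
    szz = float(prs_c @ prs_c)
    u = outcome - outcome.mean() - slope * (exposure - exposure.mean())
    sxz = float(prs_c @ (exposure - exposure.mean()))
    if sxz != 0:
        # effect per unit exposure; identical to `slope` when stage-1 is
        # linear with no rounding (fitted-value algebra), else reported
        beta_iv = float(prs_c @ (outcome - outcome.mean())) / sxz
        u_iv = outcome - outcome.mean() - beta_iv * (exposure - exposure.mean())
        se_iv = math.sqrt(float(u_iv @ u_iv) / max(n - 2, 1) * szz / sxz**2)
    else:
        beta_iv, se_iv = float("nan"), float("nan")

    # instrument strength: exposure regressed on the fitted PRS
    f_slope, _, f_se, f_rss = _simple_ols(prs, exposure)
    degenerate = f_rss <= 1e-12 * max(1.0, float(exposure.var()) * n)
    f_stat = float("inf") if (degenerate or f_se == 0) else (f_slope / f_se) ** 2
    stage1 = Stage1Fit(fitted_prs=prs, f_statistic=f_stat, rounding_dp=rounding_dp,
                       degenerate=degenerate)

    se = se_naive if se_mode == "naive" else se_iv
    pval = 2.0 * stats.norm.sf(abs(slope / se)) if se > 0 else 0.0
    estimate = MrEstimate(
        method="2sls_prs",
        beta=slope,
        se=se,
        pval=float(pval),
        n_snps=G.m,
        valid=not stage1.weak_instrument,
        notes={
            "se_naive": se_naive,
            "se_iv_robust": se_iv,
            "beta_iv_per_exposure_unit": beta_iv,
            "f_statistic": f_stat,
            "n": n,
            "stage1_r2": weights.r_squared,
            "dropped_incomplete": n_drop,
        },
    )
    return estimate, stage1


def instrument_f(prs: np.ndarray, exposure: np.ndarray) -> float:
    """F-statistic of the single-instrument regression exposure ~ PRS.

    With one numerator degree of freedom this is exactly the squared
    t-statistic of the slope.
    """
    slope, _, se, rss = _simple_ols(np.asarray(prs, float), np.asarray(exposure, float))
    if rss <= 1e-12 * max(1.0, float(np.var(exposure)) * len(prs)) or se == 0:
        return float("inf")
    return (slope / se) ** 2


def tertile_assign(prs: np.ndarray) -> np.ndarray:
    """Tertile index (0, 1, 2) with ties broken deterministically.

    Individuals are stable-sorted by PRS and split into three groups whose
    sizes differ by at most one; equal scores go to the lower tertile
    first, in input order.
    """
    prs = np.asarray(prs, dtype=float)
    n = len(prs)
    order = np.argsort(prs, kind="stable")
    sizes = [n // 3 + (1 if r < n % 3 else 0) for r in range(3)]
    idx = np.empty(n, dtype=int)
    start = 0
    for t, size in enumerate(sizes):
        idx[order[start : start + size]] = t
        start += size
    return idx


@dataclass
class TertileTable:
    """Descriptive statistics by PRS tertile with group-difference tests."""

    counts: pd.Series
    continuous: pd.DataFrame  # variable x (mean_T1..3, sd_T1..3, p_anova, p_trend)
    discrete: pd.DataFrame  # variable x (counts per tertile, p_chisq, p_trend)
    notes: list[str] = field(default_factory=list)


def tertile_descriptives(
    prs: np.ndarray,
    phenotypes: PhenotypeTable,
    continuous_vars: Sequence[str] = ("outcome", "age"),
    discrete_vars: Sequence[str] = ("exposure_binary", "sex"),
) -> TertileTable:
    """The standard cohort table across PRS tertiles.

    Continuous variables: per-tertile mean and SD, one-way ANOVA p, and a
    p for trend from the regression of the variable on the tertile index.
    Discrete variables: per-tertile counts, Pearson chi-squared p, and a
    Cochran-Armitage trend p for binary variables.  A constant variable
    yields p = NaN with a note, never p = 1.
    """
    if len(prs) < 3:
        raise ValueError("need at least 3 individuals for tertiles")
    tert = tertile_assign(prs)
    counts = pd.Series(tert).value_counts().sort_index()
    notes: list[str] = []

    cont_rows = {}
    for var in continuous_vars:
        x = np.asarray(getattr(phenotypes, var), dtype=float)
        groups = [x[tert == t] for t in range(3)]
        row = {}
        for t in range(3):
            row[f"mean_T{t + 1}"] = float(groups[t].mean())
            row[f"sd_T{t + 1}"] = float(groups[t].std(ddof=1)) if len(groups[t]) > 1 else float("nan")
        if np.ptp(x) == 0:
            row["p_anova"] = row["p_trend"] = float("nan")
            notes.append(f"{var}: constant, tests not applicable")
        else:
            row["p_anova"] = float(stats.f_oneway(*groups).pvalue)
            slope, _, se, _ = _simple_ols(tert.astype(float), x)
            row["p_trend"] = float(2.0 * stats.norm.sf(abs(slope / se))) if se > 0 else float("nan")
        cont_rows[var] = row

    disc_rows = {}
    for var in discrete_vars:
        x = np.asarray(getattr(phenotypes, var))
        levels = np.unique(x)
        table = np.array([[int(((x == lv) & (tert == t)).sum()) for t in range(3)] for lv in levels])
        row = {f"n_T{t + 1}": table[:, t].tolist() for t in range(3)}
        row["levels"] = levels.tolist()
        if len(levels) < 2:
            row["p_chisq"] = row["p_trend"] = float("nan")
            notes.append(f"{var}: constant, tests not applicable")
        else:
            row["p_chisq"] = float(stats.chi2_contingency(table).pvalue)
            if len(levels) == 2:
                _, p_tr = cochran_armitage(table[::-1], scores=np.arange(3, dtype=float))
                row["p_trend"] = p_tr
            else:
                slope, _, se, _ = _simple_ols(tert.astype(float), x.astype(float))
                row["p_trend"] = float(2.0 * stats.norm.sf(abs(slope / se))) if se > 0 else float("nan")
        disc_rows[var] = row

    return TertileTable(
        counts=counts,
        continuous=pd.DataFrame(cont_rows).T,
        discrete=pd.DataFrame(disc_rows).T,
        notes=notes,
    )


def cochran_armitage(
    counts: np.ndarray, scores: Optional[np.ndarray] = None
) -> tuple[float, float]:
    """Cochran-Armitage test for trend in a 2 x k table.

    ``counts`` rows are (cases, controls) across k ordered columns.  The
    statistic is ``Z = T / sqrt(Var(T))`` with
    ``T = sum_i s_i (r_i - n_i R/N)`` and
    ``Var(T) = p(1-p) [sum n_i s_i^2 - (sum n_i s_i)^2 / N]``; Z^2 is
    invariant to affine rescaling of the scores.  Columns with zero total
    are dropped with a log note.  Returns (Z, two-sided normal p).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 2 or counts.shape[1] < 2:
        raise ValueError("counts must be a 2 x k table with k >= 2")
    if (counts.sum(axis=1) <= 0).any():
        raise ValueError("both rows must have positive totals")
    if scores is None:
        scores = np.arange(counts.shape[1], dtype=float)
    scores = np.asarray(scores, dtype=float)
    n_i = counts.sum(axis=0)
    empty = n_i == 0
    if empty.any():
        logger.info("cochran_armitage: dropped %d empty columns", int(empty.sum()))
        counts, scores, n_i = counts[:, ~empty], scores[~empty], n_i[~empty]
    r_i = counts[0]
    N = n_i.sum()
    R = r_i.sum()
    p = R / N
    T = float((scores * (r_i - n_i * R / N)).sum())
    var = p * (1.0 - p) * float((n_i * scores**2).sum() - (n_i * scores).sum() ** 2 / N)
    if var <= 0:
        return 0.0, 1.0
    z = T / math.sqrt(var)
    return z, float(2.0 * stats.norm.sf(abs(z)))
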