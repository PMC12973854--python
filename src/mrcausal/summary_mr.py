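"""Summary-statistic MR estimators and sensitivity analyses.

Per-SNP Wald ratios ``beta_j = Gamma_j / gamma_j`` (outcome association
over exposure association) are combined by inverse-variance weighting,
MR-Egger regression with the I2_GX weak-instrument gate, and the weighted
median.  Sensitivity analyses: funnel-plot outlier detection by the
3x-IQR rule, leave-one-out re-estimation, and an optional re-run with
outliers excluded.

The ratio is oriented outcome-over-exposure throughout: the causal
estimate carries outcome units per unit of exposure, which is the only
orientation under which combining ratios across SNPs estimates a single
causal slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import InstrumentSet, MrEstimate

__all__ = [
    "RatioEstimates",
    "EggerResult",
    "SensitivityReport",
    "MrReport",
    "wald_ratios",
    "ivw",
    "i2_gx",
    "mr_egger",
    "weighted_median",
    "weighted_median_point",
    "funnel_outliers",
    "leave_one_out",
    "beta_to_or",
    "mr_report",
]

I2_GX_GATE = 0.90  # Egger requires I2_GX >= 90% (NO-measurement-error proxy)


@dataclass
class RatioEstimates:
    """Per-SNP Wald ratios with first-order delta-method SEs."""

    table: pd.DataFrame  # snp_id, ratio_beta, ratio_se, weight
    excluded: pd.DataFrame  # snp_id, reason

    @property
    def k(self) -> int:
        return len(self.table)


@dataclass
class EggerResult:
    """MR-Egger slope and intercept with the I2_GX validity gate."""

    slope: MrEstimate
    intercept: float
    intercept_se: float
    intercept_pval: float
    i2_gx: float

    @property
    def valid(self) -> bool:
        return self.i2_gx >= I2_GX_GATE


@dataclass
class SensitivityReport:
    """Funnel outliers and leave-one-out re-estimates."""

    outlier_snp_ids: list[str]
    outlier_rule_applicable: bool
    leave_one_out: pd.DataFrame  # excluded_snp_id, beta, se, ci_low, ci_high, outside_full_ci
    funnel: pd.DataFrame  # snp_id, ratio_beta, precision


def wald_ratios(iset: InstrumentSet, second_order_se: bool = False) -> RatioEstimates:
    """Per-SNP causal estimates ``Gamma_j / gamma_j``.

    The first-order delta SE is ``se(Gamma_j)/|gamma_j|``; the optional
    second-order term adds the exposure-side uncertainty
    ``Gamma_j^2 se(gamma_j)^2 / gamma_j^4``.  SNPs with a zero exposure
    association have an undefined ratio and are excluded with a reason.
    """
    t = iset.table
    if (t["se_gamma"] <= 0).any() or (t["se_big_gamma"] <= 0).any():
        raise ValueError("all SEs must be positive")
    zero = t["gamma"] == 0
    excluded = pd.DataFrame(
        {"snp_id": t.loc[zero, "snp_id"], "reason": "zero exposure association"}
    ).reset_index(drop=True)
    kept = t.loc[~zero]
    beta = kept["big_gamma"] / kept["gamma"]
    var = kept["se_big_gamma"] ** 2 / kept["gamma"] ** 2
    if second_order_se:
        var = var + kept["big_gamma"] ** 2 * kept["se_gamma"] ** 2 / kept["gamma"] ** 4
    se = np.sqrt(var)
    table = pd.DataFrame(
        {
            "snp_id": kept["snp_id"].to_numpy(),
            "ratio_beta": beta.to_numpy(),
            "ratio_se": se.to_numpy(),
            "weight": 1.0 / se.to_numpy() ** 2,
        }
    )
    return RatioEstimates(table=table, excluded=excluded)


def _normal_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else 0.0


def ivw(
    ratios: RatioEstimates,
    model: Literal["fixed", "multiplicative_random"] = "fixed",
) -> MrEstimate:
    """Inverse-variance weighted combination of the Wald ratios.

    Fixed effect: ``beta = sum(w b) / sum(w)``, ``se = sum(w)^(-1/2)``.
    Multiplicative random effects scale the SE by
    ``max(1, sqrt(Q/(k-1)))`` with Cochran's Q over the ratios, never
    deflating below the fixed-effect SE.
    """
    k = ratios.k
    if k < 1 or (model == "multiplicative_random" and k < 2):
        raise ValueError(f"too few instruments (k={k}) for IVW {model}")
    b = ratios.table["ratio_beta"].to_numpy()
    w = ratios.table["weight"].to_numpy()
    beta = float((w * b).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    q = float((w * (b - beta) ** 2).sum())
    if model == "multiplicative_random":
        se *= max(1.0, math.sqrt(q / (k - 1)))
    return MrEstimate(
        method=f"ivw_{model}",
        beta=beta,
        se=se,
        pval=_normal_p(beta, se),
        n_snps=k,
        notes={"cochran_q": q},
    )


def i2_gx(iset: InstrumentSet) -> float:
    """I2_GX: strength of exposure-association heterogeneity relative to
    its measurement error, the MR-Egger regression-dilution diagnostic.

    With ``v_j = 1/se(gamma_j)^2`` and the precision-weighted mean of the
    |gamma_j|, ``Q_GX = sum v_j (|gamma_j| - mean)^2`` and
    ``I2_GX = max(0, (Q_GX - (k-1)) / Q_GX)``.  Values below 0.90 signal
    that Egger estimates are diluted by more than ~10%.
    """
    t = iset.table
    k = len(t)
    if k < 2:
        raise ValueError("I2_GX requires at least 2 instruments")
    g = np.abs(t["gamma"].to_numpy())  # Egger orientation uses |gamma|
    v = 1.0 / t["se_gamma"].to_numpy() ** 2
    gbar = float((v * g).sum() / v.sum())
    q_gx = float((v * (g - gbar) ** 2).sum())
    if q_gx <= 0:
        return 0.0
    return max(0.0, (q_gx - (k - 1)) / q_gx)


def mr_egger(iset: InstrumentSet) -> EggerResult:
    """MR-Egger: weighted regression of Gamma on gamma with an intercept.

    Each SNP is first oriented so gamma_j >= 0 (flipping both
    associations), the weights are 1/se(Gamma_j)^2, the slope is the
    causal estimate and the intercept the average directional pleiotropy.
    SEs use a multiplicative random-effects scale floored at 1.  The
    result is gated by I2_GX but returned regardless, flagged invalid
    below the 90% gate.
    """
    t = iset.table
    k = len(t)
    if k < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    sign = np.where(t["gamma"].to_numpy() < 0, -1.0, 1.0)
    g = t["gamma"].to_numpy() * sign
    G = t["big_gamma"].to_numpy() * sign
    w = 1.0 / t["se_big_gamma"].to_numpy() ** 2

    X = np.column_stack([np.ones(k), g])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    coef = np.linalg.solve(xtwx, X.T @ (w * G))
    resid = G - X @ coef
    scale = float((w * resid**2).sum() / (k - 2))
    cov = np.linalg.inv(xtwx) * max(1.0, scale)
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    i2 = i2_gx(iset)
    slope_est = MrEstimate(
        method="mr_egger",
        beta=slope,
        se=se_slope,
        pval=_normal_p(slope, se_slope),
        n_snps=k,
        valid=i2 >= I2_GX_GATE,
        notes={"i2_gx": i2},
    )
    return EggerResult(
        slope=slope_est,
        intercept=intercept,
        intercept_se=se_int,
        intercept_pval=_normal_p(intercept, se_int),
        i2_gx=i2,
    )


def weighted_median_point(beta: np.ndarray, weight: np.ndarray) -> float:
    """Interpolated weighted median of the ratios.

    Ratios are sorted; with normalized weights ``w'`` the cumulative
    midpoints are ``s_j = cumsum(w')_j - w'_j/2`` and the estimate is the
    linear interpolation of beta against s at 0.5.
    """
    order = np.argsort(beta, kind="stable")
    b = np.asarray(beta, float)[order]
    w = np.asarray(weight, float)[order]
    wn = w / w.sum()
    s = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, s, b))


def weighted_median(
    ratios: RatioEstimates,
    iset: Optional[InstrumentSet] = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> MrEstimate:
    """Weighted-median causal estimate with a parametric-bootstrap SE.

    Consistent when valid instruments carry more than half the total
    weight.  The SE is the SD of the point estimate over ``n_boot``
    replicates that redraw ``gamma_j* ~ N(gamma_j, se_gamma_j^2)`` and
    ``Gamma_j* ~ N(Gamma_j, se_Gamma_j^2)`` (when ``iset`` is supplied)
    or redraw the ratios directly from their delta SEs otherwise.
    """
    k = ratios.k
    if k < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    b = ratios.table["ratio_beta"].to_numpy()
    w = ratios.table["weight"].to_numpy()
    est = weighted_median_point(b, w)

    rng = np.random.default_rng(seed)
    if iset is not None:
        t = iset.table.loc[iset.table["gamma"] != 0]
        g0 = t["gamma"].to_numpy()
        G0 = t["big_gamma"].to_numpy()
        sg = t["se_gamma"].to_numpy()
        sG = t["se_big_gamma"].to_numpy()
        g_star = rng.normal(g0, sg, size=(n_boot, k))
        G_star = rng.normal(G0, sG, size=(n_boot, k))
        ok = g_star != 0
        b_star = np.where(ok, G_star / np.where(ok, g_star, 1.0), np.nan)
        se_star = np.where(ok, sG / np.abs(np.where(ok, g_star, 1.0)), np.nan)
        w_star = 1.0 / se_star**2
    else:
        se0 = ratios.table["ratio_se"].to_numpy()
        b_star = rng.normal(b, se0, size=(n_boot, k))
        w_star = np.broadcast_to(w, (n_boot, k))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        mask = np.isfinite(b_star[i]) & np.isfinite(w_star[i])
        boots[i] = weighted_median_point(b_star[i][mask], w_star[i][mask])
    se = float(boots.std(ddof=1))
    return MrEstimate(
        method="weighted_median",
        beta=est,
        se=se,
        pval=_normal_p(est, se),
        n_snps=k,
        notes={"n_boot": n_boot, "seed": seed},
    )


def funnel_outliers(ratios: RatioEstimates) -> tuple[list[str], bool]:
    """Funnel-plot outliers by the 3x-IQR rule.

    Quartiles of the ratio estimates use linear interpolation of order
    statistics; a SNP is an outlier when its ratio lies below
    ``Q1 - 3 IQR`` or above ``Q3 + 3 IQR``.  With fewer than 5
    instruments the rule is not applicable (second return value False).
    """
    if ratios.k < 5:
        return [], False
    b = ratios.table["ratio_beta"].to_numpy()
    q1, q3 = np.quantile(b, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    mask = (b < lo) | (b > hi)
    return ratios.table.loc[mask, "snp_id"].tolist(), True


def leave_one_out(
    iset: InstrumentSet,
    estimator: Literal["ivw", "weighted_median"] = "ivw",
    model: Literal["fixed", "multiplicative_random"] = "fixed",
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-estimate excluding each SNP in turn.

    Flags exclusions that move the estimate outside the full-set 95% CI.
    Rows where the reduced set violates the estimator's minimum k carry
    NaN estimates.
    """
    ratios_full = wald_ratios(iset)
    if estimator == "ivw":
        if ratios_full.k < 2:
            raise ValueError("leave-one-out IVW requires k >= 2")
        full = ivw(ratios_full, model=model)
    else:
        full = weighted_median(ratios_full, iset=iset, n_boot=n_boot, seed=seed)
    rows = []
    for snp in iset.table["snp_id"]:
        sub = iset.drop([snp])
        try:
            r = wald_ratios(sub)
            est = (
                ivw(r, model=model)
                if estimator == "ivw"
                else weighted_median(r, iset=sub, n_boot=n_boot, seed=seed)
            )
            rows.append(
                {
                    "excluded_snp_id": snp,
                    "beta": est.beta,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "outside_full_ci": not (full.ci_low <= est.beta <= full.ci_high),
                }
            )
        except ValueError:
            rows.append(
                {
                    "excluded_snp_id": snp,
                    "beta": float("nan"),
                    "se": float("nan"),
                    "ci_low": float("nan"),
                    "ci_high": float("nan"),
                    "outside_full_ci": False,
                }
            )
    return pd.DataFrame(rows)


def beta_to_or(
    beta: float, ci_low: float, ci_high: float
) -> tuple[float, float, float]:
    """Exponentiate a log-scale estimate and CI to the odds-ratio scale."""
    return math.exp(beta), math.exp(ci_low), math.exp(ci_high)


@dataclass
class MrReport:
    """Everything the summary-MR stage computes, as plain tables."""

    estimates: dict[str, MrEstimate]
    egger: EggerResult
    ratios: RatioEstimates
    sensitivity: SensitivityReport
    excluding_outliers: Optional[dict[str, MrEstimate]] = None
    forest: pd.DataFrame = field(default_factory=pd.DataFrame)
    ratio_orientation: str = "outcome_over_exposure"

    #: the three estimators a reader compares first; IVW is the
    #: multiplicative random-effects model (fixed is reported alongside)
    HEADLINE = ("ivw", "mr_egger", "weighted_median")

    def headline(self) -> pd.DataFrame:
        rows = []
        for key in self.HEADLINE:
            est = self.estimates[key]
            d = est.to_dict()
            orr, lo, hi = beta_to_or(est.beta, est.ci_low, est.ci_high)
            d.update({"or": round(orr, 2), "or_low": round(lo, 2), "or_high": round(hi, 2)})
            rows.append(d)
        return pd.DataFrame(rows)

    def all_estimates(self) -> pd.DataFrame:
        return pd.DataFrame([est.to_dict() for est in self.estimates.values()])


def mr_report(
    iset: InstrumentSet,
    n_boot: int = 1000,
    seed: int = 0,
    rerun_without_outliers: bool = True,
) -> MrReport:
    """Run the full summary-MR battery on a harmonized instrument set.

    Headline estimators: fixed-effect IVW (with multiplicative
    random-effects alongside), MR-Egger gated by I2_GX, and the weighted
    median.  Sensitivity: funnel outliers (3x IQR), an optional re-run
    excluding them, and leave-one-out IVW.
    """
    ratios = wald_ratios(iset)
    estimates = {
        "ivw": ivw(ratios, model="multiplicative_random"),
        "ivw_fixed": ivw(ratios, model="fixed"),
    }
    egger = mr_egger(iset)
    estimates["mr_egger"] = egger.slope
    estimates["weighted_median"] = weighted_median(ratios, iset=iset, n_boot=n_boot, seed=seed)

    outliers, applicable = funnel_outliers(ratios)
    loo = leave_one_out(iset, estimator="ivw")
    funnel = pd.DataFrame(
        {
            "snp_id": ratios.table["snp_id"],
            "ratio_beta": ratios.table["ratio_beta"],
            "precision": 1.0 / ratios.table["ratio_se"],
        }
    )
    sensitivity = SensitivityReport(
        outlier_snp_ids=outliers,
        outlier_rule_applicable=applicable,
        leave_one_out=loo,
        funnel=funnel,
    )

    excluding = None
    if rerun_without_outliers and outliers:
        sub = iset.drop(outliers)
        sub_ratios = wald_ratios(sub)
        excluding = {
            "ivw": ivw(sub_ratios, model="multiplicative_random"),
            "ivw_fixed": ivw(sub_ratios, model="fixed"),
            "weighted_median": weighted_median(sub_ratios, iset=sub, n_boot=n_boot, seed=seed),
        }

    forest = iset.table[["snp_id", "gamma", "se_gamma", "big_gamma", "se_big_gamma"]].merge(
        ratios.table[["snp_id", "ratio_beta", "ratio_se"]], on="snp_id", how="left"
    )
    forest["ci_low"] = forest["ratio_beta"] - 1.96 * forest["ratio_se"]
    forest["ci_high"] = forest["ratio_beta"] + 1.96 * forest["ratio_se"]

    return MrReport(
        estimates=estimates,
        egger=egger,
        ratios=ratios,
        sensitivity=sensitivity,
        excluding_outliers=excluding,
        forest=forest,
    )
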