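"""Instrument-strength, heterogeneity, pleiotropy and power diagnostics.

Instrument strength is summarized per SNP by the variance explained

    R2 = [2 * BETA^2 * EAF * (1-EAF)]
         / [2 * BETA^2 * EAF * (1-EAF) + 2 * SE(BETA)^2 * N * EAF * (1-EAF)]

(BETA the SNP's effect on the exposure, EAF the effect-allele frequency,
SE(BETA) its standard error, N the exposure sample size) and by the
approximate F statistic F = R2 * (N - 2) / (1 - R2); F > 10 is the
conventional weak-instrument screen, reported as a property of the
instrument set rather than enforced as a filter.

Heterogeneity across Wald ratios uses Cochran's Q; directional pleiotropy
uses the MR-Egger intercept test; per-SNP influence uses leave-one-out
re-estimation and forest/funnel tables. Statistical power uses the standard
two-sided asymptotic approximation for summary-data MR (a desk substitute
for the commonly used web calculator): with non-centrality
nu = |beta| * sqrt(n * R2) for continuous outcomes (times sqrt(k*(1-k)) for
binary outcomes with case fraction k, beta on the log-odds scale),

    power = 1 - Phi(z_{1-a/2} - nu) + Phi(-z_{1-a/2} - nu).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    Z95,
    IVWEstimator,
    MREggerEstimator,
    MREstimate,
    ivw,
    wald_ratios,
)
from .exceptions import CytomrError, InsufficientInstrumentsError


def variance_explained(beta: float, se: float, eaf: float, n: int) -> float:
    """Share of exposure variance explained by one SNP (R2).

    The 2*EAF*(1-EAF) factor appears in numerator and denominator, so the
    value is symmetric under EAF <-> 1-EAF.
    """
    if not 0.0 < eaf < 1.0:
        raise CytomrError(f"eaf {eaf} outside (0,1)")
    if se <= 0.0 or n <= 0:
        raise CytomrError("se must be positive and n a positive integer")
    het = 2.0 * eaf * (1.0 - eaf)
    num = beta**2 * het
    return num / (num + se**2 * n * het)


def f_statistic(r2: float, n: int) -> float:
    """Approximate one-instrument F: R2 * (N - 2) / (1 - R2)."""
    if not 0.0 <= r2 < 1.0:
        raise CytomrError(f"r2 {r2} outside [0,1)")
    if n <= 2:
        raise CytomrError("n must exceed 2")
    return r2 * (n - 2) / (1.0 - r2)


def cochran_q(
    ratios: pd.DataFrame, beta_ivw: float
) -> tuple[float, int, float]:
    """Cochran's Q = sum w_j (r_j - beta)^2, df = J-1, chi-square upper p."""
    if len(ratios) < 2:
        raise InsufficientInstrumentsError(len(ratios), 2)
    r = ratios["ratio"].to_numpy(float)
    w = ratios["weight"].to_numpy(float)
    q = float((w * (r - beta_ivw) ** 2).sum())
    df = len(ratios) - 1
    return q, df, float(stats.chi2.sf(q, df))


def mr_power(
    n_outcome: int,
    total_r2: float,
    true_beta: float,
    alpha: float = 0.05,
    trait_type: str = "continuous",
    case_fraction: float | None = None,
) -> float:
    """Two-sided asymptotic power of the IVW test at level ``alpha``."""
    if not 0.0 < total_r2 < 1.0:
        raise CytomrError(f"total_r2 {total_r2} outside (0,1)")
    if not 0.0 < alpha < 1.0:
        raise CytomrError(f"alpha {alpha} outside (0,1)")
    if trait_type == "binary":
        if case_fraction is None:
            raise CytomrError("binary outcome requires case_fraction")
        nu = abs(true_beta) * np.sqrt(
            n_outcome * total_r2 * case_fraction * (1.0 - case_fraction)
        )
    elif trait_type == "continuous":
        nu = abs(true_beta) * np.sqrt(n_outcome * total_r2)
    else:
        raise CytomrError(f"unknown trait_type {trait_type!r}")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.sf(z - nu) + stats.norm.cdf(-z - nu))


def leave_one_out(
    instruments: pd.DataFrame,
    method: str = "ivw_mre",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Re-estimate dropping each SNP in turn (IVW by default).

    Flags drops that change the sign of the estimate or move it across the
    ``alpha`` significance boundary relative to the full-set estimate.
    """
    if len(instruments) < 3:
        raise InsufficientInstrumentsError(len(instruments), 3)
    mode = "fixed" if method == "ivw_fe" else "multiplicative_random"
    full = IVWEstimator(mode=mode).fit(instruments)
    rows = []
    for i in range(len(instruments)):
        rest = instruments.drop(instruments.index[i])
        est = IVWEstimator(mode=mode).fit(rest)
        rows.append(
            dict(
                snp_id=instruments["snp_id"].iloc[i],
                beta=est.beta_,
                se=est.se_,
                ci_low=est.ci_low_,
                ci_high=est.ci_high_,
                pval=est.pval_,
                sign_change=np.sign(est.beta_) != np.sign(full.beta_),
                crosses_alpha=(est.pval_ < alpha) != (full.pval_ < alpha),
            )
        )
    return pd.DataFrame(rows)


def per_snp_diagnostics(instruments: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready forest/funnel table: per-SNP ratio, 95% CI, precision."""
    if len(instruments) == 0:
        return pd.DataFrame(
            columns=["snp_id", "ratio", "se_ratio", "ci_low", "ci_high", "precision"]
        )
    ratios = wald_ratios(instruments)
    out = ratios[["snp_id", "ratio", "se_ratio"]].copy()
    out["ci_low"] = out["ratio"] - Z95 * out["se_ratio"]
    out["ci_high"] = out["ratio"] + Z95 * out["se_ratio"]
    out["precision"] = 1.0 / out["se_ratio"]
    return out


@dataclass
class SensitivityReport:
    """Diagnostics bundle for one exposure-outcome pair."""

    per_snp_r2: pd.DataFrame  # snp_id, r2, f
    min_f: float
    mean_f: float
    all_f_above_10: bool
    q: float
    q_df: int
    q_pval: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_pval: float
    power: float | None
    leave_one_out: pd.DataFrame
    single_snp: pd.DataFrame
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(
            per_snp_r2=self.per_snp_r2.to_dict(orient="records"),
            min_f=self.min_f,
            mean_f=self.mean_f,
            all_f_above_10=self.all_f_above_10,
            q=self.q,
            q_df=self.q_df,
            q_pval=self.q_pval,
            egger_intercept=self.egger_intercept,
            egger_intercept_se=self.egger_intercept_se,
            egger_intercept_pval=self.egger_intercept_pval,
            power=self.power,
            leave_one_out=self.leave_one_out.to_dict(orient="records"),
            single_snp=self.single_snp.to_dict(orient="records"),
        )


def sensitivity_report(
    instruments: pd.DataFrame,
    alpha: float = 0.05,
    trait_type: str = "continuous",
    case_fraction: float | None = None,
) -> SensitivityReport:
    """Full diagnostics bundle (needs >= 3 instruments for Egger and LOO).

    Power is computed at the IVW point estimate, with total instrument R2
    taken as the sum of per-SNP R2 (independence after clumping) and the
    outcome sample size as the median ``n_out``; it is ``None`` when any
    exposure EAF is unavailable.
    """
    if len(instruments) < 3:
        raise InsufficientInstrumentsError(len(instruments), 3)
    rows = []
    for _, row in instruments.iterrows():
        r2 = variance_explained(
            row["beta_exp"], row["se_exp"], row["eaf_exp"], int(row["n_exp"])
        )
        rows.append(
            dict(
                snp_id=row["snp_id"],
                r2=r2,
                f=f_statistic(r2, int(row["n_exp"])),
            )
        )
    per_snp = pd.DataFrame(rows)
    ratios = wald_ratios(instruments)
    ivw_est = ivw(instruments)
    q, q_df, q_pval = cochran_q(ratios, _ivw_fixed_beta(ratios))
    egger = MREggerEstimator().fit(instruments)
    total_r2 = float(per_snp["r2"].sum())
    power = None
    if 0.0 < total_r2 < 1.0:
        power = mr_power(
            int(instruments["n_out"].median()),
            total_r2,
            ivw_est.beta,
            alpha=alpha,
            trait_type=trait_type,
            case_fraction=case_fraction,
        )
    return SensitivityReport(
        per_snp_r2=per_snp,
        min_f=float(per_snp["f"].min()),
        mean_f=float(per_snp["f"].mean()),
        all_f_above_10=bool((per_snp["f"] > 10.0).all()),
        q=q,
        q_df=q_df,
        q_pval=q_pval,
        egger_intercept=egger.intercept_,
        egger_intercept_se=egger.intercept_se_,
        egger_intercept_pval=egger.intercept_pval_,
        power=power,
        leave_one_out=leave_one_out(instruments, alpha=alpha),
        single_snp=per_snp_diagnostics(instruments),
        extra={"total_r2": total_r2, "ivw_beta": ivw_est.beta},
    )


def _ivw_fixed_beta(ratios: pd.DataFrame) -> float:
    w = ratios["weight"].to_numpy(float)
    r = ratios["ratio"].to_numpy(float)
    return float((w * r).sum() / w.sum())
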