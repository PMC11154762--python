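"""Causal-effect estimators for two-sample MR.

Given J harmonized instruments with exposure effects ``beta_exp`` (SE
``se_exp``) and outcome effects ``beta_out`` (SE ``se_out``), each SNP j
provides a Wald ratio r_j = beta_out_j / beta_exp_j with first-order
(delta-method) standard error se_out_j / |beta_exp_j| and inverse-variance
weight w_j = 1 / se_ratio_j**2. Three combiners are provided:

* **IVW** — beta = sum(w r) / sum(w); fixed-effect SE = sum(w)**-0.5. The
  default multiplicative random-effects variant inflates the SE by
  sqrt(phi) with phi = max(1, Q/(J-1)), where Q is Cochran's statistic,
  giving more conservative intervals under heterogeneity. p-values from the
  standard normal.
* **MR-Egger** — weighted least squares of beta_out on beta_exp *with* a free
  intercept (weights 1/se_out**2), after orienting every instrument so
  beta_exp >= 0. The slope is the causal estimate; a non-zero intercept
  indicates directional pleiotropy. SEs use a residual inflation factor
  max(1, RSS_w/(J-2)); inference from t(J-2).
* **Weighted median** — the 50% point of the weight-ordered ratio
  distribution (linear interpolation of ratio against cumulative-weight
  midpoints); consistent when valid instruments carry at least half of the
  total weight. SE by parametric bootstrap.

Estimators follow the scikit-learn protocol: construct with hyperparameters,
``fit(instruments)`` on a harmonized-instrument DataFrame, read fitted
attributes with trailing underscores. The module-level ``ivw``, ``mr_egger``
and ``weighted_median`` functions are thin wrappers returning
:class:`MREstimate` records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import DegenerateInstrumentError, InsufficientInstrumentsError

#: normal 95% multiplier used by IVW and the weighted median
Z95 = 1.96


@dataclass(frozen=True)
class RatioEstimate:
    """One SNP's Wald ratio with its first-order SE and IVW weight."""

    snp_id: str
    ratio: float
    se_ratio: float
    weight: float


@dataclass
class MREstimate:
    """One method's causal estimate for one exposure-outcome pair."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    or_scale: tuple[float, float, float] | None = None  # (OR, OR low, OR high)
    extra: dict = field(default_factory=dict)

    def with_or_scale(self) -> "MREstimate":
        """Attach exp(beta) and exponentiated CI (binary outcomes)."""
        self.or_scale = (
            math.exp(self.beta),
            math.exp(self.ci_low),
            math.exp(self.ci_high),
        )
        return self


def _check_instruments(instruments: pd.DataFrame, minimum: int) -> pd.DataFrame:
    required = {"beta_exp", "se_exp", "beta_out", "se_out"}
    missing = required - set(instruments.columns)
    if missing:
        raise ValueError(f"instrument table lacks columns {sorted(missing)}")
    if len(instruments) < minimum:
        raise InsufficientInstrumentsError(len(instruments), minimum)
    return instruments


def wald_ratio(inst) -> RatioEstimate:
    """Per-SNP causal estimate beta_out/beta_exp with delta-method SE."""
    beta_exp = float(inst["beta_exp"])
    if beta_exp == 0.0:
        raise DegenerateInstrumentError(
            f"beta_exp = 0 for {inst.get('snp_id', '?')}"
        )
    ratio = float(inst["beta_out"]) / beta_exp
    se_ratio = float(inst["se_out"]) / abs(beta_exp)
    return RatioEstimate(
        snp_id=str(inst.get("snp_id", "")),
        ratio=ratio,
        se_ratio=se_ratio,
        weight=se_ratio**-2,
    )


def wald_ratios(instruments: pd.DataFrame) -> pd.DataFrame:
    """Vectorized Wald ratios: columns snp_id, ratio, se_ratio, weight."""
    bx = instruments["beta_exp"].to_numpy(float)
    if np.any(bx == 0.0):
        bad = instruments.loc[bx == 0.0, "snp_id"].tolist()
        raise DegenerateInstrumentError(f"beta_exp = 0 for {bad}")
    ratio = instruments["beta_out"].to_numpy(float) / bx
    se_ratio = instruments["se_out"].to_numpy(float) / np.abs(bx)
    return pd.DataFrame(
        {
            "snp_id": instruments.get(
                "snp_id", pd.Series([""] * len(instruments))
            ).to_numpy(),
            "ratio": ratio,
            "se_ratio": se_ratio,
            "weight": se_ratio**-2.0,
        }
    )


def _ivw_core(ratio: np.ndarray, weight: np.ndarray) -> tuple[float, float, float]:
    """(beta, fixed-effect se, Cochran Q) for the weighted ratio mean."""
    wsum = weight.sum()
    beta = float((weight * ratio).sum() / wsum)
    se_fixed = float(wsum**-0.5)
    q = float((weight * (ratio - beta) ** 2).sum())
    return beta, se_fixed, q


def _norm_pval(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def weighted_median_point(ratio: np.ndarray, weight: np.ndarray) -> float:
    """Interpolated weighted median of ``ratio`` under ``weight``.

    Ratios are sorted; with normalized weights w', cumulative midpoints
    p_j = cumsum(w')_j - w'_j/2 define a piecewise-linear quantile function
    evaluated at 0.5.
    """
    order = np.argsort(ratio, kind="stable")
    r = np.asarray(ratio, float)[order]
    w = np.asarray(weight, float)[order]
    w = w / w.sum()
    p = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, p, r))


class IVWEstimator(BaseEstimator):
    """Inverse-variance-weighted combination of per-SNP Wald ratios.

    Parameters
    ----------
    mode : {"multiplicative_random", "fixed"}
        ``multiplicative_random`` (default) inflates the fixed-effect SE by
        sqrt(max(1, Q/(J-1))); under-dispersion never deflates it.

    Fitted attributes: ``beta_``, ``se_``, ``ci_low_``, ``ci_high_``,
    ``pval_``, ``n_snps_``, ``q_``, ``q_df_``, ``phi_``, ``ratios_``.
    """

    def __init__(self, mode: str = "multiplicative_random"):
        self.mode = mode

    def fit(self, instruments: pd.DataFrame, y=None) -> "IVWEstimator":
        if self.mode not in ("multiplicative_random", "fixed"):
            raise ValueError(f"unknown IVW mode {self.mode!r}")
        inst = _check_instruments(instruments, minimum=2)
        self.ratios_ = wald_ratios(inst)
        r = self.ratios_["ratio"].to_numpy()
        w = self.ratios_["weight"].to_numpy()
        beta, se_fixed, q = _ivw_core(r, w)
        self.n_snps_ = len(inst)
        self.q_ = q
        self.q_df_ = self.n_snps_ - 1
        self.phi_ = max(1.0, q / self.q_df_)
        self.beta_ = beta
        if self.mode == "multiplicative_random":
            self.se_ = se_fixed * math.sqrt(self.phi_)
        else:
            self.se_ = se_fixed
        self.ci_low_ = self.beta_ - Z95 * self.se_
        self.ci_high_ = self.beta_ + Z95 * self.se_
        self.pval_ = _norm_pval(self.beta_, self.se_)
        return self

    def to_estimate(self) -> MREstimate:
        name = "ivw_mre" if self.mode == "multiplicative_random" else "ivw_fe"
        return MREstimate(
            method=name,
            beta=self.beta_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            pval=self.pval_,
            n_snps=self.n_snps_,
            extra={"q": self.q_, "q_df": self.q_df_, "phi": self.phi_},
        )


class MREggerEstimator(BaseEstimator):
    """MR-Egger weighted regression with a pleiotropy intercept.

    Fitted attributes: ``beta_`` (slope), ``se_``, ``ci_low_``, ``ci_high_``,
    ``pval_`` (t, J-2 df), ``intercept_``, ``intercept_se_``,
    ``intercept_pval_``, ``sigma2_`` (residual inflation, clamped at 1),
    ``n_snps_``.
    """

    def fit(self, instruments: pd.DataFrame, y=None) -> "MREggerEstimator":
        inst = _check_instruments(instruments, minimum=3)
        bx = inst["beta_exp"].to_numpy(float)
        by = inst["beta_out"].to_numpy(float)
        se_out = inst["se_out"].to_numpy(float)
        # orient so every exposure effect is non-negative; negating both
        # betas leaves the Wald ratio unchanged but makes InSIDE-style
        # intercept interpretation possible
        sign = np.where(bx < 0.0, -1.0, 1.0)
        x = bx * sign
        yv = by * sign
        w = se_out**-2.0
        wsum = w.sum()
        xbar = (w * x).sum() / wsum
        ybar = (w * yv).sum() / wsum
        sxx = (w * (x - xbar) ** 2).sum()
        sxy = (w * (x - xbar) * (yv - ybar)).sum()
        slope = sxy / sxx
        intercept = ybar - slope * xbar
        resid = yv - intercept - slope * x
        j = len(inst)
        rss_w = float((w * resid**2).sum())
        self.sigma2_ = max(1.0, rss_w / (j - 2))
        var_slope = self.sigma2_ / sxx
        var_int = self.sigma2_ * (1.0 / wsum + xbar**2 / sxx)
        self.n_snps_ = j
        self.beta_ = float(slope)
        self.se_ = float(math.sqrt(var_slope))
        self.intercept_ = float(intercept)
        self.intercept_se_ = float(math.sqrt(var_int))
        df = j - 2
        tq = float(stats.t.ppf(0.975, df))
        self.ci_low_ = self.beta_ - tq * self.se_
        self.ci_high_ = self.beta_ + tq * self.se_
        self.pval_ = float(2.0 * stats.t.sf(abs(self.beta_) / self.se_, df))
        self.intercept_pval_ = float(
            2.0 * stats.t.sf(abs(self.intercept_) / self.intercept_se_, df)
        )
        return self

    def to_estimate(self) -> MREstimate:
        return MREstimate(
            method="egger",
            beta=self.beta_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            pval=self.pval_,
            n_snps=self.n_snps_,
            extra={
                "intercept": self.intercept_,
                "intercept_se": self.intercept_se_,
                "intercept_pval": self.intercept_pval_,
                "sigma2": self.sigma2_,
            },
        )


class WeightedMedianEstimator(BaseEstimator):
    """Weighted-median combiner with parametric-bootstrap SE.

    Each bootstrap replicate redraws beta_exp and beta_out from normals
    centred at the observed values with their reported SEs and recomputes
    the weighted median; ``se_`` is the SD over replicates and the p-value
    uses a normal approximation.
    """

    def __init__(self, n_boot: int = 1000, random_state: int = 0):
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, instruments: pd.DataFrame, y=None) -> "WeightedMedianEstimator":
        inst = _check_instruments(instruments, minimum=3)
        ratios = wald_ratios(inst)
        r = ratios["ratio"].to_numpy()
        w = ratios["weight"].to_numpy()
        self.n_snps_ = len(inst)
        self.beta_ = weighted_median_point(r, w)
        if self.n_boot and self.n_boot > 1:
            rng = np.random.default_rng(self.random_state)
            bx = inst["beta_exp"].to_numpy(float)
            by = inst["beta_out"].to_numpy(float)
            sx = inst["se_exp"].to_numpy(float)
            sy = inst["se_out"].to_numpy(float)
            boots = np.empty(self.n_boot)
            for b in range(self.n_boot):
                bx_b = rng.normal(bx, sx)
                by_b = rng.normal(by, sy)
                bx_b[bx_b == 0.0] = np.finfo(float).tiny  # guard degenerate draw
                r_b = by_b / bx_b
                w_b = (sy / np.abs(bx_b)) ** -2.0
                boots[b] = weighted_median_point(r_b, w_b)
            self.se_ = float(np.std(boots, ddof=1))
        else:
            self.se_ = float("nan")
        self.ci_low_ = self.beta_ - Z95 * self.se_
        self.ci_high_ = self.beta_ + Z95 * self.se_
        self.pval_ = _norm_pval(self.beta_, self.se_)
        return self

    def to_estimate(self) -> MREstimate:
        return MREstimate(
            method="weighted_median",
            beta=self.beta_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            pval=self.pval_,
            n_snps=self.n_snps_,
            extra={"n_boot": self.n_boot, "seed": self.random_state},
        )


def ivw(instruments: pd.DataFrame, mode: str = "multiplicative_random") -> MREstimate:
    """IVW causal estimate; see :class:`IVWEstimator`."""
    return IVWEstimator(mode=mode).fit(instruments).to_estimate()


def mr_egger(instruments: pd.DataFrame) -> MREstimate:
    """MR-Egger slope and pleiotropy intercept; see :class:`MREggerEstimator`."""
    return MREggerEstimator().fit(instruments).to_estimate()


def weighted_median(
    instruments: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median causal estimate; see :class:`WeightedMedianEstimator`."""
    return (
        WeightedMedianEstimator(n_boot=n_boot, random_state=seed)
        .fit(instruments)
        .to_estimate()
    )


def estimates_to_frame(
    estimates: list[MREstimate],
    exposure: str = "",
    outcome: str = "",
) -> pd.DataFrame:
    """Serialize estimates as one row per method (results-table twin)."""
    rows = []
    for est in estimates:
        orv = est.or_scale or (None, None, None)
        rows.append(
            dict(
                exposure=exposure,
                outcome=outcome,
                method=est.method,
                n_snps=est.n_snps,
                beta=est.beta,
                se=est.se,
                ci_low=est.ci_low,
                ci_high=est.ci_high,
                pval=est.pval,
                odds_ratio=orv[0],
                or_ci_low=orv[1],
                or_ci_high=orv[2],
            )
        )
    return pd.DataFrame(rows)
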