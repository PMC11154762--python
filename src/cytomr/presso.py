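"""MR-PRESSO: resampling-based pleiotropy residual sum and outlier test.

For J >= 4 instruments with exposure effects x_j (SE sx_j) and outcome
effects y_j (SE sy_j), let b_{-j} be the inverse-variance-weighted slope
(zero-intercept WLS with weights 1/sy^2, equivalent to the ratio-based IVW)
computed without SNP j. The observed statistic is

    RSS_j = (y_j - b_{-j} * x_j)^2,       RSS = sum_j RSS_j.

A parametric null resamples x*_j ~ N(x_j, sx_j) and
y*_j ~ N(b_{-j} * x_j, sy_j) ``k_sim`` times, recomputing leave-one-out
slopes and residuals within each replicate. Empirical p-values use add-one
smoothing, so they are never zero:

* global test: p = (1 + #{RSS* >= RSS}) / (k_sim + 1);
* per-SNP outlier test: raw p_j analogous on RSS_j, Bonferroni-adjusted by
  J; SNPs with adjusted p below ``outlier_alpha`` are flagged as outliers
  (selection-pipeline step 6, single pass, not iterated);
* distortion test: compares the IVW slope with and without outliers against
  the distribution of the same contrast for random subsets of the outlier
  count (reported, never used for filtering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .estimators import ivw
from .exceptions import InsufficientInstrumentsError


@dataclass
class PressoResult:
    """Outcome of the global, outlier and distortion tests."""

    rss_obs: float
    global_pval: float
    per_snp: pd.DataFrame  # snp_id, rss, pval_raw, pval_adj
    outliers: set[str]
    distortion_pval: float | None
    beta_before: object  # MREstimate (IVW with all SNPs)
    beta_after: object | None  # MREstimate without outliers
    k_sim: int
    seed: int
    extra: dict = field(default_factory=dict)


def _loo_slopes(x, y, w):
    """Leave-one-out zero-intercept WLS slopes, vectorized.

    Supports x, y of shape (J,) or (k, J); w of shape (J,).
    """
    sxy = (w * x * y).sum(axis=-1, keepdims=True)
    sxx = (w * x * x).sum(axis=-1, keepdims=True)
    return (sxy - w * x * y) / (sxx - w * x * x)


def _rss_components(x, y, w):
    b_loo = _loo_slopes(x, y, w)
    return (y - b_loo * x) ** 2


class MRPRESSO(BaseEstimator):
    """MR-PRESSO test as a scikit-learn style estimator.

    Fitted attributes: ``rss_obs_``, ``global_pval_``, ``per_snp_``,
    ``outliers_``, ``distortion_pval_``, ``beta_before_``, ``beta_after_``.
    """

    def __init__(
        self,
        k_sim: int = 1000,
        outlier_alpha: float = 0.05,
        random_state: int = 0,
        distortion_draws: int = 1000,
    ):
        self.k_sim = k_sim
        self.outlier_alpha = outlier_alpha
        self.random_state = random_state
        self.distortion_draws = distortion_draws

    def fit(self, instruments: pd.DataFrame, y=None) -> "MRPRESSO":
        j = len(instruments)
        if j < 4:
            raise InsufficientInstrumentsError(j, 4)
        rng = np.random.default_rng(self.random_state)
        x = instruments["beta_exp"].to_numpy(float)
        yv = instruments["beta_out"].to_numpy(float)
        sx = instruments["se_exp"].to_numpy(float)
        sy = instruments["se_out"].to_numpy(float)
        w = sy**-2.0

        b_loo = np.asarray(_loo_slopes(x, yv, w)).reshape(-1)
        rss_j = (yv - b_loo * x) ** 2
        self.rss_obs_ = float(rss_j.sum())

        # parametric null: expected outcome effect of SNP j is its own
        # leave-one-out prediction from the observed data
        x_sim = rng.normal(x, sx, size=(self.k_sim, j))
        y_sim = rng.normal(b_loo * x, sy, size=(self.k_sim, j))
        rss_sim_j = _rss_components(x_sim, y_sim, w)
        rss_sim = rss_sim_j.sum(axis=1)

        self.global_pval_ = float(
            (1 + (rss_sim >= self.rss_obs_).sum()) / (self.k_sim + 1)
        )
        raw = (1 + (rss_sim_j >= rss_j).sum(axis=0)) / (self.k_sim + 1)
        adj = np.minimum(1.0, raw * j)
        snp_ids = instruments["snp_id"].astype(str).to_numpy()
        self.per_snp_ = pd.DataFrame(
            {"snp_id": snp_ids, "rss": rss_j, "pval_raw": raw, "pval_adj": adj}
        )
        self.outliers_ = set(snp_ids[adj < self.outlier_alpha])

        self.beta_before_ = ivw(instruments)
        self.beta_after_ = None
        self.distortion_pval_ = None
        n_out = len(self.outliers_)
        if n_out and j - n_out >= 2:
            keep = ~instruments["snp_id"].astype(str).isin(self.outliers_)
            reduced = instruments.loc[keep]
            self.beta_after_ = ivw(reduced)
            self.distortion_pval_ = self._distortion(
                instruments, n_out, self.beta_before_.beta, self.beta_after_.beta, rng
            )
        return self

    def _distortion(self, instruments, n_out, beta_all, beta_free, rng) -> float:
        """Is the outlier-induced shift larger than random-subset shifts?"""
        if beta_free == 0.0:
            return 1.0
        d_obs = abs((beta_all - beta_free) / beta_free)
        j = len(instruments)
        count = 0
        for _ in range(self.distortion_draws):
            drop = rng.choice(j, size=n_out, replace=False)
            keep = np.ones(j, bool)
            keep[drop] = False
            if keep.sum() < 2:
                continue
            b_sub = ivw(instruments.iloc[keep]).beta
            if b_sub == 0.0:
                continue
            if abs((beta_all - b_sub) / b_sub) >= d_obs:
                count += 1
        return float((1 + count) / (self.distortion_draws + 1))

    def to_result(self) -> PressoResult:
        return PressoResult(
            rss_obs=self.rss_obs_,
            global_pval=self.global_pval_,
            per_snp=self.per_snp_,
            outliers=set(self.outliers_),
            distortion_pval=self.distortion_pval_,
            beta_before=self.beta_before_,
            beta_after=self.beta_after_,
            k_sim=self.k_sim,
            seed=self.random_state,
        )


def presso_test(
    instruments: pd.DataFrame,
    k_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """Run MR-PRESSO; see :class:`MRPRESSO` for the procedure."""
    return (
        MRPRESSO(k_sim=k_sim, outlier_alpha=outlier_alpha, random_state=seed)
        .fit(instruments)
        .to_result()
    )
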