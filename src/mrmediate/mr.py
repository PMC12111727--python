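"""Causal-effect estimators and sensitivity diagnostics for two-sample MR.

Estimators operate on a :class:`~mrmediate.sumstats.HarmonizedSet`:

* per-SNP Wald ratios with first-order delta-method standard errors;
* inverse-variance-weighted (IVW) pooling, fixed-effect or multiplicative
  random effects (the default, scaling the SE by sqrt(max(1, Q/df)));
* Cochran's Q heterogeneity statistic with a chi-square reference;
* MR-Egger weighted regression, whose intercept tests directional
  horizontal pleiotropy (t reference with n-2 df, SEs scaled by
  max(1, residual SD) as in standard two-sample MR software);
* an MR-PRESSO-style parametric-simulation global test and per-SNP
  outlier test with Bonferroni adjustment and outlier-removed re-estimate.

Causal estimates for a binary outcome are log odds ratios; ``or_ci``
maps them to an odds ratio with a 95% Wald interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .sumstats import HarmonizedSet

Z95 = 1.96  # multiplier for 95% Wald intervals


@dataclass
class MRResult:
    """Causal estimate with heterogeneity and pleiotropy diagnostics."""

    method: str  # wald | ivw_fixed | ivw_mre | egger
    n_snp: int
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    q: Optional[float] = None
    q_df: Optional[int] = None
    q_pval: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_pval: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")
        if not self.se > 0:
            raise ValueError("se must be > 0")


@dataclass
class PressoResult:
    """Global and per-SNP outlier test with outlier-removed re-estimate."""

    global_rss: float
    global_pval: float
    per_snp_pval: dict[str, float]
    outliers: list[str]
    corrected: MRResult
    n_sim: int
    seed: int


def wald_ratio(
    beta_exp: float, se_exp: float, beta_out: float, se_out: float
) -> tuple[float, float]:
    """Per-SNP causal estimate beta_out / beta_exp with first-order SE.

    The delta-method SE ``se_out / |beta_exp|`` ignores exposure noise,
    the standard first-order choice.
    """
    if beta_exp == 0:
        raise ValueError("beta_exp must be nonzero for a Wald ratio")
    return beta_out / beta_exp, se_out / abs(beta_exp)


def or_ci(beta: float, se: float) -> tuple[float, float, float]:
    """Odds ratio exp(beta) with 95% Wald interval bounds."""
    if not se > 0:
        raise ValueError("se must be > 0")
    return float(np.exp(beta)), float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se))


def _ratios(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    bx, sy, by = h.beta_exp, h.se_out, h.beta_out
    if np.any(bx == 0):
        raise ValueError("all exposure betas must be nonzero")
    return by / bx, sy / np.abs(bx)


def ivw(h: HarmonizedSet, mode: str = "mre") -> MRResult:
    """Inverse-variance-weighted pooled causal estimate.

    Pools per-SNP Wald ratios with weights 1/ratio_se^2.  ``mode="fixed"``
    uses the fixed-effect SE; ``mode="mre"`` (multiplicative random
    effects, the default) scales it by sqrt(max(1, Q/df)).  Heterogeneity
    fields (Q, df, p) are reported from two SNPs upward.  P-values use a
    two-sided normal reference.
    """
    if mode not in ("fixed", "mre"):
        raise ValueError(f"mode must be 'fixed' or 'mre', got {mode!r}")
    n = len(h)
    if n < 1:
        raise ValueError("ivw requires at least one SNP")
    r, rse = _ratios(h)
    w = 1.0 / rse**2
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sqrt(1.0 / np.sum(w)))
    q = q_df = q_pval = None
    se = se_fixed
    if n >= 2:
        q = float(np.sum(w * (r - beta) ** 2))
        q_df = n - 1
        q_pval = float(stats.chi2.sf(q, q_df))
        if mode == "mre":
            se = se_fixed * float(np.sqrt(max(1.0, q / q_df)))
    pval = float(2 * stats.norm.sf(abs(beta / se)))
    or_, lo, hi = or_ci(beta, se)
    method = "wald" if n == 1 else f"ivw_{mode}"
    return MRResult(
        method=method,
        n_snp=n,
        beta=beta,
        se=se,
        pval=pval,
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        q=q,
        q_df=q_df,
        q_pval=q_pval,
    )


def egger(h: HarmonizedSet) -> MRResult:
    """MR-Egger: weighted regression of outcome on exposure effects with a
    free intercept.

    Rows are oriented so the exposure effect is non-negative (both betas
    negated where needed); weights are 1/se_out^2.  Coefficient SEs are the
    unscaled WLS SEs multiplied by max(1, residual SD); both slope and
    intercept use a two-sided t reference with n-2 df.  A nonzero intercept
    indicates directional horizontal pleiotropy.
    """
    n = len(h)
    if n < 3:
        raise ValueError(f"egger requires >= 3 SNPs, got {n}")
    bx = h.beta_exp.copy()
    by = h.beta_out.copy()
    flip = bx < 0
    bx[flip] *= -1
    by[flip] *= -1
    w = 1.0 / h.se_out**2
    X = np.column_stack([np.ones(n), bx])
    xtwx = X.T @ (w[:, None] * X)
    cov_unscaled = np.linalg.inv(xtwx)
    coef = cov_unscaled @ (X.T @ (w * by))
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (n - 2))
    scale = max(1.0, np.sqrt(sigma2))
    se_coef = np.sqrt(np.diag(cov_unscaled)) * scale
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(se_coef[0]), float(se_coef[1])
    p_slope = float(2 * stats.t.sf(abs(slope / se_slope), n - 2))
    p_int = float(2 * stats.t.sf(abs(intercept / se_int), n - 2))
    or_, lo, hi = or_ci(slope, se_slope)
    return MRResult(
        method="egger",
        n_snp=n,
        beta=slope,
        se=se_slope,
        pval=p_slope,
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        egger_intercept=intercept,
        egger_intercept_se=se_int,
        egger_intercept_pval=p_int,
    )


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes (no-intercept WLS of by on bx, weights w).

    Works on 1-D vectors or on (n_sim, n_snp) matrices along axis -1.
    """
    num = np.sum(w * bx * by, axis=-1, keepdims=True)
    den = np.sum(w * bx**2, axis=-1, keepdims=True)
    return (num - w * bx * by) / (den - w * bx**2)


def presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """Simulation-based global and per-SNP outlier test on IVW residuals.

    The observed statistic is the weighted residual sum of squares
    ``RSS = sum_j w_j (beta_out_j - b_(-j) * beta_exp_j)^2`` with
    ``w_j = 1/se_out_j^2`` and ``b_(-j)`` the leave-one-out IVW slope.  The
    null distribution comes from ``n_sim`` parametric draws
    ``beta_out* ~ N(b_(-j) beta_exp_j, se_out_j)``,
    ``beta_exp* ~ N(beta_exp_j, se_exp_j)``; the global p is the fraction of
    simulated RSS at or above the observed one.  Each SNP's observed
    weighted squared residual is compared with its simulated counterparts,
    Bonferroni-multiplied by n_snp and capped at 1; SNPs below ``alpha``
    are removed and the IVW estimate recomputed.  Fully reproducible under
    a fixed ``seed``.
    """
    n = len(h)
    if n < 4:
        raise ValueError(f"presso requires >= 4 SNPs, got {n}")
    if n_sim < 100:
        raise ValueError(f"n_sim must be >= 100, got {n_sim}")
    bx, sx = h.beta_exp, h.se_exp
    by, sy = h.beta_out, h.se_out
    if np.any(bx == 0):
        raise ValueError("all exposure betas must be nonzero")
    w = 1.0 / sy**2
    loo = _loo_slopes(bx, by, w)
    d_obs = w * (by - loo * bx) ** 2
    rss_obs = float(np.sum(d_obs))

    rng = np.random.default_rng(seed)
    by_star = rng.normal(loo * bx, sy, size=(n_sim, n))
    bx_star = rng.normal(bx, sx, size=(n_sim, n))
    loo_star = _loo_slopes(bx_star, by_star, w)
    d_star = w * (by_star - loo_star * bx_star) ** 2
    rss_star = d_star.sum(axis=1)
    global_pval = float(np.mean(rss_star >= rss_obs))

    p_raw = np.mean(d_star >= d_obs, axis=0)
    p_adj = np.minimum(1.0, p_raw * n)
    rsids = h.rsids
    per_snp = {rsid: float(p) for rsid, p in zip(rsids, p_adj)}
    outliers = [rsid for rsid, p in zip(rsids, p_adj) if p < alpha]
    corrected = ivw(h.drop(outliers)) if outliers and len(outliers) < n else ivw(h)
    return PressoResult(
        global_rss=rss_obs,
        global_pval=global_pval,
        per_snp_pval=per_snp,
        outliers=outliers,
        corrected=corrected,
        n_sim=n_sim,
        seed=seed,
    )
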