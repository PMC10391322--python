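"""Causal-effect estimators and sensitivity statistics for two-sample MR.

All estimators operate on a :class:`~cytomr.gwas_io.HarmonisedSet` of
per-variant exposure and outcome associations (beta_x, se_x, beta_y, se_y):

* Wald ratio — single-variant estimate beta_y / beta_x, first-order SE.
* IVW — weighted regression of beta_y on beta_x through the origin with
  weights 1/se_y^2; fixed-effect or multiplicative-random-effect SE.
* MR-Egger — the same regression with a free intercept; a non-zero
  intercept indicates directional horizontal pleiotropy and the slope is a
  pleiotropy-adjusted estimate under the InSIDE assumption.
* Weighted median — consistent while less than half the instrument weight
  comes from invalid variants; bootstrap SE.
* Cochran's Q, leave-one-out — heterogeneity and influence diagnostics.

Weights are first-order (outcome-variance only) throughout; p-values and
confidence intervals use the normal reference, 95% level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .gwas_io import HarmonisedSet, two_sided_p

Z95 = 1.959963984540054  # Phi^{-1}(0.975)

WALD_RATIO = "wald_ratio"
IVW_FIXED = "ivw_fixed"
IVW_MRE = "ivw_mre"
EGGER = "egger"
WEIGHTED_MEDIAN = "weighted_median"


class EstimationError(ValueError):
    """Raised when an estimate is undefined for the given inputs."""


class NotEstimable(EstimationError):
    """Raised when a method is infeasible (too few variants)."""


@dataclass
class MREstimate:
    """One estimator's causal effect per SD of exposure.

    ``beta`` is a log odds ratio for binary outcomes; ``exp(beta)`` is then
    the odds ratio per SD. The 95% interval is beta -/+ 1.96 se.
    """

    method: str
    beta: float
    se: float
    n_snps: int
    pvalue: float = field(default=None)  # type: ignore[assignment]
    ci_low: float = field(default=None)  # type: ignore[assignment]
    ci_high: float = field(default=None)  # type: ignore[assignment]
    q: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    exposure: str = ""
    outcome: str = ""

    def __post_init__(self) -> None:
        if self.pvalue is None:
            self.pvalue = two_sided_p(self.beta, self.se) if self.se > 0 else 1.0
        if self.ci_low is None:
            self.ci_low = self.beta - Z95 * self.se
        if self.ci_high is None:
            self.ci_high = self.beta + Z95 * self.se

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "method": self.method,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "or": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "q": self.q,
            "q_pvalue": self.q_pvalue,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_p": self.egger_intercept_p,
        }


@dataclass
class LeaveOneOutResult:
    excluded_variant: str
    estimate: MREstimate


def _arrays(pairs: HarmonisedSet | Sequence[Sequence[float]]):
    if isinstance(pairs, HarmonisedSet):
        return (
            pairs.beta_exposure,
            pairs.se_exposure,
            pairs.beta_outcome,
            pairs.se_outcome,
        )
    arr = np.asarray(pairs, dtype=float)
    return arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]


def wald_ratio(
    beta_exposure: float,
    se_exposure: float,
    beta_outcome: float,
    se_outcome: float,
) -> MREstimate:
    """Single-variant causal estimate beta_y/beta_x.

    The SE is the first-order delta-method approximation se_y/|beta_x|,
    which ignores the exposure-side sampling error; it is accurate when the
    instrument is strong (F >> 10).
    """
    if beta_exposure == 0:
        raise EstimationError("Wald ratio undefined: beta_exposure is zero")
    beta = beta_outcome / beta_exposure
    se = se_outcome / abs(beta_exposure)
    return MREstimate(method=WALD_RATIO, beta=beta, se=se, n_snps=1)


def ivw(
    pairs: HarmonisedSet,
    effects_model: str = "multiplicative_random",
) -> MREstimate:
    """Inverse-variance-weighted estimate.

    Weighted regression of outcome betas on exposure betas with the
    intercept constrained to zero and weights 1/se_y^2:
    beta = sum(bx by / sy^2) / sum(bx^2 / sy^2). The fixed-effect SE is
    1/sqrt(sum(bx^2/sy^2)); the multiplicative-random-effects model inflates
    the variance by phi = max(1, Q/(k-1)). Cochran's Q is attached.

    A single pair collapses to the Wald ratio (labelled so).
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects model {effects_model!r}")
    bx, sx, by, sy = _arrays(pairs)
    k = bx.size
    if k == 0:
        raise NotEstimable("IVW requires at least one variant")
    if k == 1:
        return wald_ratio(bx[0], sx[0], by[0], sy[0])
    w = 1.0 / sy**2
    denom = float(np.sum(bx**2 * w))
    if denom == 0:
        raise EstimationError("IVW undefined: all exposure betas are zero")
    beta = float(np.sum(bx * by * w) / denom)
    se_fixed = 1.0 / math.sqrt(denom)
    q, q_df, q_p = cochran_q(pairs, beta)
    if effects_model == "multiplicative_random":
        phi = max(1.0, q / (k - 1.0))
        se = se_fixed * math.sqrt(phi)
        method = IVW_MRE
    else:
        se = se_fixed
        method = IVW_FIXED
    return MREstimate(
        method=method, beta=beta, se=se, n_snps=k, q=q, q_df=q_df, q_pvalue=q_p
    )


def mr_egger(pairs: HarmonisedSet) -> MREstimate:
    """MR-Egger regression: weighted regression of by on bx with free intercept.

    Pairs are first oriented so that every exposure beta is non-negative
    (jointly flipping the signs of bx and by leaves the causal model
    unchanged but makes the intercept interpretable as average directional
    pleiotropy). SEs are inflated by max(1, sqrt(RSS/(k-2))); p-values use
    the normal reference.
    """
    bx, sx, by, sy = _arrays(pairs)
    k = bx.size
    if k < 3:
        raise NotEstimable(f"MR-Egger requires >= 3 variants (got {k})")
    flip = np.where(bx < 0, -1.0, 1.0)
    bx = bx * flip
    by = by * flip
    w = 1.0 / sy**2
    # weighted least squares with intercept, solved via normal equations
    X = np.column_stack([np.ones(k), bx])
    XtW = X.T * w
    xtwx = XtW @ X
    try:
        cov_unscaled = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("MR-Egger design is singular (no spread in exposure betas)") from exc
    coef = cov_unscaled @ (XtW @ by)
    intercept, slope = float(coef[0]), float(coef[1])
    resid = by - X @ coef
    rss = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(rss / (k - 2.0)))
    se_intercept = math.sqrt(cov_unscaled[0, 0]) * scale
    se_slope = math.sqrt(cov_unscaled[1, 1]) * scale
    return MREstimate(
        method=EGGER,
        beta=slope,
        se=se_slope,
        n_snps=k,
        q=rss,
        q_df=k - 2,
        q_pvalue=float(stats.chi2.sf(rss, k - 2)),
        egger_intercept=intercept,
        egger_intercept_se=se_intercept,
        egger_intercept_p=two_sided_p(intercept, se_intercept),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of the cumulative-weight midpoints."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    p = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, p, r))


def weighted_median_point(pairs: HarmonisedSet) -> float:
    """Weighted-median point estimate only (no bootstrap SE)."""
    bx, _, by, sy = _arrays(pairs)
    if bx.size < 3:
        raise NotEstimable(f"weighted median requires >= 3 variants (got {bx.size})")
    return _weighted_median_point(by / bx, bx**2 / sy**2)


def weighted_median(
    pairs: HarmonisedSet,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted median of the per-variant ratio estimates.

    Ratios are weighted by bx^2/sy^2 (inverse variance of the first-order
    ratio); the estimate interpolates the ordered ratios at cumulative
    weight 0.5 and is consistent while invalid variants carry < 50% of the
    weight. The SE comes from a parametric bootstrap (``n_boot`` replicates
    resampling bx, by from their sampling distributions; ``seed`` is
    required for reproducibility).
    """
    bx, sx, by, sy = _arrays(pairs)
    k = bx.size
    if k < 3:
        raise NotEstimable(f"weighted median requires >= 3 variants (got {k})")
    if seed is None:
        raise ValueError("weighted_median requires an explicit bootstrap seed")
    ratios = by / bx
    weights = bx**2 / sy**2
    beta = _weighted_median_point(ratios, weights)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        with np.errstate(divide="ignore", invalid="ignore"):
            boot[b] = _weighted_median_point(by_b / bx_b, bx_b**2 / sy**2)
    se = float(np.std(boot, ddof=1))
    return MREstimate(method=WEIGHTED_MEDIAN, beta=beta, se=se, n_snps=k)


def cochran_q(pairs: HarmonisedSet, beta_ref: float) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity of the per-variant ratios around ``beta_ref``.

    Q = sum_j w_j (ratio_j - beta_ref)^2 with first-order weights
    w_j = bx_j^2 / sy_j^2; df = k - 1; upper-tail chi-square p-value.
    """
    bx, sx, by, sy = _arrays(pairs)
    k = bx.size
    if k < 2:
        raise NotEstimable("Cochran's Q requires >= 2 variants")
    ratios = by / bx
    w = bx**2 / sy**2
    q = float(np.sum(w * (ratios - beta_ref) ** 2))
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def leave_one_out(
    pairs: HarmonisedSet,
    effects_model: str = "multiplicative_random",
) -> list[LeaveOneOutResult]:
    """IVW re-estimated with each variant removed in turn.

    Large shifts of any leave-one-out estimate from the full-set estimate
    point at single influential (possibly pleiotropic) variants; see
    :func:`max_loo_deviation`.
    """
    k = pairs.n_snps
    if k < 3:
        raise NotEstimable(f"leave-one-out requires >= 3 variants (got {k})")
    ids = pairs.variant_ids
    results = []
    for i in range(k):
        mask = np.ones(k, dtype=bool)
        mask[i] = False
        est = ivw(pairs.subset(mask), effects_model=effects_model)
        results.append(LeaveOneOutResult(excluded_variant=str(ids[i]), estimate=est))
    return results


def max_loo_deviation(full: MREstimate, loo: Sequence[LeaveOneOutResult]) -> float:
    """Largest |leave-one-out beta - full-set beta| over all exclusions."""
    return max(abs(r.estimate.beta - full.beta) for r in loo)
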