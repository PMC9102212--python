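r"""The estimation core: Wald ratios, fixed-effects IVW, meta-analysis, Q.

For instrument :math:`j` with exposure association :math:`\hat\beta_{Xj}`
and outcome association :math:`\hat\beta_{Yj}`, the Wald ratio estimate of
the causal effect is :math:`\hat\theta_j = \hat\beta_{Yj}/\hat\beta_{Xj}`
with first-order standard error
:math:`\mathrm{se}(\hat\theta_j) = \mathrm{se}(\hat\beta_{Yj})/|\hat\beta_{Xj}|`.
The fixed-effects inverse-variance-weighted (IVW) estimate pools the
ratios with weights :math:`w_j = \mathrm{se}(\hat\theta_j)^{-2}`:

.. math::

    \hat\theta = \frac{\sum_j w_j \hat\theta_j}{\sum_j w_j},
    \qquad
    \mathrm{se}(\hat\theta) = \Big(\sum_j w_j\Big)^{-1/2},
    \qquad
    Q = \sum_j w_j (\hat\theta_j - \hat\theta)^2 .

Under homogeneity Q is chi-square with (elements - 1) degrees of freedom.
Fixed-effects meta-analysis of per-cohort estimates is the same arithmetic
applied to the cohort-level (beta, se) pairs. Everything here is
fixed-effects; no random-effects estimator is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrument

__all__ = [
    "RatioEstimate",
    "PooledEstimate",
    "wald_ratio",
    "ivw_pool",
    "fixed_effects_meta",
    "chisq_upper_p",
    "normal_two_sided_p",
    "to_or_scale",
]


@dataclass(frozen=True)
class RatioEstimate:
    """Per-variant Wald ratio: log-odds of outcome per exposure unit."""

    variant_id: str
    theta: float
    se_theta: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.theta):
            raise ValueError(f"{self.variant_id}: theta must be finite")
        if not (self.se_theta > 0 and math.isfinite(self.se_theta)):
            raise ValueError(f"{self.variant_id}: se_theta must be > 0 and finite")


@dataclass(frozen=True)
class PooledEstimate:
    """An IVW or meta-analysis result on the log-odds scale, with its
    odds-ratio-scale confidence interval and Cochran's Q heterogeneity.

    ``Q_p`` is None when ``Q_df == 0`` (heterogeneity is undefined for a
    single pooled element; it is reported blank, never as 1.0).
    """

    label: str
    outcome_name: str
    n_units: int
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    pvalue: float
    Q: float
    Q_df: int
    Q_p: Optional[float] = None
    alpha: float = field(default=0.05, compare=False)

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("pooled se must be > 0")
        if self.Q < -1e-12 or self.Q_df != self.n_units - 1:
            raise ValueError("inconsistent heterogeneity fields")
        if not (self.ci_low <= self.or_ <= self.ci_high):
            raise ValueError("CI must bracket the odds ratio")


def normal_two_sided_p(z: float) -> float:
    """Two-sided standard-normal p-value, 2 * P(Z >= |z|).

    Never truncated to zero: where the tail underflows double precision
    (|z| beyond ~38.5) the smallest positive subnormal is reported instead.
    """
    if not math.isfinite(z):
        raise ValueError("z must be finite")
    return max(float(2.0 * stats.norm.sf(abs(z))), 5e-324)


def chisq_upper_p(Q: float, df: int) -> float:
    """Upper-tail chi-square probability of a heterogeneity statistic.

    ``df = 0`` is undefined (one pooled element cannot be heterogeneous);
    callers report a blank, not 1.0.
    """
    if df < 1:
        raise ValueError("chi-square heterogeneity p is undefined for df < 1")
    if Q < 0:
        raise ValueError("Q must be >= 0")
    return float(stats.chi2.sf(Q, df))


def to_or_scale(beta: float, se: float, alpha: float = 0.05) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate into (OR, CI low, CI high).

    The confidence level is 1 - alpha; the normal quantile is exact
    (~1.959964 at alpha = 0.05), with rounding left to report time.
    """
    if se <= 0:
        raise ValueError("se must be > 0")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return (
        float(np.exp(beta)),
        float(np.exp(beta - z * se)),
        float(np.exp(beta + z * se)),
    )


def wald_ratio(inst: HarmonizedInstrument, second_order: bool = False) -> RatioEstimate:
    """Wald ratio for one harmonized instrument.

    The default standard error is the first-order delta method,
    se_outcome / |beta_exposure|, which ignores exposure-side sampling
    error; this is the convention under which fixed-effects IVW over the
    ratios reduces to the standard weighted formula. ``second_order=True``
    adds the exposure-side term
    sqrt(se_y^2/bx^2 + by^2 se_x^2 / bx^4).
    """
    if inst.excluded:
        raise ValueError(
            f"{inst.variant_id}: cannot form a ratio for an excluded instrument "
            f"({inst.exclusion_reason})"
        )
    bx = inst.beta_exposure
    if bx == 0:
        raise ZeroDivisionError(
            f"{inst.variant_id}: undefined Wald ratio (exposure beta is zero)"
        )
    theta = inst.beta_outcome / bx
    if second_order:
        se = math.sqrt(
            inst.se_outcome**2 / bx**2
            + inst.beta_outcome**2 * inst.se_exposure**2 / bx**4
        )
    else:
        se = inst.se_outcome / abs(bx)
    return RatioEstimate(variant_id=inst.variant_id, theta=theta, se_theta=se)


def _pool(
    betas: np.ndarray, ses: np.ndarray, alpha: float
) -> tuple[float, float, float, float, float, float, float, int, Optional[float]]:
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be > 0")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    pvalue = normal_two_sided_p(beta / se)
    or_, ci_low, ci_high = to_or_scale(beta, se, alpha)
    Q = float(np.sum(w * (betas - beta) ** 2))
    Q_df = len(betas) - 1
    Q_p = chisq_upper_p(Q, Q_df) if Q_df >= 1 else None
    return beta, se, or_, ci_low, ci_high, pvalue, Q, Q_df, Q_p


def ivw_pool(
    ratios: Sequence[RatioEstimate],
    alpha: float = 0.05,
    label: str = "IVW",
    outcome_name: str = "",
) -> PooledEstimate:
    """Fixed-effects inverse-variance-weighted pooling of Wald ratios.

    Weights are 1/se^2. A single ratio is returned unchanged (with Q = 0,
    df = 0 and no heterogeneity p).
    """
    if not ratios:
        raise ValueError("ivw_pool requires at least one ratio")
    betas = np.array([r.theta for r in ratios], dtype=float)
    ses = np.array([r.se_theta for r in ratios], dtype=float)
    beta, se, or_, lo, hi, p, Q, Q_df, Q_p = _pool(betas, ses, alpha)
    return PooledEstimate(
        label=label,
        outcome_name=outcome_name,
        n_units=len(ratios),
        beta=beta,
        se=se,
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        pvalue=p,
        Q=Q,
        Q_df=Q_df,
        Q_p=Q_p,
        alpha=alpha,
    )


def fixed_effects_meta(
    estimates: Sequence[PooledEstimate],
    alpha: float = 0.05,
    label: str = "META",
) -> PooledEstimate:
    """Fixed-effects meta-analysis of per-cohort pooled estimates.

    Identical arithmetic to :func:`ivw_pool`, applied to the cohort-level
    (beta, se) pairs; Cochran's Q here measures between-cohort
    heterogeneity. All inputs must share one ``outcome_name``.
    """
    if not estimates:
        raise ValueError("fixed_effects_meta requires at least one estimate")
    outcomes = {e.outcome_name for e in estimates}
    if len(outcomes) != 1:
        raise ValueError(f"cannot meta-analyze mixed outcomes: {sorted(outcomes)}")
    betas = np.array([e.beta for e in estimates], dtype=float)
    ses = np.array([e.se for e in estimates], dtype=float)
    beta, se, or_, lo, hi, p, Q, Q_df, Q_p = _pool(betas, ses, alpha)
    return PooledEstimate(
        label=label,
        outcome_name=outcomes.pop(),
        n_units=len(estimates),
        beta=beta,
        se=se,
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        pvalue=p,
        Q=Q,
        Q_df=Q_df,
        Q_p=Q_p,
        alpha=alpha,
    )
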