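"""Sensitivity analysis and publication-bias diagnostics.

* :func:`leave_one_out` re-pools the meta-analysis K times, omitting one
  study at a time, to show how much any single study drives the result.
* :func:`funnel_coordinates` exports the funnel-plot scatter (log-OR vs SE)
  with each study's side of the pooled centre.
* :func:`egger_test` regresses the standardized effect theta_i/se_i on the
  precision 1/se_i; a non-zero intercept (two-sided t-test on k-2 df)
  indicates small-study asymmetry.
* :func:`begg_test` is the rank-correlation test: Kendall's tau between
  variance-stabilized effect deviates and the study variances, with an
  exact null P for small k (<= 10, no ties) and a tie-corrected normal
  approximation otherwise.
* :func:`trim_and_fill` is the iterative Duval–Tweedie procedure with the
  L0 estimator of the number of suppressed studies and fixed-effect
  centring; the adjusted pooled estimate includes all original studies
  plus the imputed mirror images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import kendalltau

from .genetic_contrasts import EffectEstimate
from .pooling import (
    HeterogeneityResult,
    PooledResult,
    heterogeneity,
    pool_fixed_iv,
    pool_random_dl,
    select_model,
)

__all__ = [
    "LeaveOneOutRow",
    "FunnelPoint",
    "EggerResult",
    "BeggResult",
    "TrimFillResult",
    "DegenerateRegressionError",
    "leave_one_out",
    "funnel_coordinates",
    "egger_test",
    "begg_test",
    "trim_and_fill",
]


class DegenerateRegressionError(ValueError):
    """Egger regression has no information (constant precision and effect)."""


@dataclass(frozen=True)
class LeaveOneOutRow:
    omitted_study_id: str
    pooled: PooledResult
    het: HeterogeneityResult


@dataclass(frozen=True)
class FunnelPoint:
    study_id: str
    log_or: float
    se: float
    side: str  # "left" | "right"; a study exactly at the centre counts right


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    intercept_se: float
    t: float
    p: float
    slope: float
    k: int


@dataclass(frozen=True)
class BeggResult:
    kendall_tau: float
    p: float
    k: int


@dataclass(frozen=True)
class TrimFillResult:
    k0: int
    side: str  # side of the funnel on which studies were imputed
    filled_effects: list[EffectEstimate]
    adjusted: PooledResult           # rule-selected (fixed/random) on k + k0
    adjusted_fixed: PooledResult
    adjusted_random: Optional[PooledResult]
    iterations: int


def _require_k(effects: Sequence[EffectEstimate], k_min: int, op: str) -> None:
    if len(effects) < k_min:
        raise ValueError(f"{op} requires at least {k_min} studies, got {len(effects)}")


def leave_one_out(effects: Sequence[EffectEstimate], pooling: str = "auto",
                  i2_threshold: float = 50.0, p_threshold: float = 0.10,
                  ) -> list[LeaveOneOutRow]:
    """Re-pool the set K times, omitting each study in turn.

    ``pooling`` is ``"auto"`` (re-apply the heterogeneity selection rule to
    each reduced set), ``"fixed"`` or ``"random"``.
    """
    _require_k(effects, 3, "leave_one_out")
    if pooling not in ("auto", "fixed", "random"):
        raise ValueError(f"unknown pooling policy {pooling!r}")
    rows = []
    for i, omitted in enumerate(effects):
        reduced = [e for j, e in enumerate(effects) if j != i]
        fixed = pool_fixed_iv(reduced)
        het = fixed.het
        method = pooling
        if pooling == "auto":
            method = select_model(het, i2_threshold, p_threshold)
        pooled = fixed if method == "fixed" else pool_random_dl(reduced)
        rows.append(LeaveOneOutRow(omitted.study_id, pooled, het))
    return rows


def funnel_coordinates(effects: Sequence[EffectEstimate],
                       center: float) -> list[FunnelPoint]:
    """Funnel-plot coordinates with side relative to the pooled centre."""
    return [
        FunnelPoint(
            study_id=e.study_id,
            log_or=e.log_or,
            se=e.se,
            side="right" if e.log_or >= center else "left",
        )
        for e in effects
    ]


def egger_test(effects: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's regression test of funnel asymmetry (k >= 3).

    OLS of y_i = theta_i/se_i on x_i = 1/se_i; the intercept is tested
    against zero with a two-sided t-test on k-2 degrees of freedom.
    """
    _require_k(effects, 3, "egger_test")
    se = np.array([e.se for e in effects])
    theta = np.array([e.log_or for e in effects])
    x = 1.0 / se
    y = theta / se
    if np.ptp(x) == 0:
        raise DegenerateRegressionError(
            "all standard errors are equal; the precision regressor is constant")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    t = float(res.tvalues[0])
    p = float(res.pvalues[0])
    if not math.isfinite(t):  # perfect fit: zero residual variance
        p = 0.0
    return EggerResult(
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        t=t,
        p=p,
        slope=float(res.params[1]),
        k=len(effects),
    )


def begg_test(effects: Sequence[EffectEstimate],
              pooled_log_or: float) -> BeggResult:
    """Begg–Mazumdar rank-correlation test for publication bias (k >= 3).

    Correlates the variance-stabilized deviates
    v_i = (theta_i - pooled) / sqrt(se_i^2 - 1/sum(w)) with the variances
    se_i^2 using Kendall's tau.  The null P is exact for k <= 10 when there
    are no ties and a tie-corrected normal approximation otherwise.  With
    all variances identical, tau is reported as 0 (fully tied x-ranks).
    """
    _require_k(effects, 3, "begg_test")
    se = np.array([e.se for e in effects])
    theta = np.array([e.log_or for e in effects])
    var = se ** 2
    sw = float(np.sum(1.0 / var))
    vstar = var - 1.0 / sw  # strictly positive for k >= 2
    v = (theta - pooled_log_or) / np.sqrt(vstar)
    no_ties = len(np.unique(var)) == len(var) and len(np.unique(v)) == len(v)
    method = "exact" if (len(effects) <= 10 and no_ties) else "asymptotic"
    tau, p = kendalltau(var, v, method=method)
    if math.isnan(tau):  # all x or all y tied: no ordering information
        return BeggResult(kendall_tau=0.0, p=1.0, k=len(effects))
    return BeggResult(kendall_tau=float(tau), p=float(p), k=len(effects))


def _ordinal_ranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n of ``values`` ascending; ties broken by input order."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def _iv_center(theta: np.ndarray, var: np.ndarray) -> float:
    w = 1.0 / var
    return float(np.sum(w * theta) / np.sum(w))


def trim_and_fill(effects: Sequence[EffectEstimate], side: str = "auto",
                  estimator: str = "L0", max_iter: int = 100) -> TrimFillResult:
    """Duval–Tweedie trim-and-fill with the L0 estimator (k >= 3).

    ``side`` names the funnel side believed to be missing studies (where
    imputed mirror studies will be *filled*); ``"auto"`` picks the side with
    the smaller rank-sum of absolute centred effects.  The iteration trims
    the k0 most extreme studies on the opposite (over-represented) side,
    re-centres with fixed-effect (inverse-variance) pooling, and repeats
    until k0 stabilizes; k0 mirror-image studies (reflected log-OR, same SE)
    are then added and the full set of k + k0 studies is re-pooled under
    both fixed and random effects.
    """
    _require_k(effects, 3, "trim_and_fill")
    if estimator != "L0":
        raise ValueError("only the L0 estimator is implemented")
    if side not in ("auto", "left", "right"):
        raise ValueError(f"unknown side {side!r}")

    theta = np.array([e.log_or for e in effects])
    var = np.array([e.se for e in effects]) ** 2
    n = len(effects)

    if side == "auto":
        c0 = _iv_center(theta, var)
        ranks = _ordinal_ranks(np.abs(theta - c0))
        t_right = ranks[theta - c0 > 0].sum()
        t_left = ranks[theta - c0 < 0].sum()
        side = "left" if t_right > t_left else "right"

    # Work on a signed scale where the over-represented side is positive.
    sign = 1.0 if side == "left" else -1.0
    vals = sign * theta
    order = np.argsort(vals, kind="stable")  # ascending; trim from the top

    k0 = 0
    iterations = 0
    while iterations < max_iter:
        iterations += 1
        keep = order[: n - k0]
        center = _iv_center(vals[keep], var[keep])
        centered = vals - center
        ranks = _ordinal_ranks(np.abs(centered))
        t_sum = ranks[centered > 0].sum()
        k0_new = (4.0 * t_sum - n * (n + 1)) / (2.0 * n - 1.0)
        k0_new = int(max(0, math.floor(k0_new + 0.5)))
        k0_new = min(k0_new, n - 2)  # keep at least two studies for centring
        if k0_new == k0:
            break
        k0 = k0_new

    keep = order[: n - k0]
    center = _iv_center(vals[keep], var[keep])
    trimmed = order[n - k0:] if k0 > 0 else np.array([], dtype=int)
    filled = [
        EffectEstimate.from_log_or(
            f"fill_{j + 1}",
            sign * (2.0 * center - vals[i]),
            math.sqrt(var[i]),
        )
        for j, i in enumerate(trimmed)
    ]
    augmented = list(effects) + filled
    adj_fixed = pool_fixed_iv(augmented)
    adj_random = pool_random_dl(augmented) if len(augmented) >= 2 else None
    adjusted = adj_fixed
    if adj_random is not None and select_model(adj_fixed.het) == "random":
        adjusted = adj_random
    return TrimFillResult(
        k0=k0,
        side=side,
        filled_effects=filled,
        adjusted=adjusted,
        adjusted_fixed=adj_fixed,
        adjusted_random=adj_random,
        iterations=iterations,
    )
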