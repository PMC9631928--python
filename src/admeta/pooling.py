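"""Fixed- and random-effects pooling of per-study odds ratios.

Three estimators are provided:

* ``fixed_mh``  — Mantel–Haenszel on the raw 2x2 tables, with the
  Robins–Breslow–Greenland variance for ln(OR_MH);
* ``fixed_iv``  — inverse-variance weighting of per-study log-ORs;
* ``random_dl`` — DerSimonian–Laird moment estimator of the between-study
  variance tau^2, with weights 1/(se_i^2 + tau^2).

Heterogeneity is quantified by Cochran's Q (inverse-variance weights
against the pooled centre), its chi-square P on K-1 degrees of freedom,
and I^2 = max(0, (Q - (K-1))/Q) x 100%.  The conventional selection rule
chooses the random-effects model exactly when p_Q < 0.10 and I^2 > 50%
(strict inequalities), and the fixed-effect model otherwise.

In Mantel–Haenszel pooling, Q/I^2 are computed with inverse-variance
weights on the per-study log-ORs against the MH centre — the convention
of mainstream meta-analysis software — which can shift I^2 slightly
relative to IV-centred Q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy.stats import chi2, norm

from .genetic_contrasts import Z_95, EffectEstimate, TwoByTwo, odds_ratio

__all__ = [
    "HeterogeneityResult",
    "PooledResult",
    "pool_fixed_iv",
    "pool_fixed_mh",
    "pool_random_dl",
    "heterogeneity",
    "select_model",
    "z_test",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    q: float
    df: int
    p_q: float
    i2: float      # percent, floored at 0
    tau2: float    # DerSimonian–Laird moment estimate

    @property
    def has_heterogeneity(self) -> bool:
        return self.q > 0


_NO_HET = HeterogeneityResult(q=0.0, df=0, p_q=1.0, i2=0.0, tau2=0.0)


@dataclass(frozen=True)
class PooledResult:
    method: str    # fixed_mh | fixed_iv | random_dl
    k: int
    log_or: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    z: float
    p_z: float
    het: HeterogeneityResult
    weights: dict[str, float]  # study_id -> normalized weight


def z_test(pooled_log_or: float, se: float) -> tuple[float, float]:
    """Wald Z statistic and two-sided P for a pooled log odds ratio."""
    if se <= 0:
        raise ValueError("se must be positive")
    z = pooled_log_or / se
    return z, 2 * float(norm.sf(abs(z)))


def _finish(method: str, effects_ids: Sequence[str], log_or: float, se: float,
            het: HeterogeneityResult, raw_weights: Sequence[float]) -> PooledResult:
    total = sum(raw_weights)
    z, p = z_test(log_or, se)
    return PooledResult(
        method=method,
        k=len(effects_ids),
        log_or=log_or,
        se=se,
        or_value=math.exp(log_or),
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        z=z,
        p_z=p,
        het=het,
        weights={sid: w / total for sid, w in zip(effects_ids, raw_weights)},
    )


def _check_effects(effects: Sequence[EffectEstimate], k_min: int, op: str) -> None:
    if any(e.is_dropped for e in effects):
        dropped = [e.study_id for e in effects if e.is_dropped]
        raise ValueError(f"{op}: dropped studies must be excluded first: {dropped}")
    if len(effects) < k_min:
        hint = "; use fixed-effect pooling for a single study" if k_min == 2 else ""
        raise ValueError(f"{op} requires at least {k_min} studies, got {len(effects)}{hint}")
    if any(e.se <= 0 for e in effects):
        raise ValueError(f"{op}: all standard errors must be positive")


def heterogeneity(effects: Sequence[EffectEstimate],
                  pooled_log_or: float) -> HeterogeneityResult:
    """Cochran's Q, I^2 and the DL tau^2 against a given pooled centre."""
    _check_effects(effects, 2, "heterogeneity")
    w = [1.0 / e.variance for e in effects]
    q = sum(wi * (e.log_or - pooled_log_or) ** 2 for wi, e in zip(w, effects))
    df = len(effects) - 1
    p_q = float(chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    sw = sum(w)
    denom = sw - sum(wi ** 2 for wi in w) / sw
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, p_q=p_q, i2=i2, tau2=tau2)


def pool_fixed_iv(effects: Sequence[EffectEstimate]) -> PooledResult:
    """Inverse-variance fixed-effect pooling of log odds ratios."""
    _check_effects(effects, 1, "pool_fixed_iv")
    w = [1.0 / e.variance for e in effects]
    sw = sum(w)
    pooled = sum(wi * e.log_or for wi, e in zip(w, effects)) / sw
    se = 1.0 / math.sqrt(sw)
    het = heterogeneity(effects, pooled) if len(effects) >= 2 else _NO_HET
    return _finish("fixed_iv", [e.study_id for e in effects], pooled, se, het, w)


def pool_random_dl(effects: Sequence[EffectEstimate]) -> PooledResult:
    """DerSimonian–Laird random-effects pooling (requires k >= 2)."""
    _check_effects(effects, 2, "pool_random_dl")
    fixed = pool_fixed_iv(effects)
    tau2 = fixed.het.tau2
    w_star = [1.0 / (e.variance + tau2) for e in effects]
    sw = sum(w_star)
    pooled = sum(wi * e.log_or for wi, e in zip(w_star, effects)) / sw
    se = 1.0 / math.sqrt(sw)
    return _finish("random_dl", [e.study_id for e in effects], pooled, se,
                   fixed.het, w_star)


def pool_fixed_mh(tables: Sequence[TwoByTwo],
                  study_ids: Optional[Sequence[str]] = None,
                  correction: float = 0.5) -> PooledResult:
    """Mantel–Haenszel fixed-effect pooling of raw 2x2 tables.

    Tables with an all-zero exposure or reference column are information-
    free and excluded.  Remaining tables with a zero cell receive the same
    any-zero continuity correction as per-study estimation, both in the MH
    sums and in the per-study log-ORs used for Q.  The SE of ln(OR_MH) is
    the Robins–Breslow–Greenland variance.
    """
    if study_ids is None:
        study_ids = [f"study_{i+1}" for i in range(len(tables))]
    if len(study_ids) != len(tables):
        raise ValueError("study_ids must align with tables")

    usable: list[tuple[str, TwoByTwo]] = []
    for sid, t in zip(study_ids, tables):
        if (t.b == 0 and t.d == 0) or (t.a == 0 and t.c == 0):
            continue
        usable.append((sid, t))
    if not usable:
        raise ValueError("pool_fixed_mh: every table has an all-zero margin")

    R = S = 0.0
    sum_pr = sum_psqr = sum_qs = 0.0
    s_weights = []
    effects = []
    for sid, t in usable:
        a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
        if min(a, b, c, d) == 0:
            a, b, c, d = (x + correction for x in (a, b, c, d))
        n = a + b + c + d
        r_i, s_i = a * d / n, b * c / n
        p_i, q_i = (a + d) / n, (b + c) / n
        R += r_i
        S += s_i
        sum_pr += p_i * r_i
        sum_psqr += p_i * s_i + q_i * r_i
        sum_qs += q_i * s_i
        s_weights.append(s_i)
        effects.append(odds_ratio(t, correction=correction, study_id=sid))
    if R == 0 or S == 0:
        raise ValueError("pool_fixed_mh: Mantel–Haenszel odds ratio is degenerate (0 or infinite)")
    log_or = math.log(R / S)
    var = sum_pr / (2 * R * R) + sum_psqr / (2 * R * S) + sum_qs / (2 * S * S)
    se = math.sqrt(var)
    het = heterogeneity(effects, log_or) if len(effects) >= 2 else _NO_HET
    return _finish("fixed_mh", [sid for sid, _ in usable], log_or, se, het, s_weights)


def select_model(het: HeterogeneityResult, i2_threshold: float = 50.0,
                 p_threshold: float = 0.10) -> str:
    """Heterogeneity-driven estimator choice.

    Returns ``"random"`` iff p_Q < ``p_threshold`` AND I^2 > ``i2_threshold``
    (both strict), else ``"fixed"``.
    """
    if het.p_q < p_threshold and het.i2 > i2_threshold:
        return "random"
    return "fixed"
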