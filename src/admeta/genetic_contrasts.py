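"""Genetic-model contrasts and per-study odds-ratio estimation.

For a biallelic SNP with major allele G and minor allele C, each study's
genotype counts are collapsed into an exposure-by-status 2x2 table under
one of four genetic models:

* ``allele``    — C allele vs G allele (each subject contributes 2 alleles)
* ``dominant``  — GG+GC vs CC
* ``recessive`` — GG vs GC+CC
* ``additive``  — GG+CC vs GC (homozygotes vs heterozygotes)

The allele-model exposure defaults to the minor allele C, so OR > 1 means
carrying C increases risk; the orientation is switchable because some
reports label the same contrast "G vs. C".

Per-study odds ratios use the cross-product with the Woolf standard error
``sqrt(1/a + 1/b + 1/c + 1/d)``.  When any cell is zero, a continuity
correction (default 0.5) is added to all four cells at estimation time;
tables with an all-zero exposure or reference column carry no information
about the odds ratio and are marked *dropped* instead of estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from scipy.stats import norm

from .study_io import GenotypeCounts, StudyRecord

__all__ = [
    "GeneticModel",
    "TwoByTwo",
    "EffectEstimate",
    "ContrastUnavailableError",
    "Z_95",
    "allele_counts",
    "build_contrast",
    "odds_ratio",
    "se_from_ci",
    "p_from_or_ci",
]

#: Normal quantile used for all 95% intervals (kept at full precision so
#: that OR/CI/P round-trips reproduce bit-for-bit).
Z_95 = float(norm.ppf(0.975))  # 1.959963984540054


class ContrastUnavailableError(ValueError):
    """Raised when a study lacks the genotype counts a contrast needs."""


class GeneticModel(str, Enum):
    ALLELE = "allele"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    ADDITIVE = "additive"

    @property
    def exposure_label(self) -> str:
        return _LABELS[self][0]

    @property
    def reference_label(self) -> str:
        return _LABELS[self][1]


_LABELS = {
    GeneticModel.ALLELE: ("C allele", "G allele"),
    GeneticModel.DOMINANT: ("GG+GC", "CC"),
    GeneticModel.RECESSIVE: ("GG", "GC+CC"),
    GeneticModel.ADDITIVE: ("GG+CC", "GC"),
}


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-status table: a/b = exposed/reference cases, c/d controls.

    Cells are integers as built from genotype counts; they become reals only
    after a continuity correction inside :func:`odds_ratio`.
    """

    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def swapped_exposure(self) -> "TwoByTwo":
        """The same table with exposure and reference columns exchanged."""
        return TwoByTwo(self.b, self.a, self.d, self.c)


@dataclass(frozen=True)
class EffectEstimate:
    """Per-study log odds ratio with Woolf SE and 95% CI."""

    study_id: str
    log_or: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    corrected: bool = False
    k_dropped_reason: Optional[str] = None

    @classmethod
    def from_log_or(cls, study_id: str, log_or: float, se: float,
                    corrected: bool = False) -> "EffectEstimate":
        if se <= 0:
            raise ValueError(f"se must be positive, got {se}")
        return cls(
            study_id=study_id,
            log_or=log_or,
            se=se,
            or_value=math.exp(log_or),
            ci_low=math.exp(log_or - Z_95 * se),
            ci_high=math.exp(log_or + Z_95 * se),
            corrected=corrected,
        )

    @classmethod
    def dropped(cls, study_id: str, reason: str) -> "EffectEstimate":
        nan = float("nan")
        return cls(study_id, nan, nan, nan, nan, nan, k_dropped_reason=reason)

    @property
    def is_dropped(self) -> bool:
        return self.k_dropped_reason is not None

    @property
    def variance(self) -> float:
        return self.se ** 2


def allele_counts(g: GenotypeCounts) -> tuple[int, int]:
    """(G alleles, C alleles) under autosomal diploid counting."""
    return (2 * g.gg + g.gc, 2 * g.cc + g.gc)


def build_contrast(record: StudyRecord, model: GeneticModel | str,
                   allele_exposure: str = "C") -> TwoByTwo:
    """Collapse a study's genotype counts into a 2x2 table for ``model``.

    ``allele_exposure`` ("C" or "G") only affects the allele model; the
    default treats the minor allele C as the exposure.
    """
    model = GeneticModel(model)
    if not record.has_genotypes:
        raise ContrastUnavailableError(
            f"study {record.study_id!r} has no genotype counts; "
            f"cannot build the {model.value} contrast"
        )
    case = record.case_genotypes
    ctrl = record.control_genotypes
    if model is GeneticModel.ALLELE:
        if allele_exposure not in ("C", "G"):
            raise ValueError("allele_exposure must be 'C' or 'G'")
        case_g, case_c = allele_counts(case)
        ctrl_g, ctrl_c = allele_counts(ctrl)
        if allele_exposure == "C":
            return TwoByTwo(case_c, case_g, ctrl_c, ctrl_g)
        return TwoByTwo(case_g, case_c, ctrl_g, ctrl_c)
    if model is GeneticModel.DOMINANT:
        return TwoByTwo(case.gg + case.gc, case.cc, ctrl.gg + ctrl.gc, ctrl.cc)
    if model is GeneticModel.RECESSIVE:
        return TwoByTwo(case.gg, case.gc + case.cc, ctrl.gg, ctrl.gc + ctrl.cc)
    # additive: homozygotes vs heterozygotes
    return TwoByTwo(case.gg + case.cc, case.gc, ctrl.gg + ctrl.cc, ctrl.gc)


def odds_ratio(t: TwoByTwo, correction: float = 0.5,
               policy: str = "any-zero-add-to-all",
               study_id: str = "") -> EffectEstimate:
    """Odds ratio of a 2x2 table with Woolf SE and continuity correction.

    Under the default ``any-zero-add-to-all`` policy, ``correction`` is
    added to all four cells whenever any cell is zero.  A table whose
    exposure column (a and c) or reference column (b and d) is entirely
    zero is returned as a dropped estimate with ``k_dropped_reason`` set.
    """
    if policy not in ("any-zero-add-to-all", "none"):
        raise ValueError(f"unknown correction policy {policy!r}")
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if b == 0 and d == 0:
        return EffectEstimate.dropped(study_id, "no subjects in the reference category in either arm")
    if a == 0 and c == 0:
        return EffectEstimate.dropped(study_id, "no subjects in the exposure category in either arm")
    corrected = False
    if min(a, b, c, d) == 0:
        if policy == "none" or correction <= 0:
            raise ValueError(
                "zero cell with no continuity correction; "
                "use the any-zero-add-to-all policy or a positive correction"
            )
        a, b, c, d = a + correction, b + correction, c + correction, d + correction
        corrected = True
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate.from_log_or(study_id, log_or, se, corrected=corrected)


def se_from_ci(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Recover the log-scale SE from a printed OR confidence interval."""
    if ci_low <= 0 or ci_high <= 0:
        raise ValueError("confidence bounds must be positive")
    if ci_low > ci_high:
        raise ValueError("ci_low must not exceed ci_high")
    z = float(norm.ppf(0.5 + level / 2))
    return (math.log(ci_high) - math.log(ci_low)) / (2 * z)


def p_from_or_ci(or_value: float, ci_low: float, ci_high: float,
                 level: float = 0.95) -> float:
    """Two-sided Z-test P recovered from a printed (OR, CI) pair."""
    if not (0 < ci_low <= or_value <= ci_high):
        raise ValueError("require 0 < ci_low <= or_value <= ci_high")
    se = se_from_ci(ci_low, ci_high, level=level)
    if se == 0:
        if or_value == 1.0:
            return 1.0
        raise ValueError("degenerate CI with a non-null odds ratio")
    z = math.log(or_value) / se
    return 2 * float(norm.sf(abs(z)))
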