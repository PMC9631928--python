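"""Synthetic case-control genotype studies with known truth.

The generator emulates the statistical structure a SNP meta-analysis
assumes: ``k_studies`` independent case-control studies at one biallelic
SNP (major G, minor C).  Control genotypes follow Hardy–Weinberg
proportions at a given minor-allele frequency; case genotypes are the
control distribution tilted multiplicatively by exp(d * theta_j) for d
copies of C, where each study's true per-allele log odds ratio theta_j is
drawn from Normal(ln OR, tau^2).  Under this log-additive risk model the
case arm is again Hardy–Weinberg at a shifted allele frequency, so the
induced allele-model odds ratio equals exp(theta_j) exactly, and the
induced dominant/recessive/additive contrasts have closed forms via
:func:`induced_log_or`.

Each study draws from its own deterministic substream, so adding a study
to a configuration never perturbs the studies before it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genetic_contrasts import GeneticModel, TwoByTwo, odds_ratio
from .study_io import CohortTable, GenotypeCounts, StudyRecord

__all__ = [
    "SimulationConfig",
    "control_genotype_probs",
    "case_genotype_probs",
    "induced_log_or",
    "simulate_meta",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative truth for one simulated meta-analysis.

    maf is the control-population frequency of the minor allele C;
    or_per_allele is the grand-mean multiplicative per-C-allele odds
    ratio; tau2 is the between-study variance of the true log-OR.
    Arm-size ranges are inclusive integer intervals.
    """

    k_studies: int
    maf: float = 0.3
    or_per_allele: float = 1.3
    tau2: float = 0.04
    n_case_range: tuple[int, int] = (500, 2000)
    n_control_range: tuple[int, int] = (500, 2000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_studies < 1:
            raise ValueError("k_studies must be positive")
        if not 0.0 < self.maf < 1.0:
            raise ValueError("maf must lie strictly inside (0, 1)")
        if self.or_per_allele <= 0:
            raise ValueError("or_per_allele must be positive")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        for name, (lo, hi) in (("n_case_range", self.n_case_range),
                               ("n_control_range", self.n_control_range)):
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be a non-empty positive interval")


def control_genotype_probs(maf: float) -> np.ndarray:
    """Hardy–Weinberg genotype probabilities (GG, GC, CC) at C-frequency maf."""
    if not 0.0 < maf < 1.0:
        raise ValueError("maf must lie strictly inside (0, 1)")
    g = 1.0 - maf
    return np.array([g * g, 2.0 * maf * g, maf * maf])


def case_genotype_probs(control_probs: np.ndarray, study_log_or: float) -> np.ndarray:
    """Case genotype probabilities under a multiplicative per-allele effect.

    The genotype with d copies of C gets unnormalized weight
    control_prob * exp(d * study_log_or); the result is renormalized.
    """
    probs = np.asarray(control_probs, dtype=float)
    if probs.shape != (3,) or np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("control_probs must be a probability vector over (GG, GC, CC)")
    w = probs * np.exp(np.arange(3) * study_log_or)
    return w / w.sum()


def induced_log_or(model: GeneticModel | str, maf: float,
                   study_log_or: float, allele_exposure: str = "C") -> float:
    """Population log-OR induced on a genetic-model contrast by the truth.

    Computed from the expected genotype proportions of the two arms, so it
    is the value the corresponding per-study estimator is consistent for.
    """
    model = GeneticModel(model)
    p0 = control_genotype_probs(maf)
    p1 = case_genotype_probs(p0, study_log_or)
    if model is GeneticModel.ALLELE:
        case_c = p1[2] * 2 + p1[1]
        case_g = p1[0] * 2 + p1[1]
        ctrl_c = p0[2] * 2 + p0[1]
        ctrl_g = p0[0] * 2 + p0[1]
        if allele_exposure == "C":
            t = TwoByTwo(case_c, case_g, ctrl_c, ctrl_g)
        else:
            t = TwoByTwo(case_g, case_c, ctrl_g, ctrl_c)
    elif model is GeneticModel.DOMINANT:
        t = TwoByTwo(p1[0] + p1[1], p1[2], p0[0] + p0[1], p0[2])
    elif model is GeneticModel.RECESSIVE:
        t = TwoByTwo(p1[0], p1[1] + p1[2], p0[0], p0[1] + p0[2])
    else:
        t = TwoByTwo(p1[0] + p1[2], p1[1], p0[0] + p0[2], p0[1])
    return odds_ratio(t, policy="none", correction=0.0).log_or


def _study_rng(seed: int, index: int) -> np.random.Generator:
    # Deterministic per-study substream: independent of k_studies, so
    # appending studies never changes earlier ones.
    return np.random.default_rng(np.random.SeedSequence([abs(int(seed)), int(index)]))


def simulate_meta(config: SimulationConfig) -> CohortTable:
    """Simulate a full meta-analysis input table from a known truth."""
    grand_log_or = math.log(config.or_per_allele)
    sd = math.sqrt(config.tau2)
    p_ctrl = control_genotype_probs(config.maf)
    studies = []
    for i in range(config.k_studies):
        rng = _study_rng(config.seed, i)
        n_case = int(rng.integers(config.n_case_range[0], config.n_case_range[1] + 1))
        n_control = int(rng.integers(config.n_control_range[0], config.n_control_range[1] + 1))
        theta = rng.normal(grand_log_or, sd) if sd > 0 else grand_log_or
        p_case = case_genotype_probs(p_ctrl, theta)
        ctrl_counts = rng.multinomial(n_control, p_ctrl)
        case_counts = rng.multinomial(n_case, p_case)
        studies.append(StudyRecord(
            study_id=f"sim{i + 1:03d}",
            population="synthetic",
            n_case=n_case,
            n_control=n_control,
            case_genotypes=GenotypeCounts(*map(int, case_counts)),
            control_genotypes=GenotypeCounts(*map(int, ctrl_counts)),
        ))
    return CohortTable(studies=studies, label=f"simulated_seed{config.seed}")
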