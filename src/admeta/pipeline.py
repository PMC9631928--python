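"""Full analysis orchestration and structured report export.

:func:`run_analysis` takes a cohort table and, for each requested genetic
model: builds per-study contrasts (accepting precomputed log-OR/SE rows
for the allele model only), pools under both a fixed-effect estimator
(Mantel–Haenszel on raw tables, inverse-variance otherwise) and
DerSimonian–Laird random effects, applies the heterogeneity-driven
selection rule, and — when at least three studies are usable — runs the
leave-one-out sensitivity analysis and the publication-bias battery
(funnel coordinates, Egger, Begg, trim-and-fill).

:func:`export_report` writes ``report.json`` (full precision) plus
plot-ready per-model CSV tables (forest, funnel, leave-one-out) with
display rounding: ORs/CIs to 2 decimals, P-values in scientific notation
with 3 significant digits.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .genetic_contrasts import (
    EffectEstimate,
    GeneticModel,
    TwoByTwo,
    build_contrast,
    odds_ratio,
)
from .pooling import (
    HeterogeneityResult,
    PooledResult,
    pool_fixed_iv,
    pool_fixed_mh,
    pool_random_dl,
    select_model,
)
from .robustness import (
    BeggResult,
    DegenerateRegressionError,
    EggerResult,
    FunnelPoint,
    LeaveOneOutRow,
    TrimFillResult,
    begg_test,
    egger_test,
    funnel_coordinates,
    leave_one_out,
    trim_and_fill,
)
from .study_io import (
    CohortTable,
    ValidationError,
    ValidationFinding,
    cohort_totals,
    validate_table,
)

__all__ = [
    "AnalysisOptions",
    "ModelSection",
    "AnalysisReport",
    "run_analysis",
    "export_report",
    "fmt_or",
    "fmt_p",
]

log = logging.getLogger("admeta")

ALL_MODELS = ("allele", "dominant", "recessive", "additive")


def fmt_or(x: float) -> str:
    """Display rounding for ORs and CI bounds."""
    return f"{x:.2f}"


def fmt_p(p: float) -> str:
    """P-value display: scientific notation, 3 significant digits."""
    return f"{p:.2E}"


@dataclass(frozen=True)
class AnalysisOptions:
    """Resolved settings; the snapshot stored in the report reproduces it."""

    models: tuple[str, ...] = ALL_MODELS
    pooling: str = "auto"            # auto | fixed | random
    fixed_estimator: str = "auto"    # auto | mh | iv
    correction: float = 0.5
    allele_exposure: str = "C"       # C (minor-allele exposure) | G
    trimfill_side: str = "auto"      # auto | left | right
    i2_threshold: float = 50.0
    p_threshold: float = 0.10
    allow_invalid: bool = False      # run despite error-severity findings


@dataclass
class ModelSection:
    """Everything computed for one genetic model."""

    model: str
    n_studies_used: int = 0
    dropped: list[tuple[str, str]] = field(default_factory=list)
    effects: list[EffectEstimate] = field(default_factory=list)
    fixed: Optional[PooledResult] = None
    random: Optional[PooledResult] = None
    selected: Optional[str] = None
    het: Optional[HeterogeneityResult] = None
    loo: list[LeaveOneOutRow] = field(default_factory=list)
    funnel: list[FunnelPoint] = field(default_factory=list)
    egger: Optional[EggerResult] = None
    begg: Optional[BeggResult] = None
    trimfill: Optional[TrimFillResult] = None
    error: Optional[str] = None

    @property
    def selected_result(self) -> Optional[PooledResult]:
        if self.selected is None:
            return None
        return self.fixed if self.selected == "fixed" else self.random


@dataclass
class AnalysisReport:
    input_label: str
    totals: tuple[int, int]
    validation: list[ValidationFinding]
    settings: AnalysisOptions
    per_model: dict[str, ModelSection]

    def to_dict(self) -> dict:
        """JSON-safe dict (full precision, deterministic key order)."""
        return _as_jsonable(dataclasses.asdict(self))


def _as_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        return obj
    if isinstance(obj, GeneticModel):
        return obj.value
    return obj


def _gather_effects(table: CohortTable, model: GeneticModel,
                    options: AnalysisOptions
                    ) -> tuple[list[EffectEstimate], list[Optional[TwoByTwo]], list[tuple[str, str]]]:
    """Per-study effects for one model, plus tables and drop reasons.

    Genotype-complete studies are contrasted; allele-model pooling also
    accepts precomputed (log_or, se) rows.  ``tables`` aligns with the
    usable effects, with None where the effect came precomputed.
    """
    effects: list[EffectEstimate] = []
    tables: list[Optional[TwoByTwo]] = []
    dropped: list[tuple[str, str]] = []
    for s in table.studies:
        if s.has_genotypes:
            t = build_contrast(s, model, allele_exposure=options.allele_exposure)
            est = odds_ratio(t, correction=options.correction, study_id=s.study_id)
            if est.is_dropped:
                dropped.append((s.study_id, est.k_dropped_reason))
            else:
                effects.append(est)
                tables.append(t)
        elif model is GeneticModel.ALLELE and s.has_precomputed:
            effects.append(EffectEstimate.from_log_or(
                s.study_id, s.precomputed_log_or, s.precomputed_se))
            tables.append(None)
        elif model is GeneticModel.ALLELE:
            dropped.append((s.study_id, "no genotype counts and no precomputed effect"))
        else:
            dropped.append((s.study_id, "no genotype counts"))
    return effects, tables, dropped


def _analyze_model(table: CohortTable, model: GeneticModel,
                   options: AnalysisOptions) -> ModelSection:
    section = ModelSection(model=model.value)
    effects, tables, dropped = _gather_effects(table, model, options)
    section.dropped = dropped
    section.effects = effects
    section.n_studies_used = len(effects)
    if len(effects) < 2:
        section.error = (
            f"{model.value} model has {len(effects)} usable studies; "
            "at least 2 are required"
        )
        return section

    use_mh = options.fixed_estimator == "mh" or (
        options.fixed_estimator == "auto" and all(t is not None for t in tables)
    )
    if use_mh and all(t is not None for t in tables):
        section.fixed = pool_fixed_mh(
            tables, study_ids=[e.study_id for e in effects],
            correction=options.correction)
    else:
        section.fixed = pool_fixed_iv(effects)
    section.random = pool_random_dl(effects)
    section.het = section.fixed.het
    if options.pooling == "auto":
        section.selected = select_model(
            section.het, options.i2_threshold, options.p_threshold)
    else:
        section.selected = options.pooling

    if len(effects) >= 3:
        section.loo = leave_one_out(
            effects, pooling=options.pooling,
            i2_threshold=options.i2_threshold, p_threshold=options.p_threshold)
        center = section.fixed.log_or
        section.funnel = funnel_coordinates(effects, center)
        try:
            section.egger = egger_test(effects)
        except DegenerateRegressionError as exc:
            log.info("egger test degenerate for %s: %s", model.value, exc)
        section.begg = begg_test(effects, center)
        section.trimfill = trim_and_fill(effects, side=options.trimfill_side)

    sel = section.selected_result
    log.info(
        "model=%s k=%d method=%s Q=%.3f I2=%.1f%% OR=%.3f [%.3f, %.3f] p=%s",
        model.value, section.n_studies_used, sel.method, section.het.q,
        section.het.i2, sel.or_value, sel.ci_low, sel.ci_high, fmt_p(sel.p_z),
    )
    return section


def run_analysis(table: CohortTable, models: Optional[Sequence[str]] = None,
                 options: Optional[AnalysisOptions] = None) -> AnalysisReport:
    """Run the full per-model meta-analysis on a cohort table."""
    if len(table) == 0:
        raise ValueError("cohort table is empty")
    options = options or AnalysisOptions()
    if models is not None:
        options = dataclasses.replace(options, models=tuple(models))

    findings = validate_table(table)
    errors = [f for f in findings if f.severity == "error"]
    for f in findings:
        log.log(logging.WARNING if f.severity == "warning" else logging.ERROR,
                "validation [%s] %s: %s", f.severity, f.study_id, f.message)
    if errors and not options.allow_invalid:
        raise ValidationError(
            f"{len(errors)} error finding(s) block the analysis "
            "(set allow_invalid to override): "
            + "; ".join(f"{f.study_id}: {f.message}" for f in errors)
        )

    per_model = {}
    for name in options.models:
        model = GeneticModel(name)
        per_model[model.value] = _analyze_model(table, model, options)
    return AnalysisReport(
        input_label=table.label,
        totals=cohort_totals(table),
        validation=findings,
        settings=options,
        per_model=per_model,
    )


# ---------------------------------------------------------------------------
# export

def _forest_rows(section: ModelSection) -> list[dict]:
    rows = []
    for e in section.effects:
        rows.append({
            "study_id": e.study_id,
            "or": fmt_or(e.or_value),
            "ci_low": fmt_or(e.ci_low),
            "ci_high": fmt_or(e.ci_high),
            "weight_fixed": f"{section.fixed.weights.get(e.study_id, 0.0):.4f}",
            "weight_random": f"{section.random.weights.get(e.study_id, 0.0):.4f}",
        })
    for label, pooled in (("POOLED_FIXED", section.fixed),
                          ("POOLED_RANDOM", section.random)):
        rows.append({
            "study_id": label,
            "or": fmt_or(pooled.or_value),
            "ci_low": fmt_or(pooled.ci_low),
            "ci_high": fmt_or(pooled.ci_high),
            "weight_fixed": "",
            "weight_random": "",
        })
    return rows


def _write_csv(path: Path, rows: list[dict], columns: list[str]) -> None:
    lines = [",".join(columns)]
    for row in rows:
        lines.append(",".join(str(row[c]) for c in columns))
    path.write_text("\n".join(lines) + "\n")


def export_report(report: AnalysisReport, out_dir) -> list[Path]:
    """Write report.json and per-model forest/funnel/loo CSVs; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    json_path = out / "report.json"
    json_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True,
                                    allow_nan=False) + "\n")
    written.append(json_path)

    for name, section in report.per_model.items():
        if section.error is not None:
            continue
        forest = out / f"forest_{name}.csv"
        _write_csv(forest, _forest_rows(section),
                   ["study_id", "or", "ci_low", "ci_high",
                    "weight_fixed", "weight_random"])
        written.append(forest)

        funnel = out / f"funnel_{name}.csv"
        _write_csv(
            funnel,
            [{"study_id": p.study_id, "log_or": repr(p.log_or),
              "se": repr(p.se), "side": p.side} for p in section.funnel],
            ["study_id", "log_or", "se", "side"],
        )
        written.append(funnel)

        loo = out / f"loo_{name}.csv"
        _write_csv(
            loo,
            [{
                "omitted_study_id": r.omitted_study_id,
                "or": fmt_or(r.pooled.or_value),
                "ci_low": fmt_or(r.pooled.ci_low),
                "ci_high": fmt_or(r.pooled.ci_high),
                "i2": f"{r.het.i2:.1f}",
                "p": fmt_p(r.pooled.p_z),
            } for r in section.loo],
            ["omitted_study_id", "or", "ci_low", "ci_high", "i2", "p"],
        )
        written.append(loo)
    return written
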