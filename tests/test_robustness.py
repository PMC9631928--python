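"""Leave-one-out sensitivity and publication-bias diagnostics."""

import math

import pytest

from admeta.genetic_contrasts import EffectEstimate
from admeta.robustness import (
    DegenerateRegressionError,
    begg_test,
    egger_test,
    funnel_coordinates,
    leave_one_out,
    trim_and_fill,
)


def eff(sid, log_or, se):
    return EffectEstimate.from_log_or(sid, log_or, se)


def symmetric_nine(center=math.log(1.3)):
    """Nine studies funnel-symmetric about ``center``: bigger offsets get
    bigger standard errors, as in a genuine funnel."""
    offsets = [0.0, 0.1, -0.1, 0.2, -0.2, 0.3, -0.3, 0.4, -0.4]
    ses = [0.05, 0.10, 0.10, 0.15, 0.15, 0.20, 0.20, 0.25, 0.25]
    return [eff(f"s{i}", center + o, s)
            for i, (o, s) in enumerate(zip(offsets, ses))]


# ---------------------------------------------------------------------------
# leave-one-out

def test_loo_of_identical_studies_is_flat():
    effects = [eff(f"s{i}", 0.25, 0.1) for i in range(4)]
    rows = leave_one_out(effects)
    assert [r.omitted_study_id for r in rows] == ["s0", "s1", "s2", "s3"]
    for r in rows:
        assert r.pooled.k == 3
        assert r.pooled.log_or == pytest.approx(0.25)
        assert r.het.i2 == 0.0


def test_loo_requires_three_studies():
    with pytest.raises(ValueError):
        leave_one_out([eff("a", 0.1, 0.1), eff("b", 0.2, 0.1)])


def test_loo_on_fixture_allele_effects(fixture_table, allele_effects):
    effects = allele_effects(fixture_table)
    rows = leave_one_out(effects)
    assert len(rows) == 7  # genotype-complete studies only
    assert {r.omitted_study_id for r in rows} == {e.study_id for e in effects}


def test_loo_honours_forced_pooling_method():
    effects = [eff("a", -0.5, 0.1), eff("b", 0.6, 0.1), eff("c", 0.1, 0.1),
               eff("d", 1.0, 0.1)]
    fixed_rows = leave_one_out(effects, pooling="fixed")
    random_rows = leave_one_out(effects, pooling="random")
    assert all(r.pooled.method == "fixed_iv" for r in fixed_rows)
    assert all(r.pooled.method == "random_dl" for r in random_rows)


# ---------------------------------------------------------------------------
# funnel

def test_funnel_sides_split_a_symmetric_pair():
    pts = funnel_coordinates([eff("a", -0.2, 0.1), eff("b", 0.2, 0.1)], 0.0)
    assert [p.side for p in pts] == ["left", "right"]


def test_funnel_centre_tie_goes_right():
    (pt,) = funnel_coordinates([eff("a", 0.3, 0.1)], 0.3)
    assert pt.side == "right"


def test_funnel_empty_input():
    assert funnel_coordinates([], 0.0) == []


# ---------------------------------------------------------------------------
# Egger

def test_egger_intercept_vanishes_for_mirrored_pairs():
    effects = []
    for i, (th, se) in enumerate([(0.1, 0.1), (0.2, 0.2), (0.3, 0.15)]):
        effects += [eff(f"p{i}", th, se), eff(f"m{i}", -th, se)]
    res = egger_test(effects)
    assert res.intercept == pytest.approx(0.0, abs=1e-12)


def test_egger_worked_three_point_example():
    res = egger_test([eff("a", 0.1, 0.1), eff("b", 0.2, 0.2), eff("c", 0.3, 0.3)])
    assert res.slope == pytest.approx(0.0, abs=1e-12)
    assert res.intercept == pytest.approx(1.0, rel=1e-12)
    assert res.k == 3


def test_egger_requires_three_studies():
    with pytest.raises(ValueError):
        egger_test([eff("a", 0.1, 0.1), eff("b", 0.2, 0.2)])


def test_egger_constant_precision_is_degenerate():
    with pytest.raises(DegenerateRegressionError):
        egger_test([eff("a", 0.1, 0.2), eff("b", 0.1, 0.2), eff("c", 0.1, 0.2)])


def test_egger_intercept_is_scale_equivariant():
    effects = [eff("a", 0.12, 0.1), eff("b", -0.3, 0.2), eff("c", 0.5, 0.35)]
    scaled = [eff(e.study_id, 3.0 * e.log_or, 3.0 * e.se) for e in effects]
    assert egger_test(scaled).intercept == pytest.approx(
        egger_test(effects).intercept, rel=1e-10)


# ---------------------------------------------------------------------------
# Begg

def test_begg_tau_is_one_for_deviates_increasing_with_variance():
    effects = [eff("a", 0.0, 0.10), eff("b", 0.3, 0.20),
               eff("c", 0.8, 0.30), eff("d", 1.5, 0.40)]
    res = begg_test(effects, pooled_log_or=0.2)
    assert res.kendall_tau == pytest.approx(1.0)


def test_begg_tau_near_zero_for_mirrored_set():
    effects = [eff("p1", 0.2, 0.1), eff("m1", -0.2, 0.11),
               eff("p2", 0.4, 0.2), eff("m2", -0.4, 0.21)]
    res = begg_test(effects, pooled_log_or=0.0)
    assert abs(res.kendall_tau) <= 0.4
    assert res.p > 0.3


def test_begg_all_variances_tied_gives_zero_tau():
    effects = [eff("a", 0.1, 0.2), eff("b", 0.5, 0.2), eff("c", -0.2, 0.2)]
    res = begg_test(effects, pooled_log_or=0.1)
    assert res.kendall_tau == 0.0
    assert res.p == 1.0


def test_begg_requires_three_studies():
    with pytest.raises(ValueError):
        begg_test([eff("a", 0.1, 0.1), eff("b", 0.2, 0.2)], 0.1)


# ---------------------------------------------------------------------------
# trim-and-fill

def test_trimfill_symmetric_set_fills_nothing():
    effects = symmetric_nine()
    res = trim_and_fill(effects, side="auto")
    assert res.k0 == 0
    assert res.filled_effects == []
    assert res.adjusted.log_or == pytest.approx(
        math.log(1.3), rel=1e-12)
    assert res.adjusted.k == len(effects)


def test_trimfill_recovers_two_deleted_left_studies():
    center = math.log(1.3)
    full = symmetric_nine(center)
    deleted = sorted((e.log_or, e.se) for e in full if e.log_or < center - 0.25)
    observed = [e for e in full if e.log_or >= center - 0.25]
    res = trim_and_fill(observed, side="left")
    assert res.k0 == 2
    filled = sorted((f.log_or, f.se) for f in res.filled_effects)
    for (got_lo, got_se), (want_lo, want_se) in zip(filled, deleted):
        assert got_lo == pytest.approx(want_lo, abs=0.05)
        assert got_se == pytest.approx(want_se, rel=1e-12)
    # the bias-adjusted centre returns to the truth
    assert res.adjusted_fixed.or_value == pytest.approx(1.3, rel=1e-6)


def test_trimfill_auto_detects_the_missing_side():
    center = math.log(1.3)
    full = symmetric_nine(center)
    observed = [e for e in full if e.log_or >= center - 0.25]
    res = trim_and_fill(observed, side="auto")
    assert res.side == "left"
    assert res.k0 == 2
    mirrored = [e for e in full if e.log_or <= center + 0.25]
    res = trim_and_fill(mirrored, side="auto")
    assert res.side == "right"
    assert res.k0 == 2


def test_trimfill_identical_effects_fill_nothing():
    effects = [eff(f"s{i}", 0.3, 0.1) for i in range(5)]
    res = trim_and_fill(effects)
    assert res.k0 == 0


def test_trimfill_keeps_all_original_studies():
    center = math.log(1.3)
    observed = [e for e in symmetric_nine(center) if e.log_or >= center - 0.25]
    res = trim_and_fill(observed, side="left")
    assert res.adjusted.k == len(observed) + res.k0
    original_ids = {e.study_id for e in observed}
    assert original_ids <= set(res.adjusted.weights)


def test_trimfill_on_mirror_completed_set_is_stable():
    # complete an asymmetric set with its own mirror images -> symmetric
    base = [eff("a", 0.1, 0.1), eff("b", 0.4, 0.2), eff("c", 0.9, 0.3)]
    mirror = [eff(f"m{e.study_id}", 2 * 0.1 - e.log_or, e.se) for e in base[1:]]
    res = trim_and_fill(base + mirror, side="auto")
    assert res.k0 == 0


def test_trimfill_requires_three_studies():
    with pytest.raises(ValueError):
        trim_and_fill([eff("a", 0.1, 0.1), eff("b", 0.2, 0.2)])
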