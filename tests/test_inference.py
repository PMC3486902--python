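"""Rates, Yates chi-squared, weighted comparisons, strata, power."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from iceffect.accounting import AneuploidyTally
from iceffect.cohort import SimConfig, simulate_cohort
from iceffect.inference import (
    cohort_ice_test,
    embryo_level_comparison,
    ice_test,
    per_chromosome_rate,
    power_experiment,
    stratified_ice,
    two_proportion_power,
    yates_chi2,
)
from iceffect.karyotype import Stage
from iceffect.weighting import WeightedControl

PERFECT_CALLS = {Stage.PB: 1.0, Stage.BLASTOMERE: 1.0, Stage.TE: 1.0}


def test_per_chromosome_rate_published_values():
    assert round(per_chromosome_rate(AneuploidyTally(10837, 553, 283)), 3) == 0.051
    assert round(per_chromosome_rate(AneuploidyTally(204406, 9598, 5078)), 3) == 0.047
    assert per_chromosome_rate(AneuploidyTally(500, 0, 10)) == 0.0
    with pytest.raises(ZeroDivisionError):
        per_chromosome_rate(AneuploidyTally(0, 0, 0))


def test_yates_null_table_clamps_to_zero():
    stat, p = yates_chi2(10, 90, 20, 180)
    assert stat == 0.0
    assert p == 1.0


def test_yates_published_pooled_table_vs_oracle():
    """The weighted 2×2 (553, 10284, 462, 10375) agrees with
    scipy.stats.chi2_contingency(correction=True) to 6 significant figures."""
    stat, p = yates_chi2(553, 10284, 462, 10375)
    res = sps.chi2_contingency(
        np.array([[553, 10284], [462, 10375]]), correction=True
    )
    assert stat == pytest.approx(res.statistic, rel=1e-6)
    assert p == pytest.approx(res.pvalue, rel=1e-6)
    assert p < 0.01  # the pooled excess is significant


def test_yates_symmetry():
    table = (7, 120, 19, 240)
    a, b, c, d = table
    stat, p = yates_chi2(a, b, c, d)
    assert yates_chi2(c, d, a, b) == pytest.approx((stat, p))
    assert yates_chi2(b, a, d, c) == pytest.approx((stat, p))


def test_yates_input_validation():
    with pytest.raises(ValueError):
        yates_chi2(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        yates_chi2(0, 0, 3, 4)


def test_yates_random_tables_match_oracle():
    rng = np.random.default_rng(12)
    for _ in range(200):
        a, b, c, d = rng.integers(1, 2000, size=4)
        stat, p = yates_chi2(a, b, c, d)
        res = sps.chi2_contingency(np.array([[a, b], [c, d]]), correction=True)
        assert stat == pytest.approx(res.statistic, rel=1e-6, abs=1e-12)
        assert p == pytest.approx(res.pvalue, rel=1e-6)


def test_ice_test_pooled_fixture_rate_difference():
    """553/10,837 carriers vs the weighted controls, with the raw pooled
    control rate 9,598/204,406: the rate difference rounds to 0.4%."""
    res = ice_test(
        AneuploidyTally(10837, 553, 283),
        WeightedControl("all", 462, 10375),
        control_rate=9598 / 204406,
    )
    assert round(res.carrier_rate, 3) == 0.051
    assert round(res.control_rate, 3) == 0.047
    assert round(res.rate_difference * 100, 1) == 0.4
    assert res.table == (553, 10284, 462, 10375)
    assert res.p_value < 0.01


def test_ice_test_equal_tallies_null():
    res = ice_test(AneuploidyTally(1000, 50, 10), WeightedControl("x", 50, 950))
    assert res.relative_risk == pytest.approx(1.0)
    assert res.chi2 == 0.0
    assert res.p_value == 1.0
    assert res.rate_difference == pytest.approx(0.0)


def test_embryo_level_published_values():
    res = embryo_level_comparison(1185, 1861, carrier_proportion=0.6981)
    assert round(res.control_proportion * 100, 2) == 63.68
    assert round(res.relative_risk, 3) == 1.096


def test_embryo_level_identity_and_errors():
    res = embryo_level_comparison(10, 100, 30, 300)
    assert res.relative_risk == pytest.approx(1.0)
    with pytest.raises(ZeroDivisionError):
        embryo_level_comparison(0, 100, 5, 100)
    with pytest.raises(ValueError):
        embryo_level_comparison(10, 100)


def test_stratified_robertsonian_pb_tally(carrier_cases, control_groups):
    """Brute-force check: the Robertsonian × polar-body stratum pools to 777
    assessed chromosomes with 65 errors."""
    cases, tallies = carrier_cases
    results = stratified_ice(
        cases, tallies, control_groups, by=("rearrangement_class", "stage")
    )
    by_label = {r.stratum: r for r in results}
    rob_pb = by_label["Robertsonian × PB"]
    assert rob_pb.carrier_errors == 65
    assert rob_pb.carrier_errors + rob_pb.carrier_normal == 777
    brute = [
        tallies[c.case_id]
        for c in cases
        if c.rearrangement_class == "Robertsonian" and c.stage is Stage.PB
    ]
    assert sum(t.errors for t in brute) == 65
    assert sum(t.chromosomes_assessed for t in brute) == 777


def test_single_stratum_reproduces_pooled(carrier_cases, control_groups):
    """Grouping on a constant attribute gives exactly the pooled test over
    the eligible (non-compound) cases."""
    cases, tallies = carrier_cases
    (whole,) = stratified_ice(cases, tallies, control_groups, by=())
    eligible = [c for c in cases if not c.is_compound]
    assert whole.n_cases == len(eligible) == 53
    pooled_err = sum(tallies[c.case_id].errors for c in eligible)
    assert whole.carrier_errors == pooled_err


def test_under_powered_flagging(carrier_cases, control_groups):
    cases, tallies = carrier_cases
    results = stratified_ice(
        cases, tallies, control_groups, min_chromosomes=1000
    )
    flags = {r.stratum: r.under_powered for r in results}
    assert flags["inversion"] is True  # few hundred chromosomes only
    assert flags["Robertsonian"] is False
    assert flags["reciprocal"] is False


def test_compound_case_excluded_by_default(carrier_cases, control_groups):
    cases, tallies = carrier_cases
    default = stratified_ice(cases, tallies, control_groups)
    assert all(r.stratum != "compound" for r in default)
    with_comp = stratified_ice(
        cases, tallies, control_groups, include_compound=True
    )
    assert any(r.stratum == "compound" for r in with_comp)


def test_cleavage_only_ice_orders_stage_relative_risks():
    """A cohort with the excess applied only at the blastomere stage shows a
    larger carrier-vs-control relative risk in the cleavage stratum than at
    either other stage at large n."""
    cfg = SimConfig(
        n_cases=90,
        carrier_samples_mean=10,
        n_control_patients_per_case=3,
        control_samples_per_patient=8,
        ice_multiplier=1.5,
        ice_stages=frozenset({Stage.BLASTOMERE}),
        age_slope=0.0,
        call_accuracy=PERFECT_CALLS,
    )
    cohort = simulate_cohort(cfg, seed=21)
    rr = {
        stage: cohort_ice_test(cohort, "truth", stages={stage}).relative_risk
        for stage in Stage
    }
    assert rr[Stage.BLASTOMERE] > rr[Stage.PB]
    assert rr[Stage.BLASTOMERE] > rr[Stage.TE]


def test_power_null_and_large_effect():
    cfg = SimConfig(
        n_cases=12,
        carrier_samples_mean=6,
        n_control_patients_per_case=4,
        control_samples_per_patient=6,
        stage_mix={Stage.PB: 0.0, Stage.BLASTOMERE: 1.0, Stage.TE: 0.0},
        age_slope=0.0,
        call_accuracy=PERFECT_CALLS,
    )
    df = power_experiment(cfg, [1.0, 3.0], [12], reps=100, seed=31)
    null_power = float(df.loc[df.ice_multiplier == 1.0, "power"].iloc[0])
    big_power = float(df.loc[df.ice_multiplier == 3.0, "power"].iloc[0])
    se = math.sqrt(0.05 * 0.95 / 100)
    assert abs(null_power - 0.05) < 3 * se
    assert big_power > 0.95


def test_power_experiment_validates_reps():
    with pytest.raises(ValueError):
        power_experiment(SimConfig(), [1.0], [4], reps=10)


def test_two_proportion_power_study_scale():
    """Closed-form cross-check at roughly the study's Robertsonian arm size
    (≈5,200 carrier chromosomes at 0.066 vs 0.047): non-trivial but
    imperfect power, and monotone in sample size."""
    p_mid = two_proportion_power(0.066, 0.047, 5200, 5200)
    assert 0.5 < p_mid < 1.0
    assert two_proportion_power(0.066, 0.047, 52000, 52000) > p_mid
    assert two_proportion_power(0.066, 0.047, 520, 520) < p_mid
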