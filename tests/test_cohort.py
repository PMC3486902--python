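"""Synthetic-cohort generator: determinism, rate recovery, profiles."""

import math

import numpy as np
import pytest

from iceffect.cohort import (
    SimConfig,
    simulate_acgh_profile,
    simulate_cohort,
    slot_of,
)
from iceffect.karyotype import COMPLEMENT_LABELS, Stage
from iceffect.samples import CopyState, Provenance, SampleCall


def _flat_rates(pb=0.08, bla=0.053, te=0.02):
    return {Stage.PB: pb, Stage.BLASTOMERE: bla, Stage.TE: te}


PERFECT_CALLS = {Stage.PB: 1.0, Stage.BLASTOMERE: 1.0, Stage.TE: 1.0}

BLA_ONLY = {Stage.PB: 0.0, Stage.BLASTOMERE: 1.0, Stage.TE: 0.0}


def _noninvolved_counts(cohort, arm="carrier", which="truth"):
    """(errors, chromosomes) over non-involved slots, brute force."""
    err = n = 0
    for case in cohort.cases:
        excluded = {slot_of(c) for c in case.excluded}
        for s in cohort.samples(arm, which)[case.case_id]:
            for chrom, st in s.states.items():
                if chrom in excluded:
                    continue
                n += 1
                err += st in (CopyState.GAIN, CopyState.LOSS)
    return err, n


def test_determinism_bit_for_bit():
    cfg = SimConfig(n_cases=8, seed=123)
    a = simulate_cohort(cfg)
    b = simulate_cohort(cfg, 123)
    assert [c.karyotype for c in a.cases] == [c.karyotype for c in b.cases]
    for arm in ("carrier", "control"):
        for which in ("truth", "called"):
            for cid in a.samples(arm, which):
                for sa, sb in zip(a.samples(arm, which)[cid], b.samples(arm, which)[cid]):
                    assert dict(sa.states) == dict(sb.states)


def test_null_case_carriers_match_controls():
    """With ICE multiplier 1 the carrier and control non-involved error
    frequencies agree within 3 binomial standard errors."""
    cfg = SimConfig(
        n_cases=40,
        carrier_samples_mean=12,
        n_control_patients_per_case=2,
        control_samples_per_patient=6,
        ice_multiplier=1.0,
        age_slope=0.0,
        call_accuracy=PERFECT_CALLS,
    )
    cohort = simulate_cohort(cfg, seed=2)
    ce, cn = _noninvolved_counts(cohort, "carrier")
    ke, kn = _noninvolved_counts(cohort, "control")
    assert cn >= 10_000 and kn >= 10_000
    p_pool = (ce + ke) / (cn + kn)
    se = math.sqrt(p_pool * (1 - p_pool) * (1 / cn + 1 / kn))
    assert abs(ce / cn - ke / kn) < 3 * se


def test_degenerate_rates_all_errors_on_involved():
    cfg = SimConfig(
        n_cases=10,
        stage_rates=_flat_rates(0.0, 0.0, 0.0),
        involved_malseg_rate=1.0,
        age_slope=0.0,
        call_accuracy=PERFECT_CALLS,
        n_control_patients_per_case=1,
        control_samples_per_patient=1,
    )
    cohort = simulate_cohort(cfg, seed=3)
    err, _ = _noninvolved_counts(cohort, "carrier")
    assert err == 0
    for case in cohort.cases:
        excluded = {slot_of(c) for c in case.excluded}
        for s in cohort.carrier_truth[case.case_id]:
            assert s.aberrant_chromosomes() == frozenset(excluded)


def test_cleavage_ice_rate_matches_closed_form():
    """Blastomere-only config, baseline 0.053, ICE multiplier 1.25: the
    empirical carrier non-involved rate lands within 3 binomial SE of the
    closed-form 0.053 × 1.25 = 0.06625, and an independent numpy binomial
    oracle with the same parameters agrees."""
    cfg = SimConfig(
        n_cases=50,
        carrier_samples_mean=8,
        n_control_patients_per_case=1,
        control_samples_per_patient=1,
        stage_mix=BLA_ONLY,
        stage_rates=_flat_rates(bla=0.053),
        ice_multiplier=1.25,
        age_slope=0.0,
        call_accuracy=PERFECT_CALLS,
    )
    cohort = simulate_cohort(cfg, seed=4)
    err, n = _noninvolved_counts(cohort, "carrier")
    p = 0.06625
    se = math.sqrt(p * (1 - p) / n)
    assert abs(err / n - p) < 3 * se
    # independent oracle: plain binomial sampling at the same (n, p)
    oracle = np.random.default_rng(4).binomial(n, p) / n
    assert abs(oracle - p) < 3 * se


def test_rate_recovery_per_stage_cell():
    """For each (stage, age) cell with enough chromosomes the empirical
    control error frequency recovers the configured baseline rate."""
    for stage, mix in [
        (Stage.PB, {Stage.PB: 1.0, Stage.BLASTOMERE: 0.0, Stage.TE: 0.0}),
        (Stage.BLASTOMERE, BLA_ONLY),
    ]:
        cfg = SimConfig(
            n_cases=20,
            n_control_patients_per_case=4,
            control_samples_per_patient=8,
            stage_mix=mix,
            age_range=(35, 35),
            call_accuracy=PERFECT_CALLS,
        )
        cohort = simulate_cohort(cfg, seed=5)
        err, n = _noninvolved_counts(cohort, "control")
        assert n >= 5000
        expected = cfg.baseline_rate(stage, 35)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(err / n - expected) < 3 * se


def test_age_ramp_monotone_in_simulated_rates():
    """A monotone baseline ramp shows up as monotone pooled rates across
    age bins at large n."""
    cfg = SimConfig(
        n_cases=60,
        n_control_patients_per_case=4,
        control_samples_per_patient=10,
        stage_mix=BLA_ONLY,
        age_slope=0.5,
        call_accuracy=PERFECT_CALLS,
    )
    assert cfg.baseline_rate(Stage.BLASTOMERE, 43) > cfg.baseline_rate(Stage.BLASTOMERE, 26)
    cohort = simulate_cohort(cfg, seed=6)
    bins = {"young": [0, 0], "old": [0, 0]}
    for case in cohort.cases:
        key = "young" if case.maternal_age <= 34 else "old"
        for s in cohort.control_truth[case.case_id]:
            ab = len(s.aberrant_chromosomes())
            bins[key][0] += ab
            bins[key][1] += len(s.states)
    assert bins["young"][1] > 5000 and bins["old"][1] > 5000
    assert bins["old"][0] / bins["old"][1] > bins["young"][0] / bins["young"][1]


def test_config_validation():
    with pytest.raises(ValueError, match="exceeds 1"):
        SimConfig(stage_rates=_flat_rates(bla=0.6), ice_multiplier=2.0)
    with pytest.raises(ValueError, match="probabilities"):
        SimConfig(involved_malseg_rate=1.2)
    with pytest.raises(ValueError, match="sum to 1"):
        SimConfig(stage_mix={Stage.PB: 0.5, Stage.BLASTOMERE: 0.2, Stage.TE: 0.2})


def _truth_sample(states_map, stage=Stage.BLASTOMERE):
    states = {c: CopyState.EXPECTED for c in COMPLEMENT_LABELS}
    states.update(states_map)
    return SampleCall("s1", "c1", stage, states, Provenance.SIMULATED_TRUTH)


def test_noise_free_profiles_hit_class_centres():
    cfg = SimConfig(ratio_noise_sd=0.0, probes_per_chromosome=10)
    prof = simulate_acgh_profile(_truth_sample({"13": CopyState.LOSS}), cfg, 0)
    assert np.all(prof.ratios["13"] == 0.5)
    assert np.all(prof.ratios["1"] == 1.0)
    prof = simulate_acgh_profile(_truth_sample({"21": CopyState.GAIN}), cfg, 0)
    assert np.all(prof.ratios["21"] == 1.5)


def test_profiles_require_truth_provenance():
    s = SampleCall(
        "s1", "c1", Stage.BLASTOMERE,
        {c: CopyState.EXPECTED for c in COMPLEMENT_LABELS}, Provenance.CALLED,
    )
    with pytest.raises(ValueError, match="SIMULATED_TRUTH"):
        simulate_acgh_profile(s, SimConfig(), 0)


def test_profile_medians_concentrate_near_class_centres():
    """At noise sd 0.1 the per-chromosome median ratio falls within 0.05 of
    its class centre for >= 99% of chromosomes over 1,000 samples."""
    cfg = SimConfig(ratio_noise_sd=0.1)
    rng = np.random.default_rng(42)
    centres = {CopyState.EXPECTED: 1.0, CopyState.LOSS: 0.5, CopyState.GAIN: 1.5}
    ok = total = 0
    for i in range(1000):
        states = {
            c: [CopyState.EXPECTED, CopyState.LOSS, CopyState.GAIN][rng.integers(3)]
            for c in COMPLEMENT_LABELS
        }
        truth = SampleCall(f"s{i}", "c1", Stage.BLASTOMERE, states, Provenance.SIMULATED_TRUTH)
        prof = simulate_acgh_profile(truth, cfg, rng)
        for c in COMPLEMENT_LABELS:
            total += 1
            ok += abs(np.median(prof.ratios[c]) - centres[states[c]]) < 0.05
    assert ok / total >= 0.99
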