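"""Synthetic cohort generator.

Emulates the statistical structure of a preimplantation genetic diagnosis
(PGD) study of rearrangement carriers: each simulated carrier case has a
karyotype drawn from a configurable pool, a biopsy stage, a maternal age, a
handful of oocyte/embryo samples, and a large patient-matched control group
of the same stage and age.  Structurally normal chromosomes malsegregate
independently at a stage- and age-dependent baseline rate, inflated by a
multiplicative inter-chromosomal-effect (ICE) factor in carrier samples at a
configurable set of stages; chromosomes involved in the carrier's
rearrangement malsegregate at a separate (high) rate.  A symmetric
misclassification channel models the published per-stage accuracy of
array-CGH calls, and ratio profiles mimicking array-CGH output can be drawn
for any simulated sample.

The generator is deterministic given a configuration and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np

from .karyotype import (
    COMPLEMENT_LABELS,
    CarrierCase,
    Stage,
    parse_karyotype,
)
from .samples import ACGHProfile, CopyState, Provenance, SampleCall

__all__ = ["SimConfig", "Cohort", "simulate_cohort", "simulate_acgh_profile", "slot_of"]

#: Per-chromosome malsegregation rates observed in large control cohorts at
#: each biopsy stage (oocytes via polar bodies, day-3 blastomeres, day-5
#: trophectoderm).
DEFAULT_STAGE_RATES: Mapping[Stage, float] = MappingProxyType(
    {Stage.PB: 0.080, Stage.BLASTOMERE: 0.053, Stage.TE: 0.020}
)

#: Published array-CGH whole-chromosome call accuracy per biopsy stage.
DEFAULT_CALL_ACCURACY: Mapping[Stage, float] = MappingProxyType(
    {Stage.PB: 0.94, Stage.BLASTOMERE: 0.98, Stage.TE: 0.95}
)

#: Case mix over biopsy stages (proportions of cases, study-like).
DEFAULT_STAGE_MIX: Mapping[Stage, float] = MappingProxyType(
    {Stage.PB: 9 / 54, Stage.BLASTOMERE: 29 / 54, Stage.TE: 16 / 54}
)


def slot_of(label: str) -> str:
    """Map a chromosome label onto its analysis slot ("Y" shares the sex
    slot "X"; see :data:`~iceffect.karyotype.COMPLEMENT_LABELS`)."""
    return "X" if label in ("X", "Y") else label


def _default_karyotype_pool() -> tuple[str, ...]:
    from .datasets import load_patient_table

    return tuple(load_patient_table()["karyotype"])


@dataclass(frozen=True)
class SimConfig:
    """All stochastic-model parameters for the synthetic cohort.

    Defaults reproduce the study conditions: 54 carrier cases with the
    published karyotype pool and stage mix, ~5 samples per case, control
    groups of 12 patients contributing 8 samples each, stage-specific
    baseline rates of 8.0% (polar bodies), 5.3% (blastomeres) and 2.0%
    (trophectoderm), and per-stage call accuracies of 94%/98%/95%.
    """

    n_cases: int = 54
    n_control_patients_per_case: int = 12
    control_samples_per_patient: int = 8
    #: mean samples per carrier case; drawn as 1 + Poisson(mean - 1).
    carrier_samples_mean: float = 5.2
    stage_mix: Mapping[Stage, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_MIX)
    )
    age_range: tuple[int, int] = (26, 43)
    stage_rates: Mapping[Stage, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_RATES)
    )
    #: logistic age-ramp steepness (per year) for the baseline rate; 0
    #: switches the ramp off.  The ramp is normalised to 1 at ``age_ref`` so
    #: the stage rates are exact at the study's mean maternal age.
    age_slope: float = 0.25
    age_midpoint: float = 37.0
    age_ref: float = 35.6
    #: multiplicative ICE applied to the baseline rate of non-involved
    #: chromosomes in carrier samples at stages in ``ice_stages``.
    ice_multiplier: float = 1.25
    ice_stages: frozenset[Stage] = frozenset({Stage.BLASTOMERE})
    #: probability that a rearrangement-involved chromosome is aberrant in a
    #: carrier sample (malsegregation of the rearranged chromosomes is the
    #: dominant abnormality in carrier embryos).
    involved_malseg_rate: float = 0.5
    call_accuracy: Mapping[Stage, float] = field(
        default_factory=lambda: dict(DEFAULT_CALL_ACCURACY)
    )
    #: BAC arrays of the kind used for these cohorts carry ~3,000 clones
    #: genome-wide, i.e. on the order of 130-150 per chromosome; sparser
    #: defaults make per-chromosome medians too noisy to be realistic.
    probes_per_chromosome: int = 150
    ratio_noise_sd: float = 0.1
    #: pool of carrier karyotype strings cases are drawn from; ``None`` means
    #: the packaged study pool.
    karyotype_pool: tuple[str, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        probs = [
            self.involved_malseg_rate,
            *self.stage_rates.values(),
            *self.call_accuracy.values(),
            *self.stage_mix.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.ice_multiplier < 0:
            raise ValueError("ice_multiplier must be >= 0")
        if not math.isclose(sum(self.stage_mix.values()), 1.0, abs_tol=1e-9):
            raise ValueError("stage_mix proportions must sum to 1")
        if self.probes_per_chromosome < 1:
            raise ValueError("probes_per_chromosome must be >= 1")
        if self.ratio_noise_sd < 0:
            raise ValueError("ratio_noise_sd must be >= 0")
        lo, hi = self.age_range
        if lo > hi:
            raise ValueError("age_range must be (low, high) with low <= high")
        for stage in Stage:
            worst = self.baseline_rate(stage, hi)
            if stage in self.ice_stages:
                worst *= self.ice_multiplier
            if worst > 1.0:
                raise ValueError(
                    f"baseline_rate × ice_multiplier exceeds 1 at stage "
                    f"{stage.value}, age {hi}"
                )

    def baseline_rate(self, stage: Stage, age: float) -> float:
        """Per-chromosome malsegregation probability for a control sample.

        The stage rate is modulated by a logistic ramp in maternal age,
        normalised to 1 at ``age_ref`` (no per-age rates are published; the
        ramp shape is a modelling choice, exposed through ``age_slope`` and
        ``age_midpoint``)."""
        base = self.stage_rates[Stage(stage)]
        if self.age_slope == 0.0:
            return base
        f = 1.0 / (1.0 + math.exp(-self.age_slope * (age - self.age_midpoint)))
        f_ref = 1.0 / (1.0 + math.exp(-self.age_slope * (self.age_ref - self.age_midpoint)))
        return base * f / f_ref

    def carrier_rate(self, stage: Stage, age: float) -> float:
        """Non-involved-chromosome rate in carrier samples (baseline times
        the ICE multiplier at ICE stages)."""
        r = self.baseline_rate(stage, age)
        if Stage(stage) in self.ice_stages:
            r *= self.ice_multiplier
        return r


@dataclass(frozen=True)
class Cohort:
    """A simulated carrier cohort with patient-matched controls.

    ``carrier_truth``/``control_truth`` hold simulated true states;
    ``carrier_called``/``control_called`` the states after the per-stage
    misclassification channel.  Control samples are keyed by the matched
    case's id."""

    config: SimConfig
    seed: int | None
    cases: tuple[CarrierCase, ...]
    carrier_truth: Mapping[str, tuple[SampleCall, ...]]
    carrier_called: Mapping[str, tuple[SampleCall, ...]]
    control_truth: Mapping[str, tuple[SampleCall, ...]]
    control_called: Mapping[str, tuple[SampleCall, ...]]

    def case(self, case_id: str) -> CarrierCase:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise KeyError(case_id)

    def samples(self, arm: str, which: str = "called") -> Mapping[str, tuple[SampleCall, ...]]:
        name = f"{arm}_{which}"
        if name not in (
            "carrier_truth",
            "carrier_called",
            "control_truth",
            "control_called",
        ):
            raise ValueError(f"unknown arm/which combination: {arm}/{which}")
        return getattr(self, name)


_STATES = (CopyState.EXPECTED, CopyState.GAIN, CopyState.LOSS)


def _draw_states(
    rng: np.random.Generator, rates: np.ndarray
) -> dict[str, CopyState]:
    """One sample's true states; ``rates`` is aligned with COMPLEMENT_LABELS."""
    aberrant = rng.random(len(COMPLEMENT_LABELS)) < rates
    gains = rng.random(len(COMPLEMENT_LABELS)) < 0.5
    return {
        slot: (
            (CopyState.GAIN if gains[i] else CopyState.LOSS)
            if aberrant[i]
            else CopyState.EXPECTED
        )
        for i, slot in enumerate(COMPLEMENT_LABELS)
    }


def _miscall(
    rng: np.random.Generator, states: Mapping[str, CopyState], accuracy: float
) -> dict[str, CopyState]:
    """Symmetric misclassification channel: with probability 1 - accuracy a
    state is replaced by one of the two other states, uniformly."""
    if accuracy >= 1.0:
        return dict(states)
    wrong = rng.random(len(states)) >= accuracy
    pick = rng.integers(2, size=len(states))
    out: dict[str, CopyState] = {}
    for i, (slot, s) in enumerate(states.items()):
        if wrong[i]:
            others = [x for x in _STATES if x is not s]
            out[slot] = others[pick[i]]
        else:
            out[slot] = s
    return out


def simulate_cohort(config: SimConfig, seed: int | None = None) -> Cohort:
    """Draw a full carrier + matched-control cohort.

    Deterministic given ``config`` and ``seed`` (``seed`` overrides
    ``config.seed``).  Non-involved chromosomes in carrier samples are
    aberrant independently with ``baseline_rate × ice_multiplier`` at ICE
    stages (baseline elsewhere); involved chromosomes with
    ``involved_malseg_rate``; control samples use the baseline rate only and
    share the matched case's stage and age.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    pool = config.karyotype_pool or _default_karyotype_pool()
    stages = list(config.stage_mix.keys())
    stage_p = np.array([config.stage_mix[s] for s in stages], dtype=float)
    stage_p = stage_p / stage_p.sum()

    cases: list[CarrierCase] = []
    carrier_truth: dict[str, tuple[SampleCall, ...]] = {}
    carrier_called: dict[str, tuple[SampleCall, ...]] = {}
    control_truth: dict[str, tuple[SampleCall, ...]] = {}
    control_called: dict[str, tuple[SampleCall, ...]] = {}

    for i in range(config.n_cases):
        case_id = f"S{i + 1:03d}"
        karyotype = pool[rng.integers(len(pool))]
        sex, events = parse_karyotype(karyotype)
        stage = stages[rng.choice(len(stages), p=stage_p)]
        age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
        n_samples = 1 + int(rng.poisson(max(config.carrier_samples_mean - 1.0, 0.0)))
        case = CarrierCase(
            case_id=case_id,
            patient_id=f"P{i + 1:03d}",
            maternal_age=age,
            karyotype=karyotype,
            carrier_sex=sex,
            rearrangements=events,
            stage=stage,
            n_samples=n_samples,
        )
        cases.append(case)
        excluded_slots = {slot_of(c) for c in case.excluded}
        base = config.baseline_rate(stage, age)
        carrier = config.carrier_rate(stage, age)
        rates_carrier = np.array(
            [
                config.involved_malseg_rate if slot in excluded_slots else carrier
                for slot in COMPLEMENT_LABELS
            ]
        )
        rates_control = np.full(len(COMPLEMENT_LABELS), base)
        acc = config.call_accuracy[stage]

        truth, called = [], []
        for j in range(n_samples):
            states = _draw_states(rng, rates_carrier)
            truth.append(
                SampleCall(f"{case_id}-E{j + 1:02d}", case_id, stage, states, Provenance.SIMULATED_TRUTH)
            )
            called.append(
                SampleCall(f"{case_id}-E{j + 1:02d}", case_id, stage, _miscall(rng, states, acc), Provenance.CALLED)
            )
        carrier_truth[case_id] = tuple(truth)
        carrier_called[case_id] = tuple(called)

        truth, called = [], []
        n_ctrl = config.n_control_patients_per_case * config.control_samples_per_patient
        for j in range(n_ctrl):
            states = _draw_states(rng, rates_control)
            truth.append(
                SampleCall(f"{case_id}-C{j + 1:03d}", case_id, stage, states, Provenance.SIMULATED_TRUTH)
            )
            called.append(
                SampleCall(f"{case_id}-C{j + 1:03d}", case_id, stage, _miscall(rng, states, acc), Provenance.CALLED)
            )
        control_truth[case_id] = tuple(truth)
        control_called[case_id] = tuple(called)

    return Cohort(
        config=config,
        seed=seed,
        cases=tuple(cases),
        carrier_truth=MappingProxyType(carrier_truth),
        carrier_called=MappingProxyType(carrier_called),
        control_truth=MappingProxyType(control_truth),
        control_called=MappingProxyType(control_called),
    )


_RATIO_CENTERS = {CopyState.EXPECTED: 1.0, CopyState.LOSS: 0.5, CopyState.GAIN: 1.5}


def simulate_acgh_profile(
    truth: SampleCall,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
) -> ACGHProfile:
    """Draw an array-CGH-like ratio profile around a sample's true states.

    Probe ratios centre on 1.0 for a balanced chromosome, 0.5 for a net
    single-copy loss and 1.5 for a net single-copy gain (an oocyte inferred
    from its polar bodies uses the same convention), with multiplicative
    log-normal noise of scale ``ratio_noise_sd`` (exactly the class centre
    when the noise scale is 0).
    """
    if truth.provenance is not Provenance.SIMULATED_TRUTH:
        raise ValueError("profiles are simulated from SIMULATED_TRUTH samples")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ratios = {}
    for chrom, state in truth.states.items():
        if state is CopyState.NOCALL:
            raise ValueError("truth states cannot be NOCALL")
        centre = _RATIO_CENTERS[state]
        noise = rng.normal(0.0, config.ratio_noise_sd, config.probes_per_chromosome)
        ratios[chrom] = centre * np.exp(noise)
    return ACGHProfile(truth.sample_id, truth.case_id, truth.stage, ratios)
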