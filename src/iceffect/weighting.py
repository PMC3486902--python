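"""Matched-control rescaling.

Control groups are much larger than the patients they are matched to, and
their sizes differ between patients; pooling raw control counts would weight
some maternal ages disproportionately.  Each control group is therefore given
the same weight as its matched patient: the control per-chromosome error
frequency is multiplied by the number of chromosomes assessed for the patient
(after rearrangement-chromosome exclusion), yielding the error count the
control group would have shown at the patient's sample size.

Expected counts are rounded half-up to integers; an unrounded variant is
available for sensitivity analysis, since rounding then summing differs from
summing then rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable

from .karyotype import Stage

__all__ = [
    "ControlGroup",
    "WeightedControl",
    "round_half_up",
    "weight_control",
    "pool_weighted",
]


@dataclass(frozen=True)
class ControlGroup:
    """Aggregate tally of the control group matched to one patient case."""

    matched_case_id: str
    n_patients: int
    n_samples: int
    chromosomes_assessed: int
    errors: int
    age: float | None = None
    stage: Stage | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.errors <= self.chromosomes_assessed:
            raise ValueError(
                f"control for case {self.matched_case_id}: errors must lie in "
                f"[0, chromosomes_assessed]"
            )

    @property
    def rate(self) -> float:
        if self.chromosomes_assessed == 0:
            raise ZeroDivisionError("control group has no assessed chromosomes")
        return self.errors / self.chromosomes_assessed


@dataclass(frozen=True)
class WeightedControl:
    """A control group rescaled to its matched patient's chromosome count."""

    matched_case_id: str
    expected_errors: int | float
    expected_normal: int | float

    @property
    def total(self) -> int | float:
        return self.expected_errors + self.expected_normal


def round_half_up(x: float | Fraction) -> int:
    """Round to the nearest integer, halves away from zero-towards-plus
    (1.5 -> 2, 2.5 -> 3).  Exact for :class:`~fractions.Fraction` input."""
    if isinstance(x, Fraction):
        return int(math.floor(x + Fraction(1, 2)))
    return int(math.floor(x + 0.5))


def weight_control(
    ctrl: ControlGroup, patient_chromosomes: int, *, rounding: bool = True
) -> WeightedControl:
    """Rescale a control group's error count to the matched patient's
    chromosome count.

    ``expected_errors = ctrl.errors / ctrl.chromosomes_assessed ×
    patient_chromosomes``, rounded half-up (the arithmetic is carried out in
    exact rational form so that e.g. ``8/336 × 63 = 1.5`` rounds to 2, not to
    a float one ulp below one-half).
    """
    if ctrl.chromosomes_assessed <= 0:
        raise ValueError(
            f"control for case {ctrl.matched_case_id} has no assessed chromosomes"
        )
    if patient_chromosomes <= 0:
        raise ValueError("patient_chromosomes must be positive")
    exact = Fraction(ctrl.errors, ctrl.chromosomes_assessed) * patient_chromosomes
    if rounding:
        expected_errors: int | float = round_half_up(exact)
    else:
        expected_errors = float(exact)
    return WeightedControl(
        matched_case_id=ctrl.matched_case_id,
        expected_errors=expected_errors,
        expected_normal=patient_chromosomes - expected_errors,
    )


def pool_weighted(weighted: Iterable[WeightedControl]) -> tuple[int | float, int | float]:
    """Sum expected errors and expected normal chromosomes over control
    groups, one per case.  Duplicate case ids are rejected."""
    seen: set[str] = set()
    total_err: int | float = 0
    total_norm: int | float = 0
    for w in weighted:
        if w.matched_case_id in seen:
            raise ValueError(f"duplicate weighted control for case {w.matched_case_id}")
        seen.add(w.matched_case_id)
        total_err += w.expected_errors
        total_norm += w.expected_normal
    if not seen:
        raise ValueError("no weighted controls to pool")
    return total_err, total_norm
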