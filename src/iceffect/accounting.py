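"""Aneuploidy accounting: from per-sample calls to per-case and per-stratum
tallies of (chromosomes assessed, errors detected).

Chromosomes involved in a carrier's rearrangement are excluded from both the
numerator and the denominator, focusing the tallies on structurally normal
chromosomes.  Denominators follow the biopsy stage: an oocyte inferred from
its polar bodies contributes a haploid complement of ``23 - k`` chromosomes
per sample (``k`` = number of distinct excluded chromosomes), whereas a
cleavage- or blastocyst-stage sample contributes a diploid ``46 - 2k``.  The
error unit is the net per-chromosome-pair state: an aberrant chromosome label
contributes exactly one error per sample regardless of sign.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .karyotype import CarrierCase, CarrierSex, Stage
from .samples import CopyState, SampleCall

__all__ = [
    "AneuploidyTally",
    "per_sample_complement",
    "tally_samples",
    "tally_case",
    "tally_from_counts",
    "pool_tallies",
    "stage_table",
]


@dataclass(frozen=True)
class AneuploidyTally:
    """(chromosomes assessed, errors detected) for one stratum.

    Stratum labels are optional and purely descriptive; pooling drops any
    label on which the pooled tallies disagree.
    """

    chromosomes_assessed: int
    errors: int
    n_samples: int
    case_id: str | None = None
    stage: Stage | None = None
    rearrangement_class: str | None = None
    carrier_sex: CarrierSex | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.errors <= self.chromosomes_assessed:
            raise ValueError(
                f"errors ({self.errors}) must lie in "
                f"[0, chromosomes_assessed={self.chromosomes_assessed}]"
            )

    @property
    def rate(self) -> float:
        if self.chromosomes_assessed == 0:
            raise ZeroDivisionError("tally has no assessed chromosomes")
        return self.errors / self.chromosomes_assessed


def per_sample_complement(stage: Stage, k_excluded: int) -> int:
    """Number of assessable chromosomes contributed by one sample after
    excluding ``k_excluded`` distinct rearrangement chromosomes."""
    if k_excluded < 0:
        raise ValueError("k_excluded must be >= 0")
    stage = Stage(stage)
    n = 23 - k_excluded if stage is Stage.PB else 46 - 2 * k_excluded
    if n <= 0:
        raise ValueError(
            f"no assessable chromosomes left at stage {stage.value} with "
            f"{k_excluded} exclusions"
        )
    return n


def tally_samples(
    samples: Sequence[SampleCall],
    excluded: Iterable[str],
    stage: Stage,
    *,
    allow_nocall: bool = False,
    **labels,
) -> AneuploidyTally:
    """Tally an arbitrary collection of same-stage samples against an
    excluded-chromosome set.

    With ``allow_nocall`` a flagged :attr:`CopyState.NOCALL` slot is dropped
    from both numerator and denominator (one chromosome for an oocyte sample,
    a pair for an embryo sample); without it, a NOCALL is a data error.
    Keyword arguments become stratum labels on the returned tally.
    """
    excluded = frozenset(excluded)
    stage = Stage(stage)
    per_slot = 1 if stage is Stage.PB else 2
    denominator = len(samples) * per_sample_complement(stage, len(excluded))
    errors = 0
    for s in samples:
        if s.stage is not stage:
            raise ValueError(
                f"sample {s.sample_id} has stage {s.stage.value}, expected {stage.value}"
            )
        for chrom, state in s.states.items():
            if chrom in excluded:
                continue
            if state is CopyState.NOCALL:
                if not allow_nocall:
                    raise ValueError(
                        f"sample {s.sample_id}: no-call on chromosome {chrom}"
                    )
                denominator -= per_slot
            elif state is not CopyState.EXPECTED:
                errors += 1
    return AneuploidyTally(
        chromosomes_assessed=denominator,
        errors=errors,
        n_samples=len(samples),
        stage=stage,
        **labels,
    )


def tally_case(
    samples: Sequence[SampleCall],
    excluded: Iterable[str],
    case: CarrierCase,
    *,
    allow_nocall: bool = False,
) -> AneuploidyTally:
    """Tally one carrier case's samples against its excluded-chromosome set."""
    if len(samples) != case.n_samples:
        raise ValueError(
            f"case {case.case_id}: got {len(samples)} samples, "
            f"case records n_samples={case.n_samples}"
        )
    return tally_samples(
        samples,
        excluded,
        case.stage,
        allow_nocall=allow_nocall,
        case_id=case.case_id,
        rearrangement_class=case.rearrangement_class,
        carrier_sex=case.carrier_sex,
    )


def tally_from_counts(case: CarrierCase, chromosomes_assessed: int, errors: int) -> AneuploidyTally:
    """Build a tally from pre-aggregated per-case counts (published-table
    input), validating the stage arithmetic against the case's karyotype."""
    expected = case.n_samples * per_sample_complement(case.stage, len(case.excluded))
    if chromosomes_assessed != expected:
        raise ValueError(
            f"case {case.case_id}: reported {chromosomes_assessed} chromosomes "
            f"assessed, but {case.n_samples} samples at stage {case.stage.value} "
            f"with {len(case.excluded)} exclusions imply {expected}"
        )
    return AneuploidyTally(
        chromosomes_assessed=chromosomes_assessed,
        errors=errors,
        n_samples=case.n_samples,
        case_id=case.case_id,
        stage=case.stage,
        rearrangement_class=case.rearrangement_class,
        carrier_sex=case.carrier_sex,
    )


def pool_tallies(tallies: Iterable[AneuploidyTally], **labels) -> AneuploidyTally:
    """Sum tallies into one stratum tally; keyword arguments set the pooled
    stratum labels."""
    tallies = list(tallies)
    if not tallies:
        raise ValueError("cannot pool an empty collection of tallies")
    pooled = AneuploidyTally(
        chromosomes_assessed=sum(t.chromosomes_assessed for t in tallies),
        errors=sum(t.errors for t in tallies),
        n_samples=sum(t.n_samples for t in tallies),
    )
    return replace(pooled, **labels)


def stage_table(
    carrier_tallies: Iterable[AneuploidyTally],
    control_tallies: Iterable[AneuploidyTally],
) -> pd.DataFrame:
    """Per-stage pooled tallies and rates for the carrier and control arms.

    Returns a tidy frame with one row per (stage, arm) plus a pooled total
    row per arm, columns ``stage, arm, chromosomes, errors, rate``.
    """
    rows = []
    for arm, tallies in (("carrier", list(carrier_tallies)), ("control", list(control_tallies))):
        for stage in Stage:
            sub = [t for t in tallies if t.stage is stage]
            if not sub:
                continue
            p = pool_tallies(sub, stage=stage)
            rows.append((stage.value, arm, p.chromosomes_assessed, p.errors, p.rate))
        total = pool_tallies(tallies)
        rows.append(("all", arm, total.chromosomes_assessed, total.errors, total.rate))
    return pd.DataFrame(rows, columns=["stage", "arm", "chromosomes", "errors", "rate"])
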