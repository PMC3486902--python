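"""Whole-chromosome copy-number calling from array-CGH-like ratio profiles.

The analysis unit is the whole chromosome: per chromosome the *median* probe
ratio (robust to outlying probes) is compared against a lower and an upper
linear-ratio threshold.  Default thresholds sit at the midpoints between the
copy-number class centres (0.5 / 1.0 / 1.5), not at the extremes sometimes
used to render individual plots.  No within-chromosome segmentation is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .karyotype import COMPLEMENT_LABELS
from .samples import ACGHProfile, CopyState, Provenance, SampleCall

__all__ = ["CallThresholds", "call_copy_number"]


@dataclass(frozen=True)
class CallThresholds:
    """Median-ratio thresholds for whole-chromosome calls."""

    loss_below: float = 0.75
    gain_above: float = 1.25
    min_probes: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.loss_below < 1.0 < self.gain_above:
            raise ValueError("thresholds must satisfy 0 < loss_below < 1 < gain_above")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")


def call_copy_number(
    profile: ACGHProfile, thresholds: CallThresholds | None = None
) -> SampleCall:
    """Call per-chromosome net copy state from a ratio profile.

    median < ``loss_below`` -> LOSS; median > ``gain_above`` -> GAIN;
    otherwise EXPECTED.  A chromosome with fewer than ``min_probes`` probes
    is flagged :attr:`CopyState.NOCALL` rather than guessed.
    """
    thresholds = thresholds or CallThresholds()
    states: dict[str, CopyState] = {}
    for chrom in COMPLEMENT_LABELS:
        if chrom not in profile.ratios:
            raise ValueError(f"profile {profile.sample_id}: missing chromosome {chrom}")
        v = profile.ratios[chrom]
        if v.size < thresholds.min_probes:
            states[chrom] = CopyState.NOCALL
            continue
        med = float(np.median(v))
        if med < thresholds.loss_below:
            states[chrom] = CopyState.LOSS
        elif med > thresholds.gain_above:
            states[chrom] = CopyState.GAIN
        else:
            states[chrom] = CopyState.EXPECTED
    return SampleCall(
        sample_id=profile.sample_id,
        case_id=profile.case_id,
        stage=profile.stage,
        states=states,
        provenance=Provenance.CALLED,
    )
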