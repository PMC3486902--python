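"""Per-sample copy-state containers shared by the simulator, caller, and
accounting layers.

A sample's state map always covers the 23 analysis slots of
:data:`~iceffect.karyotype.COMPLEMENT_LABELS`: the haploid complement for an
oocyte inferred from its polar bodies, or the net per-pair state for a
cleavage- or blastocyst-stage biopsy (one GAIN/LOSS per chromosome label per
sample, even though denominators count 46 chromosomes per embryo sample).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

import numpy as np

from .karyotype import COMPLEMENT_LABELS, Stage

__all__ = ["CopyState", "Provenance", "SampleCall", "ACGHProfile"]


class CopyState(str, enum.Enum):
    EXPECTED = "EXPECTED"
    GAIN = "GAIN"
    LOSS = "LOSS"
    #: flagged missing call (e.g. too few informative probes); distinct from a
    #: silently absent state, which is a data error.
    NOCALL = "NOCALL"


class Provenance(str, enum.Enum):
    SIMULATED_TRUTH = "SIMULATED_TRUTH"
    CALLED = "CALLED"


@dataclass(frozen=True)
class SampleCall:
    """Called (or simulated-truth) copy states of one biopsied sample."""

    sample_id: str
    case_id: str
    stage: Stage
    states: Mapping[str, CopyState]
    provenance: Provenance

    def __post_init__(self) -> None:
        # freeze and validate the complement
        states = dict(self.states)
        missing = set(COMPLEMENT_LABELS) - states.keys()
        extra = states.keys() - set(COMPLEMENT_LABELS)
        if missing or extra:
            raise ValueError(
                f"sample {self.sample_id}: state map must cover exactly the "
                f"{len(COMPLEMENT_LABELS)} analysis slots "
                f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
            )
        object.__setattr__(self, "states", MappingProxyType(states))

    def aberrant_chromosomes(self) -> frozenset[str]:
        return frozenset(
            c for c, s in self.states.items() if s in (CopyState.GAIN, CopyState.LOSS)
        )


@dataclass(frozen=True)
class ACGHProfile:
    """Simulated array-CGH profile: per chromosome, an ordered vector of
    linear test/reference probe ratios (1.0 = balanced)."""

    sample_id: str
    case_id: str
    stage: Stage
    ratios: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        ratios = {c: np.asarray(v, dtype=float) for c, v in self.ratios.items()}
        for c, v in ratios.items():
            if c not in COMPLEMENT_LABELS:
                raise ValueError(f"unknown chromosome label {c!r}")
            if np.any(v <= 0):
                raise ValueError(f"chromosome {c}: probe ratios must be positive")
        object.__setattr__(self, "ratios", MappingProxyType(ratios))
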