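"""Parsing of carrier karyotypes and derivation of excluded chromosomes.

The analysis works with a restricted subset of ISCN nomenclature covering the
rearrangements seen in preimplantation genetic diagnosis referrals for
balanced rearrangement carriers:

* Robertsonian translocations, written ``45,XX,der(13;14)(q10;q10)`` —
  centromeric fusion of two acrocentric chromosomes, carrier has 45
  chromosomes;
* reciprocal translocations, written ``46,XY,t(9;16)(p13.1;p11.2)``;
* pericentric/paracentric inversions, written ``46,XY,inv(8)(p21q24.1)``;
* couples in which each partner carries a rearrangement, written as two
  karyotype clauses separated by ``/``.

Breakpoint bands are preserved verbatim but never interpreted: downstream
accounting only needs the identity of the chromosomes involved, because every
chromosome that takes part in a rearrangement is excluded from the
inter-chromosomal-effect tallies.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass, field

__all__ = [
    "AUTOSOMES",
    "CHROMOSOME_LABELS",
    "COMPLEMENT_LABELS",
    "Stage",
    "CarrierSex",
    "RearrangementKind",
    "Rearrangement",
    "CarrierCase",
    "KaryotypeError",
    "KaryotypeParseError",
    "UnsupportedRearrangementError",
    "parse_karyotype",
    "karyotype_to_string",
    "excluded_chromosomes",
    "rearrangement_class",
]

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
CHROMOSOME_LABELS: tuple[str, ...] = AUTOSOMES + ("X", "Y")

#: Chromosome slots carried by every sample's state map: the 22 autosome
#: pairs plus a single sex-chromosome slot (labelled "X").  An oocyte call is
#: a haploid complement of 23; an embryo call records the *net* state of each
#: pair under the same 23 labels, while denominators count 46 chromosomes.
COMPLEMENT_LABELS: tuple[str, ...] = AUTOSOMES + ("X",)

#: Acrocentric chromosomes that can participate in Robertsonian fusions.
ACROCENTRICS = frozenset({"13", "14", "15", "21", "22"})


class Stage(str, enum.Enum):
    """Developmental stage at which a sample was biopsied."""

    PB = "PB"
    BLASTOMERE = "blastomere"
    TE = "TE"

    @classmethod
    def from_token(cls, token: str) -> "Stage":
        t = str(token).strip().lower()
        aliases = {
            "pb": cls.PB,
            "polar body": cls.PB,
            "bla": cls.BLASTOMERE,
            "blastomere": cls.BLASTOMERE,
            "cleavage": cls.BLASTOMERE,
            "te": cls.TE,
            "trophectoderm": cls.TE,
        }
        if t not in aliases:
            raise ValueError(f"unknown stage code: {token!r}")
        return aliases[t]


class CarrierSex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    #: couple in which both partners carry a rearrangement; such cases are
    #: excluded from sex-stratified inference.
    BOTH = "both"


class RearrangementKind(str, enum.Enum):
    ROBERTSONIAN = "Robertsonian"
    RECIPROCAL = "reciprocal"
    INVERSION = "inversion"


class KaryotypeError(ValueError):
    """Base class for karyotype handling errors."""


class KaryotypeParseError(KaryotypeError):
    """Malformed karyotype string; the message names the offending token."""


class UnsupportedRearrangementError(KaryotypeError):
    """Structurally valid ISCN event outside the supported subset."""


_N_INVOLVED = {
    RearrangementKind.ROBERTSONIAN: 2,
    RearrangementKind.RECIPROCAL: 2,
    RearrangementKind.INVERSION: 1,
}


@dataclass(frozen=True)
class Rearrangement:
    """A single balanced structural rearrangement.

    ``involved`` holds chromosome labels only; ``breakpoints`` keeps the raw
    band text (e.g. ``"q13.1;q21.2"``) for round-tripping.
    """

    kind: RearrangementKind
    involved: frozenset[str]
    breakpoints: str = ""

    def __post_init__(self) -> None:
        bad = self.involved - set(CHROMOSOME_LABELS)
        if bad:
            raise KaryotypeError(f"invalid chromosome labels: {sorted(bad)}")
        if len(self.involved) != _N_INVOLVED[self.kind]:
            raise KaryotypeError(
                f"{self.kind.value} rearrangement must involve "
                f"{_N_INVOLVED[self.kind]} distinct chromosomes, "
                f"got {sorted(self.involved)}"
            )

    def _sorted_involved(self) -> list[str]:
        order = {c: i for i, c in enumerate(CHROMOSOME_LABELS)}
        return sorted(self.involved, key=order.__getitem__)

    def to_iscn(self) -> str:
        chroms = ";".join(self._sorted_involved())
        prefix = {
            RearrangementKind.ROBERTSONIAN: "der",
            RearrangementKind.RECIPROCAL: "t",
            RearrangementKind.INVERSION: "inv",
        }[self.kind]
        bands = f"({self.breakpoints})" if self.breakpoints else ""
        return f"{prefix}({chroms}){bands}"


_CLAUSE_RE = re.compile(r"^(4[56]),(XX|XY),(.+)$")
_EVENT_RE = re.compile(r"^([a-z]+)\(([^()]*)\)(?:\(([^()]*)\))?$")
_UNSUPPORTED_PREFIXES = {"r", "ins", "idic", "mar", "dup", "del", "dic", "i"}


def _parse_event(token: str) -> Rearrangement:
    m = _EVENT_RE.match(token.strip())
    if m is None:
        raise KaryotypeParseError(f"malformed rearrangement event: {token!r}")
    prefix, chrom_part, bands = m.group(1), m.group(2), m.group(3) or ""
    chroms = [c.strip() for c in chrom_part.split(";")]
    for c in chroms:
        if c not in CHROMOSOME_LABELS:
            raise KaryotypeParseError(f"invalid chromosome {c!r} in {token!r}")
    if prefix in _UNSUPPORTED_PREFIXES:
        raise UnsupportedRearrangementError(
            f"rearrangement type {prefix!r} is outside the supported subset: {token!r}"
        )
    if prefix == "der":
        if len(chroms) != 2:
            raise KaryotypeParseError(f"der event needs two chromosomes: {token!r}")
        if bands.replace(" ", "") != "q10;q10":
            raise UnsupportedRearrangementError(
                "only whole-arm (q10;q10) derivative chromosomes — Robertsonian "
                f"fusions — are supported: {token!r}"
            )
        return Rearrangement(RearrangementKind.ROBERTSONIAN, frozenset(chroms), bands)
    if prefix == "t":
        if len(chroms) != 2:
            raise UnsupportedRearrangementError(
                f"only two-way reciprocal translocations are supported: {token!r}"
            )
        if bands.replace(" ", "") == "q10;q10" and set(chroms) <= ACROCENTRICS:
            # Conventionally such a fusion would be written der(a;b)(q10;q10);
            # flag rather than silently reclassify.
            warnings.warn(
                f"t{chroms} with q10;q10 breakpoints looks Robertsonian but is "
                "classified as reciprocal; rewrite as der(a;b)(q10;q10) if a "
                "Robertsonian fusion is intended",
                stacklevel=3,
            )
        return Rearrangement(RearrangementKind.RECIPROCAL, frozenset(chroms), bands)
    if prefix == "inv":
        if len(chroms) != 1:
            raise KaryotypeParseError(f"inv event needs one chromosome: {token!r}")
        return Rearrangement(RearrangementKind.INVERSION, frozenset(chroms), bands)
    raise KaryotypeParseError(f"unrecognised event type {prefix!r} in {token!r}")


def _parse_clause(clause: str) -> tuple[CarrierSex, Rearrangement]:
    m = _CLAUSE_RE.match(clause.strip())
    if m is None:
        raise KaryotypeParseError(f"malformed karyotype clause: {clause!r}")
    count, sex_token, event_token = m.group(1), m.group(2), m.group(3)
    event = _parse_event(event_token)
    expected = 45 if event.kind is RearrangementKind.ROBERTSONIAN else 46
    if int(count) != expected:
        raise KaryotypeParseError(
            f"chromosome count {count} inconsistent with {event.kind.value} "
            f"event in {clause!r} (expected {expected})"
        )
    sex = CarrierSex.FEMALE if sex_token == "XX" else CarrierSex.MALE
    return sex, event


def parse_karyotype(text: str) -> tuple[CarrierSex, tuple[Rearrangement, ...]]:
    """Parse a karyotype string into carrier sex and rearrangement events.

    A ``/``-separated pair of clauses denotes a couple in which both partners
    carry a rearrangement; carrier sex is then :attr:`CarrierSex.BOTH`.

    Raises
    ------
    KaryotypeParseError
        If the string does not match the supported grammar.
    UnsupportedRearrangementError
        For recognisable ISCN events outside the supported subset
        (rings, insertions, three-way translocations, ...).
    """
    if not isinstance(text, str) or not text.strip():
        raise KaryotypeParseError("empty karyotype string")
    clauses = [c for c in text.split("/") if c.strip()]
    parsed = [_parse_clause(c) for c in clauses]
    sexes = {s for s, _ in parsed}
    sex = sexes.pop() if len(sexes) == 1 else CarrierSex.BOTH
    return sex, tuple(ev for _, ev in parsed)


def karyotype_to_string(
    sex: CarrierSex, rearrangements: tuple[Rearrangement, ...] | list[Rearrangement]
) -> str:
    """Serialise parsed events back to a karyotype string.

    For ``BOTH`` (a compound couple) the first event is attributed to the male
    partner and the second to the female partner, matching the clause order in
    which such karyotypes are written here.  The result re-parses to an
    equivalent event list.
    """
    rearrangements = tuple(rearrangements)
    if not rearrangements:
        raise KaryotypeError("no rearrangements to serialise")
    if sex is CarrierSex.BOTH:
        if len(rearrangements) != 2:
            raise KaryotypeError("BOTH carrier sex requires exactly two events")
        clause_sexes = [CarrierSex.MALE, CarrierSex.FEMALE]
    else:
        clause_sexes = [sex] * len(rearrangements)
    clauses = []
    for s, ev in zip(clause_sexes, rearrangements):
        count = 45 if ev.kind is RearrangementKind.ROBERTSONIAN else 46
        sex_token = "XX" if s is CarrierSex.FEMALE else "XY"
        clauses.append(f"{count},{sex_token},{ev.to_iscn()}")
    return "/".join(clauses)


@dataclass(frozen=True)
class CarrierCase:
    """One PGD cycle of one rearrangement-carrier couple at one biopsy stage."""

    case_id: str
    patient_id: str
    maternal_age: float
    karyotype: str
    carrier_sex: CarrierSex
    rearrangements: tuple[Rearrangement, ...]
    stage: Stage
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError(f"case {self.case_id}: n_samples must be >= 0")
        if not self.rearrangements:
            raise ValueError(f"case {self.case_id}: at least one rearrangement required")

    @property
    def is_compound(self) -> bool:
        """True for a couple in which both partners carry a rearrangement."""
        return len(self.rearrangements) > 1

    @property
    def rearrangement_class(self) -> str:
        return rearrangement_class(self.rearrangements)

    @property
    def excluded(self) -> frozenset[str]:
        return excluded_chromosomes(self)


def excluded_chromosomes(case: CarrierCase) -> frozenset[str]:
    """Chromosomes removed from the case's tallies: the union of chromosomes
    involved in any of the case's rearrangements."""
    out: frozenset[str] = frozenset()
    for r in case.rearrangements:
        out |= r.involved
    return out


def rearrangement_class(
    rearrangements: tuple[Rearrangement, ...] | list[Rearrangement],
) -> str:
    """Stratification label: the kind for a single event, ``"compound"`` for
    carriers of more than one rearrangement."""
    if len(rearrangements) == 1:
        return rearrangements[0].kind.value
    return "compound"
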