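"""Tab-separated readers and writers for every pipeline artifact.

All files are UTF-8 TSV with a header row; ``.`` marks a missing value.
Writers prepend ``#``-prefixed metadata lines carrying the seed and a
configuration hash so every artifact records how it was produced; readers
skip such lines.  Chromosome labels are plain strings ("1".."22", "X") —
the analysis is whole-chromosome, so no genome coordinates appear anywhere.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .karyotype import (
    COMPLEMENT_LABELS,
    CarrierCase,
    KaryotypeError,
    Stage,
    parse_karyotype,
)
from .samples import ACGHProfile, CopyState, Provenance, SampleCall
from .weighting import ControlGroup, WeightedControl

__all__ = [
    "PipelineConfig",
    "read_case_table",
    "write_case_table",
    "read_sample_table",
    "write_sample_table",
    "read_control_table",
    "write_control_table",
    "write_weighted_table",
    "read_profile_table",
    "write_profile_table",
    "write_seg_table",
]


@dataclass
class PipelineConfig:
    """Paths, thresholds and flags tying the pipeline stages together."""

    case_table: str | None = None
    sample_table: str | None = None
    control_table: str | None = None
    loss_below: float = 0.75
    gain_above: float = 1.25
    min_probes: int = 3
    rounding: bool = True
    include_compound: bool = False
    ice_stages: tuple[str, ...] = ("blastomere",)
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "ice_stages" in data:
            data["ice_stages"] = tuple(data["ice_stages"])
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=".")


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=["."], keep_default_na=False, **kwargs
    )


# -- case table -------------------------------------------------------------

CASE_COLUMNS = ["case_id", "patient_id", "maternal_age", "karyotype", "stage", "n_samples"]


def read_case_table(path: str | Path) -> list[CarrierCase]:
    """Read a carrier case table (``case_id, patient_id, maternal_age,
    karyotype, stage, n_samples``); failures name the offending row."""
    df = _read_tsv(path, dtype={"case_id": str, "patient_id": str})
    missing = set(CASE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: case table missing columns {sorted(missing)}")
    cases = []
    for i, row in df.iterrows():
        try:
            sex, events = parse_karyotype(row["karyotype"])
            cases.append(
                CarrierCase(
                    case_id=row["case_id"],
                    patient_id=row["patient_id"],
                    maternal_age=float(row["maternal_age"]),
                    karyotype=row["karyotype"],
                    carrier_sex=sex,
                    rearrangements=events,
                    stage=Stage.from_token(row["stage"]),
                    n_samples=int(row["n_samples"]),
                )
            )
        except (KaryotypeError, ValueError) as e:
            raise ValueError(f"{path}: row {i + 2}: {e}") from e
    return cases


def write_case_table(cases: Sequence[CarrierCase], path: str | Path, meta=None) -> None:
    df = pd.DataFrame(
        [
            (c.case_id, c.patient_id, c.maternal_age, c.karyotype, c.stage.value, c.n_samples)
            for c in cases
        ],
        columns=CASE_COLUMNS,
    )
    _write_tsv(df, path, meta)


# -- sample table -----------------------------------------------------------

SAMPLE_COLUMNS = ["sample_id", "case_id", "stage", "chromosome", "state", "provenance"]


def read_sample_table(path: str | Path, *, missing_as_nocall: bool = False) -> list[SampleCall]:
    """Read a long-format per-sample state table into grouped
    :class:`~iceffect.samples.SampleCall` objects.

    Each sample must cover the full 23-slot complement unless
    ``missing_as_nocall`` is set, in which case absent rows become flagged
    no-calls.  Duplicate (sample, chromosome) rows are an error.
    """
    df = _read_tsv(path, dtype={"sample_id": str, "case_id": str, "chromosome": str})
    missing = {"sample_id", "case_id", "stage", "chromosome", "state"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample table missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["sample_id", "chromosome"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate state for sample {first['sample_id']!r} "
            f"chromosome {first['chromosome']!r}"
        )
    calls = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        states = {
            r["chromosome"]: CopyState(r["state"]) for _, r in grp.iterrows()
        }
        absent = set(COMPLEMENT_LABELS) - states.keys()
        if absent:
            if not missing_as_nocall:
                raise ValueError(
                    f"{path}: sample {sample_id!r} missing chromosomes {sorted(absent)}"
                )
            states.update({c: CopyState.NOCALL for c in absent})
        prov = (
            Provenance(grp["provenance"].iloc[0])
            if "provenance" in grp.columns
            else Provenance.CALLED
        )
        calls.append(
            SampleCall(
                sample_id=sample_id,
                case_id=grp["case_id"].iloc[0],
                stage=Stage.from_token(grp["stage"].iloc[0]),
                states=states,
                provenance=prov,
            )
        )
    return calls


def write_sample_table(samples: Iterable[SampleCall], path: str | Path, meta=None) -> None:
    rows = [
        (s.sample_id, s.case_id, s.stage.value, c, s.states[c].value, s.provenance.value)
        for s in samples
        for c in COMPLEMENT_LABELS
    ]
    _write_tsv(pd.DataFrame(rows, columns=SAMPLE_COLUMNS), path, meta)


# -- control and weighted tables -------------------------------------------

CONTROL_COLUMNS = [
    "matched_case_id",
    "age",
    "stage",
    "n_patients",
    "n_samples",
    "chromosomes_assessed",
    "errors",
]


def read_control_table(path: str | Path) -> dict[str, ControlGroup]:
    df = _read_tsv(path, dtype={"matched_case_id": str})
    missing = set(CONTROL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: control table missing columns {sorted(missing)}")
    out: dict[str, ControlGroup] = {}
    for i, row in df.iterrows():
        cid = row["matched_case_id"]
        if cid in out:
            raise ValueError(f"{path}: row {i + 2}: duplicate control group for case {cid}")
        out[cid] = ControlGroup(
            matched_case_id=cid,
            n_patients=int(row["n_patients"]),
            n_samples=int(row["n_samples"]),
            chromosomes_assessed=int(row["chromosomes_assessed"]),
            errors=int(row["errors"]),
            age=float(row["age"]),
            stage=Stage.from_token(row["stage"]),
        )
    return out


def write_control_table(groups: Iterable[ControlGroup], path: str | Path, meta=None) -> None:
    rows = [
        (
            g.matched_case_id,
            g.age,
            g.stage.value if g.stage else ".",
            g.n_patients,
            g.n_samples,
            g.chromosomes_assessed,
            g.errors,
        )
        for g in groups
    ]
    _write_tsv(pd.DataFrame(rows, columns=CONTROL_COLUMNS), path, meta)


def write_weighted_table(
    weighted: Mapping[str, WeightedControl], path: str | Path, meta=None
) -> None:
    rows = [
        (cid, w.expected_errors, w.expected_normal)
        for cid, w in weighted.items()
    ]
    _write_tsv(
        pd.DataFrame(rows, columns=["case_id", "expected_errors", "expected_normal"]),
        path,
        meta,
    )


# -- profiles ---------------------------------------------------------------

PROFILE_COLUMNS = ["sample_id", "case_id", "stage", "chromosome", "probe_index", "ratio"]


def read_profile_table(path: str | Path) -> list[ACGHProfile]:
    df = _read_tsv(path, dtype={"sample_id": str, "case_id": str, "chromosome": str})
    profiles = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        ratios = {
            chrom: sub.sort_values("probe_index")["ratio"].to_numpy()
            for chrom, sub in grp.groupby("chromosome")
        }
        profiles.append(
            ACGHProfile(
                sample_id=sample_id,
                case_id=grp["case_id"].iloc[0],
                stage=Stage.from_token(grp["stage"].iloc[0]),
                ratios=ratios,
            )
        )
    return profiles


def write_profile_table(profiles: Iterable[ACGHProfile], path: str | Path, meta=None) -> None:
    rows = [
        (p.sample_id, p.case_id, p.stage.value, c, i, r)
        for p in profiles
        for c in p.ratios
        for i, r in enumerate(p.ratios[c])
    ]
    _write_tsv(pd.DataFrame(rows, columns=PROFILE_COLUMNS), path, meta)


def write_seg_table(samples: Iterable[SampleCall], path: str | Path, meta=None) -> None:
    """SEG-like whole-chromosome export for viewers: one segment per
    chromosome with a log2-ratio-style value (-1 loss, 0 expected, +1 gain)."""
    value = {
        CopyState.EXPECTED: 0.0,
        CopyState.GAIN: 1.0,
        CopyState.LOSS: -1.0,
        CopyState.NOCALL: float("nan"),
    }
    rows = [
        (s.sample_id, c, s.states[c].value, value[s.states[c]])
        for s in samples
        for c in COMPLEMENT_LABELS
    ]
    _write_tsv(
        pd.DataFrame(rows, columns=["sample_id", "chromosome", "state", "seg_value"]),
        path,
        meta,
    )
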