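"""Packaged study tables.

The package ships the published aggregate tables of the carrier cohort as
tab-separated fixtures, transcribed verbatim:

* ``table1_patients.tsv`` — one row per carrier couple: karyotype and the
  stages tested;
* ``table2_cases.tsv`` — one row per PGD cycle (case): maternal age,
  rearrangement class, biopsy stage, samples with a result, chromosomes
  assessed after exclusion, errors detected;
* ``table3_controls.tsv`` — the patient-matched control group tallies;
* ``table5_weighted.tsv`` — the published weighted (expected-error) control
  counts, used to validate the weighting transform row-for-row;
* ``embryo_level_robertsonian.json`` — sample-level abnormality inputs for
  the cleavage-stage Robertsonian comparison.

A SHA-256 manifest guards against silent fixture corruption.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .accounting import AneuploidyTally, tally_from_counts
from .karyotype import CarrierCase, Stage, parse_karyotype
from .weighting import ControlGroup

__all__ = [
    "load_patient_table",
    "load_case_table",
    "load_carrier_cases",
    "load_control_groups",
    "load_weighted_table",
    "load_embryo_level",
    "verify_checksums",
]

_CLASS_TOKENS = {
    "Rob": "Robertsonian",
    "Rec": "reciprocal",
    "Inv": "inversion",
    "Rec/Inv": "compound",
}


def _data_dir() -> Path:
    return Path(resources.files("iceffect") / "data")


def data_path(name: str) -> Path:
    p = _data_dir() / name
    if not p.exists():
        raise FileNotFoundError(f"packaged table not found: {name}")
    return p


def verify_checksums() -> None:
    """Check every packaged table against the SHA-256 manifest."""
    manifest = data_path("checksums.sha256").read_text().strip().splitlines()
    for line in manifest:
        digest, name = line.split()
        actual = hashlib.sha256(data_path(name).read_bytes()).hexdigest()
        if actual != digest:
            raise RuntimeError(f"packaged table {name} fails its checksum")


def load_patient_table() -> pd.DataFrame:
    """Carrier couples: ``patient_id``, ``karyotype``, ``stages_tested``."""
    df = pd.read_csv(data_path("table1_patients.tsv"), sep="\t", dtype={"patient_id": str})
    return df


def load_case_table() -> pd.DataFrame:
    """Per-cycle case table joined with each patient's karyotype."""
    cases = pd.read_csv(
        data_path("table2_cases.tsv"),
        sep="\t",
        dtype={"case_id": str, "patient_id": str},
    )
    patients = load_patient_table()
    return cases.merge(patients[["patient_id", "karyotype"]], on="patient_id", how="left")


def load_carrier_cases() -> tuple[list[CarrierCase], dict[str, AneuploidyTally]]:
    """Parse the study cases into structured form.

    Returns the cases and their per-case tallies; building the tallies
    revalidates the published chromosome-count arithmetic (samples ×
    stage complement after exclusion) for every row.
    """
    df = load_case_table()
    cases: list[CarrierCase] = []
    tallies: dict[str, AneuploidyTally] = {}
    for _, row in df.iterrows():
        sex, events = parse_karyotype(row["karyotype"])
        case = CarrierCase(
            case_id=row["case_id"],
            patient_id=row["patient_id"],
            maternal_age=float(row["maternal_age"]),
            karyotype=row["karyotype"],
            carrier_sex=sex,
            rearrangements=events,
            stage=Stage.from_token(row["stage"]),
            n_samples=int(row["n_samples"]),
        )
        expected_class = _CLASS_TOKENS[row["rearrangement_class"]]
        if case.rearrangement_class != expected_class:
            raise ValueError(
                f"case {case.case_id}: karyotype parses as "
                f"{case.rearrangement_class}, table says {expected_class}"
            )
        cases.append(case)
        tallies[case.case_id] = tally_from_counts(
            case, int(row["chromosomes_assessed"]), int(row["errors"])
        )
    return cases, tallies


def load_control_groups() -> dict[str, ControlGroup]:
    """The patient-matched control tallies, keyed by matched case id."""
    df = pd.read_csv(
        data_path("table3_controls.tsv"), sep="\t", dtype={"matched_case_id": str}
    )
    groups: dict[str, ControlGroup] = {}
    for _, row in df.iterrows():
        groups[row["matched_case_id"]] = ControlGroup(
            matched_case_id=row["matched_case_id"],
            n_patients=int(row["n_patients"]),
            n_samples=int(row["n_samples"]),
            chromosomes_assessed=int(row["chromosomes_assessed"]),
            errors=int(row["errors"]),
            age=float(row["age"]),
            stage=Stage.from_token(row["stage"]),
        )
    return groups


def load_weighted_table() -> pd.DataFrame:
    """The published weighted-control table (expected errors per case)."""
    return pd.read_csv(
        data_path("table5_weighted.tsv"), sep="\t", dtype={"case_id": str}
    )


def load_embryo_level() -> dict:
    """Sample-level inputs for the cleavage-stage Robertsonian comparison."""
    return json.loads(data_path("embryo_level_robertsonian.json").read_text())
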