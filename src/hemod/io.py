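"""Flat-file readers/writers and configuration loading.

The canonical exchange formats are plain CSV (UTF-8, comma-separated,
header row mandatory, ISO 8601 timestamps at minute resolution):

* ``patients.csv``      — patient_id, age_years, admission, discharge
* ``observations.csv``  — patient_id, loinc_code, value, unit, timestamp
* ``diagnoses.csv``     — patient_id, icd10gm_code
* ``procedures.csv``    — patient_id, procedure, start, end
* ``episodes.csv``      — patient_id, start, end, cause  (detector output)
* ``truth_episodes.csv``— patient_id, start, end         (reference standard)

These columns mirror the semantic payload of the source clinical
information models (LOINC-coded laboratory results with specimen
timestamps, ICD-10-GM diagnoses, procedure intervals), so an adapter to
a structured clinical repository remains feasible without making one a
dependency.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from .evaluation import EvalConfig
from .simulate import SimConfig, SyntheticCohort
from .types import (
    ANALYTE_BY_LOINC,
    Analyte,
    DiagnosisRecord,
    LabObservation,
    ODEpisode,
    ODCause,
    PatientRecord,
    ProcedureEpisode,
    ReferenceEpisode,
    RuleConfig,
)

logger = logging.getLogger(__name__)

TIME_FORMAT = "%Y-%m-%dT%H:%M"

#: accepted unit spellings and the factor converting them to /mm**3
_PLT_UNIT_FACTORS = {
    "/mm3": 1.0,
    "/mm^3": 1.0,
    "/ul": 1.0,
    "/µl": 1.0,
    "10*9/l": 1000.0,
    "10^9/l": 1000.0,
    "x10^9/l": 1000.0,
    "g/l": 1000.0,  # Giga per liter == 10^9/L
}
_INR_UNITS = {"", "1", "{inr}", "inr", "dimensionless"}


def _fmt(t: datetime) -> str:
    return t.strftime(TIME_FORMAT)


def _parse_time(raw: str, line: int, path: Path) -> datetime:
    try:
        return datetime.fromisoformat(str(raw))
    except ValueError as exc:
        raise ValueError(f"{path}, line {line}: bad timestamp {raw!r}") from exc


def read_observations(path: str | Path) -> list[LabObservation]:
    """Read LOINC-coded observations, converting units to /mm**3 and INR.

    Rows with LOINC codes other than the two supported analytes are
    skipped; their count is reported via a warning, never silently.
    Malformed rows and unknown units raise with the offending line.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    out: list[LabObservation] = []
    skipped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        code = str(row.loinc_code).strip()
        analyte = ANALYTE_BY_LOINC.get(code)
        if analyte is None:
            skipped += 1
            continue
        try:
            value = float(row.value)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {line}: bad value {row.value!r}") from exc
        unit = str(getattr(row, "unit", "") or "").strip().lower()
        if unit == "nan":
            unit = ""
        if analyte is Analyte.PLT:
            if unit not in _PLT_UNIT_FACTORS:
                raise ValueError(
                    f"{path}, line {line}: unknown platelet unit {unit!r}"
                )
            value *= _PLT_UNIT_FACTORS[unit]
        else:
            if unit not in _INR_UNITS:
                raise ValueError(f"{path}, line {line}: unknown INR unit {unit!r}")
        ts = _parse_time(row.timestamp, line, path)
        out.append(LabObservation(str(row.patient_id), analyte, value, ts, code))
    if skipped:
        logger.warning(
            "%s: skipped %d row(s) with unsupported LOINC codes", path, skipped
        )
    return out


def read_patients(path: str | Path) -> list[tuple[str, float, datetime, datetime]]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        rows.append(
            (
                str(row.patient_id),
                float(row.age_years),
                _parse_time(row.admission, line, path),
                _parse_time(row.discharge, line, path),
            )
        )
    return rows


def read_diagnoses(path: str | Path) -> list[DiagnosisRecord]:
    df = pd.read_csv(Path(path), dtype=str)
    return [
        DiagnosisRecord(str(r.patient_id), str(r.icd10gm_code).strip())
        for r in df.itertuples(index=False)
    ]


def read_procedures(path: str | Path) -> list[ProcedureEpisode]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        out.append(
            ProcedureEpisode(
                str(row.patient_id),
                _parse_time(row.start, line, path),
                _parse_time(row.end, line, path),
                str(row.procedure),
            )
        )
    return out


def load_cohort_dir(directory: str | Path) -> list[PatientRecord]:
    """Assemble PatientRecords from a cohort directory.

    Observations outside a patient's [admission, discharge] window are
    rejected with a warning (never silently clamped), as are records
    referencing unknown patients.
    """
    directory = Path(directory)
    for name in ("patients.csv", "observations.csv"):
        if not (directory / name).exists():
            raise FileNotFoundError(f"missing required input file: {directory / name}")
    patients_raw = read_patients(directory / "patients.csv")
    observations = read_observations(directory / "observations.csv")
    diagnoses = (
        read_diagnoses(directory / "diagnoses.csv")
        if (directory / "diagnoses.csv").exists()
        else []
    )
    procedures = (
        read_procedures(directory / "procedures.csv")
        if (directory / "procedures.csv").exists()
        else []
    )

    known = {pid for pid, *_ in patients_raw}
    windows = {pid: (adm, dis) for pid, _, adm, dis in patients_raw}
    obs_by_pid: dict[str, list[LabObservation]] = {pid: [] for pid in known}
    dropped = 0
    for o in observations:
        if o.patient_id not in known:
            dropped += 1
            continue
        adm, dis = windows[o.patient_id]
        if not adm <= o.timestamp <= dis:
            dropped += 1
            continue
        obs_by_pid[o.patient_id].append(o)
    if dropped:
        logger.warning(
            "rejected %d observation(s) outside their patient's stay "
            "or referencing unknown patients",
            dropped,
        )
    dx_by_pid: dict[str, list[DiagnosisRecord]] = {pid: [] for pid in known}
    for d in diagnoses:
        if d.patient_id in known:
            dx_by_pid[d.patient_id].append(d)
    pr_by_pid: dict[str, list[ProcedureEpisode]] = {pid: [] for pid in known}
    for p in procedures:
        if p.patient_id in known:
            pr_by_pid[p.patient_id].append(p)

    return [
        PatientRecord(
            pid,
            age,
            adm,
            dis,
            tuple(sorted(obs_by_pid[pid], key=lambda o: o.timestamp)),
            tuple(dx_by_pid[pid]),
            tuple(pr_by_pid[pid]),
        )
        for pid, age, adm, dis in patients_raw
    ]


def write_cohort_dir(cohort: SyntheticCohort, directory: str | Path) -> None:
    """Write a synthetic cohort in the canonical flat-file formats."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "age_years": round(p.age_years, 2),
                "admission": _fmt(p.admission),
                "discharge": _fmt(p.discharge),
            }
            for p in cohort.patients
        ]
    ).to_csv(directory / "patients.csv", index=False)
    pd.DataFrame(
        [
            {
                "patient_id": o.patient_id,
                "loinc_code": o.code,
                "value": o.value,
                "unit": "/mm3" if o.analyte is Analyte.PLT else "",
                "timestamp": _fmt(o.timestamp),
            }
            for p in cohort.patients
            for o in p.observations
        ],
        columns=["patient_id", "loinc_code", "value", "unit", "timestamp"],
    ).to_csv(directory / "observations.csv", index=False)
    pd.DataFrame(
        [
            {"patient_id": d.patient_id, "icd10gm_code": d.icd10gm_code}
            for p in cohort.patients
            for d in p.diagnoses
        ],
        columns=["patient_id", "icd10gm_code"],
    ).to_csv(directory / "diagnoses.csv", index=False)
    pd.DataFrame(
        [
            {
                "patient_id": pr.patient_id,
                "procedure": pr.procedure,
                "start": _fmt(pr.start),
                "end": _fmt(pr.end),
            }
            for p in cohort.patients
            for pr in p.procedures
        ],
        columns=["patient_id", "procedure", "start", "end"],
    ).to_csv(directory / "procedures.csv", index=False)
    write_reference_episodes(cohort.truth, directory / "truth_episodes.csv")


def write_episodes(episodes: Iterable[ODEpisode], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "start": _fmt(e.start),
                "end": _fmt(e.end),
                "cause": e.cause.value,
            }
            for e in episodes
        ],
        columns=["patient_id", "start", "end", "cause"],
    ).to_csv(Path(path), index=False)


def read_episodes(path: str | Path) -> list[ODEpisode]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        out.append(
            ODEpisode(
                str(row.patient_id),
                _parse_time(row.start, line, path),
                _parse_time(row.end, line, path),
                ODCause(str(row.cause)),
            )
        )
    return out


def write_reference_episodes(episodes: Iterable[ReferenceEpisode], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"patient_id": e.patient_id, "start": _fmt(e.start), "end": _fmt(e.end)}
            for e in episodes
        ],
        columns=["patient_id", "start", "end"],
    ).to_csv(Path(path), index=False)


def read_reference_episodes(path: str | Path) -> list[ReferenceEpisode]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        out.append(
            ReferenceEpisode(
                str(row.patient_id),
                _parse_time(row.start, line, path),
                _parse_time(row.end, line, path),
            )
        )
    return out


def read_labeled_episodes(path: str | Path) -> tuple[list[ReferenceEpisode], list[ReferenceEpisode]]:
    """Read an episodes file with a ``source`` column ({cdss, reference})."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    cdss, ref = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        ep = ReferenceEpisode(
            str(row.patient_id),
            _parse_time(row.start, line, path),
            _parse_time(row.end, line, path),
        )
        source = str(row.source).strip().lower()
        if source == "cdss":
            cdss.append(ep)
        elif source == "reference":
            ref.append(ep)
        else:
            raise ValueError(f"{path}, line {line}: unknown source {row.source!r}")
    return cdss, ref


# -- configuration -----------------------------------------------------------

def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def load_config(path: str | Path) -> dict:
    """Load a YAML config with optional rules/evaluation/simulation sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    if "rules" in raw:
        out["rules"] = RuleConfig(**_tupled(raw["rules"]))
    if "evaluation" in raw:
        out["evaluation"] = EvalConfig(**raw["evaluation"])
    if "simulation" in raw:
        out["simulation"] = SimConfig(**_tupled(raw["simulation"]))
    return out


def dump_config_yaml(configs: dict, path: str | Path) -> None:
    payload = {
        name: dataclasses.asdict(cfg) for name, cfg in configs.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# -- run manifest ------------------------------------------------------------

def write_manifest(
    out_dir: str | Path,
    command: str,
    config_echo: dict,
    input_paths: Sequence[str | Path] = (),
) -> Path:
    """Write the run manifest (command, resolved config, input digests)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hashes = {}
    for p in input_paths:
        p = Path(p)
        hashes[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "command": command,
        "config_echo": config_echo,
        "input_hashes": hashes,
        "versions": {"hemod": __version__},
        "timestamp": datetime.now().strftime(TIME_FORMAT),
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


__all__ = [
    "TIME_FORMAT",
    "read_observations",
    "read_patients",
    "read_diagnoses",
    "read_procedures",
    "load_cohort_dir",
    "write_cohort_dir",
    "write_episodes",
    "read_episodes",
    "write_reference_episodes",
    "read_reference_episodes",
    "read_labeled_episodes",
    "load_config",
    "dump_config_yaml",
    "write_manifest",
]
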