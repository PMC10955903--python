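"""Plain-text serialisation of corpus and result artefacts.

Stays travel as CSV (ISO-8601 datetimes, semicolon-joined ICD-10 codes),
notes as JSON lines, truth tables and monthly counts as CSV, configurations
as YAML, and fit/stat results as JSON.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .series import MonthlySeries
from .synthetic import SimulationConfig
from .types import NoteRecord, StayRecord


def _iso(value: dt.datetime | None) -> str:
    return value.isoformat() if value is not None else ""


def write_stays_csv(stays: Sequence[StayRecord], path: str | Path) -> None:
    frame = pd.DataFrame([{
        "stay_id": s.stay_id, "patient_id": s.patient_id,
        "hospital_id": s.hospital_id,
        "admission_dt": _iso(s.admission_dt),
        "discharge_dt": _iso(s.discharge_dt),
        "age_at_admission": s.age_at_admission, "sex": s.sex,
        "death_during_stay": s.death_during_stay,
        "icd10_codes": ";".join(sorted(s.icd10_codes)),
    } for s in stays])
    frame.to_csv(path, index=False)


def read_stays_csv(path: str | Path) -> list[StayRecord]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        StayRecord(
            stay_id=row.stay_id, patient_id=row.patient_id,
            hospital_id=row.hospital_id,
            admission_dt=dt.datetime.fromisoformat(row.admission_dt),
            discharge_dt=(dt.datetime.fromisoformat(row.discharge_dt)
                          if row.discharge_dt else None),
            age_at_admission=int(row.age_at_admission), sex=row.sex,
            death_during_stay=row.death_during_stay == "True",
            icd10_codes=frozenset(c for c in row.icd10_codes.split(";") if c),
        )
        for row in frame.itertuples()
    ]


def write_notes_jsonl(notes: Sequence[NoteRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in notes:
            fh.write(json.dumps({
                "note_id": n.note_id, "stay_id": n.stay_id,
                "note_type": n.note_type, "edited_dt": _iso(n.edited_dt),
                "text": n.text,
            }, ensure_ascii=False) + "\n")


def read_notes_jsonl(path: str | Path) -> list[NoteRecord]:
    notes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            obj = json.loads(line)
            notes.append(NoteRecord(
                note_id=obj["note_id"], stay_id=obj["stay_id"],
                note_type=obj["note_type"],
                edited_dt=dt.datetime.fromisoformat(obj["edited_dt"]),
                text=obj["text"],
            ))
    return notes


def write_monthly_counts_csv(series_list: Sequence[MonthlySeries],
                             path: str | Path) -> None:
    rows = []
    for series in series_list:
        labels = series.calendar_labels()
        for t, count in enumerate(series.counts):
            rows.append({"stratum": series.stratum, "year_month": labels[t],
                         "month_index": t, "count": count})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_config_yaml(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(json.loads(config.model_dump_json()), fh,
                       sort_keys=False, allow_unicode=True)


def read_config_yaml(path: str | Path) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh) or {}
    return SimulationConfig.model_validate(payload)


def sha256_of(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()
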