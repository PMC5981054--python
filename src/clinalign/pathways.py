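"""Temporal clinical pathways.

A *clinical pathway* is one patient's chronologically ordered sequence of
typed, coded medical events — lab tests, conditions, symptoms, diagnoses and
prescriptions — spanning one or more hospital admissions. Event codes are
prefixed by type (``l_``, ``c_``, ``s_``, ``d_``, ``p_``) so that, once
flattened to a token sequence, a code is unambiguous across coding systems.
Pathways are the "sentences" on which contextual embeddings are trained, and
the event streams from which patient vectors are built.

This module turns raw longitudinal event tables into pathways, applies
ICD-9 level-3 generalization to diagnosis codes, and implements the cohort
filters used throughout: dropping single-admission patients (no final
admission to predict) and dropping codes seen in too few distinct admissions.
"""

from __future__ import annotations

import csv
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Set

from .errors import ConfigError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "EventType",
    "MedicalEvent",
    "ClinicalPathway",
    "Cohort",
    "prefix_code",
    "truncate_icd9",
    "build_pathways",
    "cohort_from_events",
    "filter_cohort",
    "read_events_csv",
    "write_pathways_jsonl",
    "read_pathways_jsonl",
    "write_sentences",
    "sentences_from_cohort",
]


class EventType(str, Enum):
    """The five structured-data event types and their code prefixes."""

    LAB = "lab"
    CONDITION = "condition"
    SYMPTOM = "symptom"
    DIAGNOSIS = "diagnosis"
    PRESCRIPTION = "prescription"

    @property
    def prefix(self) -> str:
        return _PREFIXES[self]

    @property
    def sort_order(self) -> int:
        """Deterministic intra-timestamp ordering (see build_pathways)."""
        return _TIE_ORDER[self]


_PREFIXES: Dict[EventType, str] = {
    EventType.LAB: "l_",
    EventType.CONDITION: "c_",
    EventType.SYMPTOM: "s_",
    EventType.DIAGNOSIS: "d_",
    EventType.PRESCRIPTION: "p_",
}

# Tie-break order among events sharing a timestamp: conditions and symptoms
# (context of the encounter) first, then the diagnosis, then what was
# ordered as a consequence. Any fixed order would do; this one is frozen so
# embeddings are reproducible.
_TIE_ORDER: Dict[EventType, int] = {
    EventType.CONDITION: 0,
    EventType.SYMPTOM: 1,
    EventType.DIAGNOSIS: 2,
    EventType.LAB: 3,
    EventType.PRESCRIPTION: 4,
}


@dataclass(frozen=True)
class MedicalEvent:
    """One raw (unprefixed) coded event for one patient."""

    patient_id: str
    admission_id: str
    timestamp: object  # any totally ordered value (int tick or ISO datetime)
    event_type: EventType
    code: str

    def __post_init__(self):
        if not isinstance(self.event_type, EventType):
            try:
                object.__setattr__(self, "event_type", EventType(self.event_type))
            except ValueError:
                raise ConfigError(
                    f"unknown event_type {self.event_type!r}; expected one of "
                    f"{[t.value for t in EventType]}"
                ) from None
        if not self.code:
            raise ConfigError("event code must be non-empty")


@dataclass
class ClinicalPathway:
    """One patient's ordered, prefixed event codes with admission boundaries.

    ``admission_index[i]`` is the 0-based ordinal of the admission to which
    ``events[i]`` belongs; it is non-decreasing along the pathway.
    """

    patient_id: str
    events: List[str]
    admission_index: List[int]

    def __post_init__(self):
        if len(self.events) != len(self.admission_index):
            raise ConfigError(
                "events and admission_index must have equal length "
                f"({len(self.events)} vs {len(self.admission_index)})"
            )

    @property
    def n_admissions(self) -> int:
        return (self.admission_index[-1] + 1) if self.admission_index else 0

    def events_before_final_admission(self) -> List[str]:
        """Events strictly before the final admission (the PDPS input)."""
        if not self.events:
            return []
        last = self.admission_index[-1]
        return [e for e, a in zip(self.events, self.admission_index) if a < last]


@dataclass
class Cohort:
    """A set of pathways plus final-admission diagnosis labels.

    ``label_map`` maps patient_id to the set of level-3 diagnosis codes
    (prefixed, e.g. ``d_250``) observed in that patient's final admission.
    Every labeled patient appears in ``pathways``.
    """

    pathways: Dict[str, ClinicalPathway]
    label_map: Dict[str, Set[str]] = field(default_factory=dict)

    def __post_init__(self):
        missing = set(self.label_map) - set(self.pathways)
        if missing:
            raise ConfigError(
                f"label_map contains {len(missing)} patients absent from pathways"
            )

    @property
    def patient_ids(self) -> List[str]:
        return sorted(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def subset(self, patient_ids: Iterable[str]) -> "Cohort":
        ids = set(patient_ids)
        return Cohort(
            pathways={p: pw for p, pw in self.pathways.items() if p in ids},
            label_map={p: set(s) for p, s in self.label_map.items() if p in ids},
        )


def prefix_code(event_type: EventType, code: str) -> str:
    """Prepend the type prefix (``l_``, ``c_``, ``s_``, ``d_``, ``p_``).

    The caller must pass an unprefixed code; prefixing is not idempotent.
    """
    if not isinstance(event_type, EventType):
        try:
            event_type = EventType(event_type)
        except ValueError:
            raise ConfigError(f"unknown event_type {event_type!r}") from None
    if not code:
        raise ConfigError("cannot prefix an empty code")
    return event_type.prefix + code


def truncate_icd9(code: str) -> str:
    """Generalize an ICD-9 code to its level-3 stem.

    ``250.13`` (diabetes with ketoacidosis) becomes ``250`` (diabetes
    mellitus). Numeric codes keep the first three characters of the integer
    part. Supplementary V codes keep the letter plus two digits; external
    cause E codes keep the letter plus three digits, per the ICD-9 stem
    structure.
    """
    if not code:
        raise ConfigError("cannot truncate an empty code")
    stem = code.split(".", 1)[0]
    if not stem:
        raise ConfigError(f"ICD-9 code {code!r} has no integer part")
    first = stem[0].upper()
    if first == "V":
        return stem[:3]
    if first == "E":
        return stem[:4]
    return stem[:3]


def build_pathways(
    events: Iterable[MedicalEvent], icd9_truncate: bool = True
) -> Dict[str, ClinicalPathway]:
    """Assemble one chronologically ordered pathway per patient.

    Admissions are ordered by their earliest event (ties by admission id);
    within an admission events sort by ``(timestamp, event-type order,
    code)`` so the result is a deterministic function of the input multiset.
    Diagnosis codes are level-3 truncated when ``icd9_truncate`` is set;
    all codes come out prefixed.
    """
    per_patient: Dict[str, List[MedicalEvent]] = defaultdict(list)
    for ev in events:
        per_patient[ev.patient_id].append(ev)

    out: Dict[str, ClinicalPathway] = {}
    for pid in sorted(per_patient):
        evs = per_patient[pid]
        adm_start: Dict[str, object] = {}
        for ev in evs:
            if ev.admission_id not in adm_start or ev.timestamp < adm_start[ev.admission_id]:
                adm_start[ev.admission_id] = ev.timestamp
        adm_rank = {
            a: i
            for i, (_, _, a) in enumerate(
                sorted((t, str(a), a) for a, t in adm_start.items())
            )
        }
        evs.sort(
            key=lambda e: (
                adm_rank[e.admission_id],
                e.timestamp,
                e.event_type.sort_order,
                e.code,
            )
        )
        codes, adm_idx = [], []
        for ev in evs:
            code = ev.code
            if icd9_truncate and ev.event_type is EventType.DIAGNOSIS:
                code = truncate_icd9(code)
            codes.append(prefix_code(ev.event_type, code))
            adm_idx.append(adm_rank[ev.admission_id])
        out[pid] = ClinicalPathway(pid, codes, adm_idx)
    return out


def cohort_from_events(
    events: Iterable[MedicalEvent], icd9_truncate: bool = True
) -> Cohort:
    """Build a Cohort, labeling each patient with the level-3 diagnosis
    codes of their final admission."""
    pathways = build_pathways(events, icd9_truncate=icd9_truncate)
    label_map: Dict[str, Set[str]] = {}
    for pid, pw in pathways.items():
        if not pw.events:
            continue
        last = pw.admission_index[-1]
        labels = {
            c
            for c, a in zip(pw.events, pw.admission_index)
            if a == last and c.startswith("d_")
        }
        if labels:
            label_map[pid] = labels
    return Cohort(pathways=pathways, label_map=label_map)


def filter_cohort(
    cohort: Cohort, min_admissions: int = 2, min_event_admissions: int = 50
) -> Cohort:
    """Apply the cohort filters: multi-admission patients, then code rarity.

    Patients with fewer than ``min_admissions`` distinct admissions are
    removed first. Then any code occurring in fewer than
    ``min_event_admissions`` distinct admissions (counted once per
    admission over the patient-filtered cohort, however often it repeats
    inside an admission) is removed from every pathway. Pathways emptied by
    the code filter are dropped. Idempotent for fixed thresholds.
    """
    kept = {
        pid: pw
        for pid, pw in cohort.pathways.items()
        if pw.n_admissions >= min_admissions
    }

    if min_event_admissions > 0:
        adm_count: Dict[str, int] = defaultdict(int)
        for pid, pw in kept.items():
            seen_in_adm: Set[tuple] = set()
            for code, adm in zip(pw.events, pw.admission_index):
                key = (code, adm)
                if key not in seen_in_adm:
                    seen_in_adm.add(key)
                    adm_count[code] += 1
        frequent = {c for c, n in adm_count.items() if n >= min_event_admissions}
    else:
        frequent = None  # keep everything

    out_paths: Dict[str, ClinicalPathway] = {}
    for pid, pw in kept.items():
        if frequent is None:
            out_paths[pid] = ClinicalPathway(
                pid, list(pw.events), list(pw.admission_index)
            )
            continue
        ev, ai = [], []
        for code, adm in zip(pw.events, pw.admission_index):
            if code in frequent:
                ev.append(code)
                ai.append(adm)
        if ev:
            out_paths[pid] = ClinicalPathway(pid, ev, ai)

    label_map = {
        pid: set(labels)
        for pid, labels in cohort.label_map.items()
        if pid in out_paths
    }
    return Cohort(pathways=out_paths, label_map=label_map)


# ---------------------------------------------------------------------------
# File interfaces

_COLUMNS = ["patient_id", "admission_id", "timestamp", "event_type", "code"]


def read_events_csv(path, delimiter: str | None = None) -> List[MedicalEvent]:
    """Read a delimited event table (header required).

    Columns: patient_id, admission_id, timestamp, event_type, code.
    The delimiter is sniffed from the header when not given (``,`` or tab).
    Integer-looking timestamps are parsed as ints; anything else is kept as
    a string (ISO datetimes compare correctly as strings).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        head = fh.readline()
        if not head:
            raise FormatError(f"{path}: empty file", line=1)
        if delimiter is None:
            delimiter = "\t" if "\t" in head else ","
        header = [h.strip() for h in head.rstrip("\n").split(delimiter)]
        if header != _COLUMNS:
            raise FormatError(
                f"{path}: expected header {_COLUMNS}, got {header}", line=1
            )
        reader = csv.reader(fh, delimiter=delimiter)
        events = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_COLUMNS):
                raise FormatError(
                    f"{path}: expected {len(_COLUMNS)} fields, got {len(row)}",
                    line=lineno,
                )
            pid, adm, ts, etype, code = (f.strip() for f in row)
            ts_val: object = int(ts) if ts.lstrip("-").isdigit() else ts
            try:
                events.append(MedicalEvent(pid, adm, ts_val, EventType(etype), code))
            except (ValueError, ConfigError) as exc:
                raise FormatError(f"{path}: {exc}", line=lineno) from None
    return events


def write_pathways_jsonl(pathways: Mapping[str, ClinicalPathway], path) -> None:
    """One JSON object per patient: {patient_id, events, admission_index}."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for pid in sorted(pathways):
            pw = pathways[pid]
            fh.write(
                json.dumps(
                    {
                        "patient_id": pw.patient_id,
                        "events": pw.events,
                        "admission_index": pw.admission_index,
                    }
                )
                + "\n"
            )


def read_pathways_jsonl(path) -> Dict[str, ClinicalPathway]:
    out: Dict[str, ClinicalPathway] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                pw = ClinicalPathway(
                    obj["patient_id"], list(obj["events"]), list(obj["admission_index"])
                )
            except (KeyError, ValueError, ConfigError) as exc:
                raise FormatError(f"{path}: {exc}", line=lineno) from None
            out[pw.patient_id] = pw
    return out


def sentences_from_cohort(cohort: Cohort) -> List[List[str]]:
    """Pathways as token sequences for embedding training (sorted by id)."""
    return [cohort.pathways[pid].events for pid in cohort.patient_ids]


def write_sentences(pathways: Mapping[str, ClinicalPathway], path) -> None:
    """Plain-text corpus: one patient per line, space-separated codes."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for pid in sorted(pathways):
            fh.write(" ".join(pathways[pid].events) + "\n")
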