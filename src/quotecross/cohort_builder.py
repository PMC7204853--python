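"""Case–crossover cohort construction from ICD-coded hospital records.

The design compares each patient with themselves: exposure in a hazard
("case") window 1–30 days before the index admission versus a referent
("control") window 61–90 days before it, which removes all time-invariant
confounding.  The index event is the first hospital admission for a
suicide attempt — an admission carrying an intentional self-harm or
undetermined-intent ICD-10 code (X60–X84, Y10–Y34, Y87 sequelae) and
spanning at least two calendar dates (the at-least-24-hours proxy).

Patients enter the analysis only when they have at least one clinical
document in *both* windows; each included patient contributes one
matched pair of window summaries.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

from .quote_extractor import (
    ExtractionConfig,
    RawDocument,
    count_tokens,
    extract_quoted_spans,
    quotes_per_token,
)

__all__ = [
    "Period",
    "WindowConfig",
    "AdmissionRecord",
    "Appointment",
    "PatientTimeline",
    "PeriodSummary",
    "MatchedPairRecord",
    "DocStats",
    "is_suicide_attempt_code",
    "is_qualifying_admission",
    "select_index_admission",
    "assign_window",
    "extract_doc_stats",
    "summarise_period",
    "build_matched_pairs",
    "NoQualifyingAdmissionError",
]

# ---------------------------------------------------------------------------
# ICD-10 filter
# ---------------------------------------------------------------------------

# Intentional self-harm (X60-X84), undetermined intent (Y10-Y34) and
# sequelae of intentional self-harm (Y87); printed ranges X6*, X7*,
# X80-4*, Y1*, Y2*, Y30-4*, Y87*.
_QUALIFYING_CATEGORIES = frozenset(
    [f"X{n}" for n in range(60, 85)]
    + [f"Y{n}" for n in range(10, 35)]
    + ["Y87"]
)

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}")


def is_suicide_attempt_code(code: str) -> bool:
    """True when the ICD-10 code's 3-character category marks a suicide
    attempt (intentional self-harm or undetermined intent).

    Subcodes inherit the category's status; dots and suffixes are
    stripped before comparison.  Malformed codes raise ValueError.
    """
    cleaned = code.strip().upper().replace(".", "")
    if not _CODE_RE.match(cleaned):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    return cleaned[:3] in _QUALIFYING_CATEGORIES


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class Period(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"
    NEITHER = "neither"


@dataclass(frozen=True)
class WindowConfig:
    """Day offsets (inclusive) of the two comparison windows before the
    index date.  Defaults: case 1–30 days prior, control 61–90."""

    case_start: int = 1
    case_end: int = 30
    control_start: int = 61
    control_end: int = 90

    def __post_init__(self) -> None:
        if not (0 < self.case_start <= self.case_end < self.control_start <= self.control_end):
            raise ValueError("windows must be positive-length, ordered and non-overlapping")

    @property
    def window_length(self) -> int:
        return self.case_end - self.case_start + 1


@dataclass(frozen=True)
class AdmissionRecord:
    patient_id: str
    admission_date: date
    discharge_date: date
    icd_codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.admission_date > self.discharge_date:
            raise ValueError("admission_date after discharge_date")


@dataclass(frozen=True)
class Appointment:
    date: date
    attended: bool


@dataclass
class PatientTimeline:
    """Everything known about one patient, anchored at the index date."""

    patient_id: str
    index_date: date
    documents: list[RawDocument] = field(default_factory=list)
    appointments: list[Appointment] = field(default_factory=list)
    inpatient_stays: list[tuple[date, date]] = field(default_factory=list)


@dataclass(frozen=True)
class PeriodSummary:
    """Exposure and covariate totals for one patient in one window."""

    patient_id: str
    period: Period
    n_documents: int
    n_quotes: int
    n_tokens: int
    quotes_per_token: float
    any_quote: int
    face_to_face: int
    dna: int
    bed_days: int


@dataclass(frozen=True)
class MatchedPairRecord:
    patient_id: str
    case: PeriodSummary
    control: PeriodSummary

    def __post_init__(self) -> None:
        if self.case.period is not Period.CASE or self.control.period is not Period.CONTROL:
            raise ValueError("summaries assigned to the wrong period slots")


@dataclass(frozen=True)
class DocStats:
    n_quotes: int
    n_tokens: int


# ---------------------------------------------------------------------------
# Index admission selection
# ---------------------------------------------------------------------------


class NoQualifyingAdmissionError(LookupError):
    """No admission satisfies the suicide-attempt and >=24h criteria."""


def is_qualifying_admission(a: AdmissionRecord) -> bool:
    """Suicide-attempt code present and the stay spans different dates
    (the hospitalised-for-at-least-24-hours proxy)."""
    if a.admission_date == a.discharge_date:
        return False
    return any(is_suicide_attempt_code(c) for c in a.icd_codes)


def select_index_admission(
    admissions: Sequence[AdmissionRecord],
    study_start: date | None = None,
    study_end: date | None = None,
) -> AdmissionRecord:
    """The first qualifying admission (earliest admission date) within the
    study window; ties broken by longest stay, then input order."""
    candidates = [
        (a.admission_date, -(a.discharge_date - a.admission_date).days, i, a)
        for i, a in enumerate(admissions)
        if is_qualifying_admission(a)
        and (study_start is None or a.admission_date >= study_start)
        and (study_end is None or a.admission_date <= study_end)
    ]
    if not candidates:
        raise NoQualifyingAdmissionError("no qualifying suicide-attempt admission")
    return min(candidates)[3]


# ---------------------------------------------------------------------------
# Window assignment and summarisation
# ---------------------------------------------------------------------------


def assign_window(event_date: date, index_date: date, windows: WindowConfig | None = None) -> Period:
    """Which comparison window an event falls in, by whole days prior to
    the index date (boundaries inclusive; the index day itself is in
    neither window)."""
    w = windows or WindowConfig()
    d = (index_date - event_date).days
    if w.case_start <= d <= w.case_end:
        return Period.CASE
    if w.control_start <= d <= w.control_end:
        return Period.CONTROL
    return Period.NEITHER


def extract_doc_stats(
    documents: Iterable[RawDocument], cfg: ExtractionConfig | None = None
) -> dict[str, DocStats]:
    """Run quote extraction and tokenisation over documents once, keyed
    by doc_id, for reuse across window summaries."""
    cfg = cfg or ExtractionConfig()
    return {
        doc.doc_id: DocStats(
            n_quotes=len(extract_quoted_spans(doc, cfg)),
            n_tokens=count_tokens(doc.text, cfg),
        )
        for doc in documents
    }


def _window_dates(index_date: date, start_offset: int, end_offset: int) -> set[date]:
    return {index_date - timedelta(days=d) for d in range(start_offset, end_offset + 1)}


def _bed_days(
    stays: Iterable[tuple[date, date]], window_days: set[date]
) -> int:
    """Distinct window dates on which the patient occupied an inpatient
    bed overnight: a stay [start, end] covers the nights of start..end-1
    (day-level resolution; a same-day stay occupies no night)."""
    occupied: set[date] = set()
    for start, end in stays:
        day = start
        while day < end:
            if day in window_days:
                occupied.add(day)
            day += timedelta(days=1)
    return len(occupied)


def summarise_period(
    timeline: PatientTimeline,
    period: Period,
    doc_stats: Mapping[str, DocStats],
    windows: WindowConfig | None = None,
) -> PeriodSummary:
    """Aggregate documents, quotations, appointments and bed-days for one
    patient over one comparison window."""
    if period is Period.NEITHER:
        raise ValueError("summaries are defined for the case and control windows only")
    w = windows or WindowConfig()
    n_documents = n_quotes = n_tokens = 0
    for doc in timeline.documents:
        if assign_window(doc.timestamp, timeline.index_date, w) is period:
            n_documents += 1
            stats = doc_stats[doc.doc_id]
            n_quotes += stats.n_quotes
            n_tokens += stats.n_tokens
    face_to_face = dna = 0
    for appt in timeline.appointments:
        if assign_window(appt.date, timeline.index_date, w) is period:
            if appt.attended:
                face_to_face += 1
            else:
                dna += 1
    if period is Period.CASE:
        window_days = _window_dates(timeline.index_date, w.case_start, w.case_end)
    else:
        window_days = _window_dates(timeline.index_date, w.control_start, w.control_end)
    return PeriodSummary(
        patient_id=timeline.patient_id,
        period=period,
        n_documents=n_documents,
        n_quotes=n_quotes,
        n_tokens=n_tokens,
        quotes_per_token=quotes_per_token(n_quotes, n_tokens),
        any_quote=int(n_quotes >= 1),
        face_to_face=face_to_face,
        dna=dna,
        bed_days=_bed_days(timeline.inpatient_stays, window_days),
    )


def build_matched_pairs(
    timelines: Sequence[PatientTimeline],
    doc_stats: Mapping[str, DocStats],
    windows: WindowConfig | None = None,
) -> tuple[list[MatchedPairRecord], dict[str, int]]:
    """One matched pair per patient with >=1 document in both windows.

    Returns (pairs, audit) where audit counts inclusions and the reason
    each excluded patient fell out.
    """
    w = windows or WindowConfig()
    pairs: list[MatchedPairRecord] = []
    audit = {
        "n_input": len(timelines),
        "n_included": 0,
        "excluded_no_case_documents": 0,
        "excluded_no_control_documents": 0,
        "excluded_no_documents_either_window": 0,
    }
    for tl in timelines:
        case = summarise_period(tl, Period.CASE, doc_stats, w)
        control = summarise_period(tl, Period.CONTROL, doc_stats, w)
        if case.n_documents >= 1 and control.n_documents >= 1:
            pairs.append(MatchedPairRecord(tl.patient_id, case=case, control=control))
            audit["n_included"] += 1
        elif case.n_documents == 0 and control.n_documents == 0:
            audit["excluded_no_documents_either_window"] += 1
        elif case.n_documents == 0:
            audit["excluded_no_case_documents"] += 1
        else:
            audit["excluded_no_control_documents"] += 1
    return pairs, audit
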