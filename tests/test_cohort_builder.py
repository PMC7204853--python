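"""Tests for ICD filtering, window logic and matched-pair assembly."""

from datetime import date, timedelta

import pytest

from quotecross.cohort_builder import (
    AdmissionRecord,
    Appointment,
    DocStats,
    MatchedPairRecord,
    NoQualifyingAdmissionError,
    PatientTimeline,
    Period,
    WindowConfig,
    assign_window,
    build_matched_pairs,
    extract_doc_stats,
    is_qualifying_admission,
    is_suicide_attempt_code,
    select_index_admission,
    summarise_period,
)
from quotecross.quote_extractor import RawDocument

INDEX = date(2014, 6, 15)


def _doc(doc_id, days_before, text="", pid="p1"):
    return RawDocument(doc_id, pid, INDEX - timedelta(days=days_before), text=text)


# ---------------------------------------------------------------------------
# ICD-10 filter
# ---------------------------------------------------------------------------


def _qualifies_by_printed_ranges(category: str) -> bool:
    """Independent oracle: direct transcription of the printed wildcard
    ranges X6*, X7*, X80-4*, Y1*, Y2*, Y30-4*, Y87*."""
    if category.startswith(("X6", "X7", "Y1", "Y2")):
        return True
    if category in ("X80", "X81", "X82", "X83", "X84"):
        return True
    if category in ("Y30", "Y31", "Y32", "Y33", "Y34"):
        return True
    return category == "Y87"


def test_icd_filter_matches_printed_ranges_for_every_category():
    for letter in "FXYZ":
        for num in range(100):
            cat = f"{letter}{num:02d}"
            assert is_suicide_attempt_code(cat) == _qualifies_by_printed_ranges(cat), cat


@pytest.mark.parametrize(
    "code, expected",
    [
        ("X61", True),
        ("X85", False),  # intentional-self-harm range stops at X84
        ("Y87.0", True),  # subcodes inherit the category
        ("Y35", False),
        ("x61", True),  # case-insensitive
        (" X700 ", True),  # 4-character subcode, stray whitespace
        ("F32.1", False),
    ],
)
def test_icd_filter_examples(code, expected):
    assert is_suicide_attempt_code(code) is expected


def test_icd_filter_rejects_malformed_codes():
    for bad in ("", "6X1", "XX", "X6"):
        with pytest.raises(ValueError):
            is_suicide_attempt_code(bad)


# ---------------------------------------------------------------------------
# Index admission
# ---------------------------------------------------------------------------


def _adm(admission, discharge, codes=("X61",), pid="p1"):
    return AdmissionRecord(pid, admission, discharge, tuple(codes))


def test_qualifying_admission_requires_code_and_overnight_stay():
    overnight = _adm(date(2010, 1, 1), date(2010, 1, 2))
    same_day = _adm(date(2010, 1, 1), date(2010, 1, 1))
    wrong_code = _adm(date(2010, 1, 1), date(2010, 1, 5), codes=("F32.1",))
    assert is_qualifying_admission(overnight)
    assert not is_qualifying_admission(same_day)
    assert not is_qualifying_admission(wrong_code)


def test_select_index_admission_earliest_then_longest():
    early = _adm(date(2012, 3, 1), date(2012, 3, 2))
    late = _adm(date(2014, 7, 9), date(2014, 7, 20))
    assert select_index_admission([late, early]) is early
    # same admission date: longer stay wins
    short = _adm(date(2012, 3, 1), date(2012, 3, 2))
    long = _adm(date(2012, 3, 1), date(2012, 3, 9))
    assert select_index_admission([short, long]) is long
    with pytest.raises(NoQualifyingAdmissionError):
        select_index_admission([_adm(date(2012, 3, 1), date(2012, 3, 1))])


def test_select_index_admission_respects_study_window():
    inside = _adm(date(2012, 3, 1), date(2012, 3, 2))
    before = _adm(date(2001, 1, 1), date(2001, 1, 2))
    assert select_index_admission([before, inside], study_start=date(2006, 4, 1)) is inside


# ---------------------------------------------------------------------------
# Window assignment
# ---------------------------------------------------------------------------


def test_assign_window_exhaustive_over_offsets():
    """Every day offset from -5 to 120 lands in exactly the printed
    window: case 1-30 days prior, control 61-90, otherwise neither."""
    for d in range(-5, 121):
        got = assign_window(INDEX - timedelta(days=d), INDEX)
        if 1 <= d <= 30:
            expected = Period.CASE
        elif 61 <= d <= 90:
            expected = Period.CONTROL
        else:
            expected = Period.NEITHER
        assert got is expected, d


def test_window_config_validation():
    with pytest.raises(ValueError):
        WindowConfig(case_start=1, case_end=70, control_start=61, control_end=90)


# ---------------------------------------------------------------------------
# Period summaries
# ---------------------------------------------------------------------------


def test_summarise_empty_window_is_all_zero():
    tl = PatientTimeline("p1", INDEX, documents=[_doc("d1", 45)])
    summary = summarise_period(tl, Period.CASE, {"d1": DocStats(3, 50)})
    assert summary.n_documents == 0
    assert summary.n_quotes == 0
    assert summary.any_quote == 0
    assert summary.quotes_per_token == 0.0


def test_summarise_aggregates_documents_and_appointments():
    tl = PatientTimeline(
        "p1",
        INDEX,
        documents=[_doc("d1", 10), _doc("d2", 75), _doc("d3", 20)],
        appointments=[
            Appointment(INDEX - timedelta(days=5), True),
            Appointment(INDEX - timedelta(days=12), False),
            Appointment(INDEX - timedelta(days=70), True),
        ],
    )
    stats = {"d1": DocStats(2, 100), "d2": DocStats(1, 40), "d3": DocStats(0, 60)}
    case = summarise_period(tl, Period.CASE, stats)
    assert case.n_documents == 2
    assert case.n_quotes == 2
    assert case.n_tokens == 160
    assert case.quotes_per_token == pytest.approx(2 / 160)
    assert case.any_quote == 1
    assert case.face_to_face == 1
    assert case.dna == 1
    control = summarise_period(tl, Period.CONTROL, stats)
    assert (control.n_documents, control.n_quotes, control.face_to_face, control.dna) == (1, 1, 1, 0)


def _brute_force_bed_days(stays, index, start_off, end_off):
    days = 0
    for off in range(start_off, end_off + 1):
        day = index - timedelta(days=off)
        if any(s <= day < e for s, e in stays):
            days += 1
    return days


@pytest.mark.parametrize(
    "stays",
    [
        [(INDEX - timedelta(days=40), INDEX + timedelta(days=5))],  # spans whole case window
        [(INDEX - timedelta(days=10), INDEX - timedelta(days=10))],  # same-day stay, no night
        [(INDEX - timedelta(days=95), INDEX - timedelta(days=80))],
        [(INDEX - timedelta(days=33), INDEX - timedelta(days=25))],  # straddles the gap
        [
            (INDEX - timedelta(days=20), INDEX - timedelta(days=15)),
            (INDEX - timedelta(days=18), INDEX - timedelta(days=10)),  # overlapping stays
        ],
    ],
)
def test_bed_days_match_day_by_day_enumeration(stays):
    tl = PatientTimeline("p1", INDEX, inpatient_stays=stays)
    case = summarise_period(tl, Period.CASE, {})
    control = summarise_period(tl, Period.CONTROL, {})
    assert case.bed_days == _brute_force_bed_days(stays, INDEX, 1, 30)
    assert control.bed_days == _brute_force_bed_days(stays, INDEX, 61, 90)
    assert case.bed_days <= 30 and control.bed_days <= 30


def test_full_window_stay_gives_thirty_bed_days():
    tl = PatientTimeline("p1", INDEX, inpatient_stays=[(INDEX - timedelta(days=40), INDEX + timedelta(days=5))])
    assert summarise_period(tl, Period.CASE, {}).bed_days == 30


# ---------------------------------------------------------------------------
# Matched pairs and invariance
# ---------------------------------------------------------------------------


def test_build_matched_pairs_applies_both_window_rule():
    both = PatientTimeline("both", INDEX, documents=[_doc("b1", 10, pid="both"), _doc("b2", 70, pid="both")])
    case_only = PatientTimeline("case_only", INDEX, documents=[_doc("c1", 10, pid="case_only")])
    neither = PatientTimeline("neither", INDEX, documents=[_doc("n1", 45, pid="neither")])
    stats = {d: DocStats(0, 10) for d in ("b1", "b2", "c1", "n1")}
    pairs, audit = build_matched_pairs([both, case_only, neither], stats)
    assert [p.patient_id for p in pairs] == ["both"]
    assert audit["n_input"] == 3
    assert audit["n_included"] == 1
    assert audit["excluded_no_control_documents"] == 1
    assert audit["excluded_no_documents_either_window"] == 1
    empty_pairs, empty_audit = build_matched_pairs([], stats)
    assert empty_pairs == [] and empty_audit["n_input"] == 0


def test_summaries_are_translation_invariant():
    """Shifting every date in a timeline by a constant changes nothing."""
    text = 'Patient said "I am fine" twice.'
    base_docs = [("d1", 10, text), ("d2", 70, text), ("d3", 45, "")]
    for shift in (0, 37, -400):
        index = INDEX + timedelta(days=shift)
        tl = PatientTimeline(
            "p1",
            index,
            documents=[RawDocument(i, "p1", index - timedelta(days=d), text=t) for i, d, t in base_docs],
            appointments=[Appointment(index - timedelta(days=7), True)],
            inpatient_stays=[(index - timedelta(days=25), index - timedelta(days=20))],
        )
        stats = extract_doc_stats(tl.documents)
        case = summarise_period(tl, Period.CASE, stats)
        control = summarise_period(tl, Period.CONTROL, stats)
        if shift == 0:
            reference = (case, control)
        else:
            assert (
                case.n_documents,
                case.n_quotes,
                case.face_to_face,
                case.bed_days,
            ) == (
                reference[0].n_documents,
                reference[0].n_quotes,
                reference[0].face_to_face,
                reference[0].bed_days,
            )
            assert control.n_documents == reference[1].n_documents


def test_pair_record_validates_period_slots():
    tl = PatientTimeline("p1", INDEX, documents=[_doc("d1", 10)])
    stats = {"d1": DocStats(1, 10)}
    case = summarise_period(tl, Period.CASE, stats)
    control = summarise_period(tl, Period.CONTROL, stats)
    with pytest.raises(ValueError):
        MatchedPairRecord("p1", case=control, control=case)
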