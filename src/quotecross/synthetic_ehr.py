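"""Seed-reproducible synthetic EHR timelines with gold quote annotations.

No patient-level mental-health record data can be shared, so the package
ships a generator that emulates the *structure* of such data: per-patient
document streams in two 30-day comparison windows, Poisson counts of
attended and missed outpatient appointments, occasional inpatient stays,
and an index admission carrying a qualifying ICD-10 code.  Document text
is assembled from clinical-style clause templates with quotations
injected at known offsets, so the extractor can be scored against exact
gold spans; optional "salting" adds the hazards the extractor must
reject (contractions, possessives, email/URL-only quotes, unclosed
runaway quotes).

The exposure effect is induced at the document level: a document in the
case window contains a quotation with probability ``p_quote_doc_case``
versus ``p_quote_doc_control`` in the control window.  The implied
pair-level discordant odds ratio is computed numerically (not assumed in
closed form) and echoed in ``true_parameters``; use
:func:`case_probability_for_pair_or` to calibrate a target OR.

Two rendering modes share one generative law:

* ``render_text=True`` builds full annotated documents (used for
  extractor round-trips and end-to-end pipeline runs);
* ``render_text=False`` draws only the per-window counts, vectorised
  across patients, for large simulation studies (the per-window counts
  have exactly the same distribution as the rendered path: a sum of n
  independent 1+Poisson(m) quote counts is n + Poisson(n*m), and token
  totals likewise add).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .cohort_builder import (
    AdmissionRecord,
    Appointment,
    MatchedPairRecord,
    PatientTimeline,
    Period,
    PeriodSummary,
    WindowConfig,
)
from .quote_extractor import DocType, RawDocument, count_tokens
from .quote_extractor import quotes_per_token as _qpt

__all__ = [
    "SimulationConfig",
    "SyntheticCorpus",
    "generate_annotated_document",
    "simulate_cohort",
    "pairs_from_counts",
    "window_prevalence",
    "implied_pair_or",
    "case_probability_for_pair_or",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for the synthetic cohort.

    Defaults reproduce the source study's reported cohort statistics:
    ~14.7 documents per 30-day window, window-level quotation prevalence
    near 58% (control) and 61% (case), mean face-to-face appointment
    counts 2.47/2.92 and missed-appointment counts 0.38/0.47
    (control/case), and roughly 2.3 inpatient bed-days per window.
    """

    n_patients: int = 1503
    seed: int = 0
    docs_per_window_mean: float = 14.7
    p_quote_doc_control: float = 0.060
    p_quote_doc_case: float = 0.064
    quotes_per_quoting_doc_mean: float = 0.7  # quote count = 1 + Poisson(mean)
    tokens_per_doc_min: int = 20
    tokens_per_doc_extra_mean: float = 100.0
    face_to_face_rate_case: float = 2.92
    face_to_face_rate_control: float = 2.47
    dna_rate_case: float = 0.47
    dna_rate_control: float = 0.38
    stay_probability: float = 0.20
    stay_mean_length: float = 10.0
    filler_docs_mean: float = 1.0  # documents in the 31-60 day gap, in no window
    delimiter_mix: tuple[tuple[str, float], ...] = (
        ('"', 0.5),
        ("“", 0.3),
        ("‘", 0.1),
        ("'", 0.1),
    )
    fraction_malformed: float = 0.10
    salting: bool = True
    render_text: bool = True
    require_both_windows: bool = True
    origin_date: date = date(2010, 1, 1)
    windows: WindowConfig = field(default_factory=WindowConfig)

    def __post_init__(self) -> None:
        for name in ("p_quote_doc_control", "p_quote_doc_case", "stay_probability", "fraction_malformed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in (
            "docs_per_window_mean",
            "quotes_per_quoting_doc_mean",
            "tokens_per_doc_extra_mean",
            "face_to_face_rate_case",
            "face_to_face_rate_control",
            "dna_rate_case",
            "dna_rate_control",
            "stay_mean_length",
            "filler_docs_mean",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.require_both_windows and self.docs_per_window_mean == 0:
            raise ValueError("inclusion-ready cohorts need a positive document rate")
        if not math.isclose(sum(w for _, w in self.delimiter_mix), 1.0, abs_tol=1e-9):
            raise ValueError("delimiter_mix weights must sum to 1")


@dataclass
class SyntheticCorpus:
    timelines: list[PatientTimeline]
    gold_spans: dict[str, list[tuple[int, int]]]
    admissions: list[AdmissionRecord]
    window_counts: dict[tuple[str, Period], dict[str, int]]
    true_parameters: dict


# ---------------------------------------------------------------------------
# Document rendering
# ---------------------------------------------------------------------------

_VOCAB = (
    "patient reports mood sleep appetite settled review plan risk team "
    "session ward attended discussed medication stable support family "
    "concerns engagement improving community nurse visit noted denies "
    "ideation history presentation calm cooperative followup care"
).split()

_QUOTE_WORDS = (
    "I feel better today nothing matters want to go home cannot cope "
    "things are looking up leave me alone thank you for listening"
).split()

_CONTRACTION_CLAUSE = "Patient says she can't sleep and won't eat at the moment. "
_POSSESSIVE_CLAUSE = "Discussed the patients' needs with the carers' group. "
_EMAIL_QUOTE = '"duty.worker@example.org" '
_URL_QUOTE = '"https://example.org/crisis-line" '
_STRAY_CLOSER = "Noted transcription artefact ” in the original letter. "


def _clause(rng: np.random.Generator) -> str:
    k = int(rng.integers(4, 9))
    words = rng.choice(_VOCAB, size=k)
    return " ".join(words).capitalize() + ". "


def _quote_content(rng: np.random.Generator, allow_contraction: bool) -> str:
    k = int(rng.integers(2, 8))
    words = list(rng.choice(_QUOTE_WORDS, size=k))
    if allow_contraction and rng.random() < 0.3:
        words.insert(int(rng.integers(0, len(words) + 1)), "can't")
    return " ".join(words)


_PAIR = {'"': '"', "“": "”", "'": "'", "‘": "’"}


def generate_annotated_document(
    rng: np.random.Generator,
    doc_id: str,
    patient_id: str,
    timestamp: date,
    n_quotes: int,
    delimiter_mix: Sequence[tuple[str, float]] = SimulationConfig.delimiter_mix,
    salting: bool = True,
    malformed: bool = False,
) -> tuple[RawDocument, list[tuple[int, int]]]:
    """One clinical-style document containing exactly ``n_quotes``
    well-formed quotations at recorded offsets.

    Salting interleaves apostrophe traps, a stray close-quote and
    email/URL-only quotes (all excluded from gold); ``malformed`` appends
    an unclosed runaway quote (> 1500 characters of content, no closer),
    also excluded from gold.
    """
    openers = [c for c, _ in delimiter_mix]
    weights = np.array([w for _, w in delimiter_mix], dtype=float)
    weights = weights / weights.sum()
    parts: list[str] = []
    gold: list[tuple[int, int]] = []
    pos = 0

    def emit(s: str) -> None:
        nonlocal pos
        parts.append(s)
        pos += len(s)

    emit(_clause(rng))
    for _ in range(n_quotes):
        if salting and rng.random() < 0.25:
            emit(rng.choice([_CONTRACTION_CLAUSE, _POSSESSIVE_CLAUSE, _STRAY_CLOSER]))
        opener = openers[int(rng.choice(len(openers), p=weights))]
        closer = _PAIR[opener]
        content = _quote_content(rng, allow_contraction=opener in ('"', "“"))
        if opener == "“" and rng.random() < 0.3:
            # nested subquotation, absorbed into the outer span
            content += " “" + _quote_content(rng, False) + "”"
        start = pos
        emit(opener + content + closer)
        gold.append((start, pos))
        emit(" ")
        emit(_clause(rng))
    if salting and rng.random() < 0.3:
        emit(rng.choice([_EMAIL_QUOTE, _URL_QUOTE]))
        emit(_clause(rng))
    if malformed:
        # unclosed opener followed by a long run of quote-free text: the
        # candidate exceeds the length cap and must be discarded whole
        emit('Letter fragment: "')
        filler = " ".join(rng.choice(_VOCAB, size=400))
        emit(filler[:1600])
    doc = RawDocument(
        doc_id=doc_id,
        patient_id=patient_id,
        timestamp=timestamp,
        doc_type=DocType.CASE_NOTE,
        text="".join(parts),
    )
    return doc, gold


# ---------------------------------------------------------------------------
# Exposure calibration
# ---------------------------------------------------------------------------


def window_prevalence(doc_mean: float, p_quote_doc: float, truncated: bool = True) -> float:
    """P(at least one quoting document in a window) when the document
    count is Poisson(doc_mean), optionally zero-truncated, and each
    document quotes independently with probability p_quote_doc.

    Computed by numerical summation over the count distribution.
    """
    if doc_mean <= 0:
        return 0.0
    k_max = int(stats.poisson.ppf(1 - 1e-12, doc_mean)) + 1
    ks = np.arange(0, k_max + 1)
    pmf = stats.poisson.pmf(ks, doc_mean)
    if truncated:
        pmf[0] = 0.0
        pmf = pmf / pmf.sum()
    none = np.sum(pmf * (1.0 - p_quote_doc) ** ks)
    return float(1.0 - none)


def implied_pair_or(cfg: SimulationConfig) -> float:
    """Pair-level discordant odds ratio implied by the per-document quote
    probabilities (windows independent given the patient)."""
    p1 = window_prevalence(cfg.docs_per_window_mean, cfg.p_quote_doc_case, cfg.require_both_windows)
    p0 = window_prevalence(cfg.docs_per_window_mean, cfg.p_quote_doc_control, cfg.require_both_windows)
    return (p1 / (1 - p1)) / (p0 / (1 - p0))


def case_probability_for_pair_or(
    target_or: float, doc_mean: float, p_quote_doc_control: float, truncated: bool = True
) -> float:
    """Per-document case-window quote probability that induces the target
    pair-level discordant odds ratio, solved numerically."""
    p0 = window_prevalence(doc_mean, p_quote_doc_control, truncated)
    target_p1 = target_or * p0 / (1 - p0) / (1 + target_or * p0 / (1 - p0))

    def gap(p: float) -> float:
        return window_prevalence(doc_mean, p, truncated) - target_p1

    return float(optimize.brentq(gap, 1e-9, 1 - 1e-9, xtol=1e-12))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


_QUALIFYING_CODES = ("X61", "X64", "X70", "X78", "X84", "Y12", "Y25", "Y31", "Y87")


def _truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    draws = rng.poisson(lam, size=size)
    while True:
        zeros = draws == 0
        if not zeros.any():
            return draws
        draws[zeros] = rng.poisson(lam, size=int(zeros.sum()))


def _truncate_stay_lengths(start_offsets: np.ndarray, lengths: np.ndarray, w_start: int) -> np.ndarray:
    """Clip stay lengths so every occupied night remains inside the stay's
    own window: a stay beginning ``start_offsets`` days before the index
    date and running forward occupies nights at offsets start, start-1,
    ..., which are truncated at the window's near edge ``w_start``."""
    return np.minimum(lengths, start_offsets - w_start + 1)


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCorpus:
    """Draw a complete synthetic cohort under ``cfg``.

    Fully reproducible: every random draw flows from ``cfg.seed``.  When
    ``cfg.require_both_windows`` each patient is guaranteed at least one
    document in both comparison windows (zero-truncated document counts),
    matching the analysis inclusion rule.
    """
    rng = np.random.default_rng(cfg.seed)
    w = cfg.windows
    n = cfg.n_patients

    index_offsets = rng.integers(2 * w.control_end, 2 * w.control_end + 3000, size=n)
    window_specs = {
        Period.CASE: (w.case_start, w.case_end, cfg.p_quote_doc_case, cfg.face_to_face_rate_case, cfg.dna_rate_case),
        Period.CONTROL: (
            w.control_start,
            w.control_end,
            cfg.p_quote_doc_control,
            cfg.face_to_face_rate_control,
            cfg.dna_rate_control,
        ),
    }

    timelines: list[PatientTimeline] = []
    gold_spans: dict[str, list[tuple[int, int]]] = {}
    admissions: list[AdmissionRecord] = []
    window_counts: dict[tuple[str, Period], dict[str, int]] = {}

    # --- per-window structural draws, vectorised across patients -----------
    draws: dict[Period, dict[str, np.ndarray]] = {}
    for period, (w_start, w_end, p_quote, f2f_rate, dna_rate) in window_specs.items():
        if cfg.require_both_windows:
            n_docs = _truncated_poisson(rng, cfg.docs_per_window_mean, n)
        else:
            n_docs = rng.poisson(cfg.docs_per_window_mean, size=n)
        n_quoting = rng.binomial(n_docs, p_quote)
        n_quotes = n_quoting + rng.poisson(cfg.quotes_per_quoting_doc_mean * n_quoting)
        n_tokens = cfg.tokens_per_doc_min * n_docs + rng.poisson(cfg.tokens_per_doc_extra_mean * n_docs)
        f2f = rng.poisson(f2f_rate, size=n)
        dna = rng.poisson(dna_rate, size=n)
        has_stay = rng.random(n) < cfg.stay_probability
        stay_start = rng.integers(w_start, w_end + 1, size=n)
        stay_len = _truncate_stay_lengths(
            stay_start, rng.geometric(1.0 / cfg.stay_mean_length, size=n), w_start
        )
        bed = np.where(has_stay, stay_len, 0)
        draws[period] = dict(
            n_docs=n_docs,
            n_quoting=n_quoting,
            n_quotes=n_quotes,
            n_tokens=n_tokens,
            f2f=f2f,
            dna=dna,
            has_stay=has_stay,
            stay_start=stay_start,
            stay_len=stay_len,
            bed_days=bed,
        )

    # --- assemble per-patient timelines -------------------------------------
    # In count mode (render_text=False) the timelines carry no event
    # objects: the per-window count draws above are the corpus, which is
    # what keeps large simulation studies cheap.
    for i in range(n):
        pid = f"P{i:05d}"
        index_date = cfg.origin_date + timedelta(days=int(index_offsets[i]))
        documents: list[RawDocument] = []
        appointments: list[Appointment] = []
        stays: list[tuple[date, date]] = []
        doc_serial = 0
        for period, (w_start, w_end, _, _, _) in window_specs.items():
            d = draws[period]
            k = int(d["n_docs"][i])
            doc_tokens_total = int(d["n_tokens"][i]) if k else 0
            if cfg.render_text:
                n_quoting = int(d["n_quoting"][i])
                # distribute the window quote total over its quoting documents
                per_doc_quotes = [0] * k
                if n_quoting:
                    extra = int(d["n_quotes"][i]) - n_quoting
                    alloc = (
                        rng.multinomial(extra, np.full(n_quoting, 1.0 / n_quoting))
                        if extra
                        else np.zeros(n_quoting, dtype=int)
                    )
                    quoting_idx = rng.choice(k, size=n_quoting, replace=False)
                    for j, qi in enumerate(quoting_idx):
                        per_doc_quotes[int(qi)] = 1 + int(alloc[j])
                window_docs: list[RawDocument] = []
                for j in range(k):
                    day = int(rng.integers(w_start, w_end + 1))
                    doc_id = f"{pid}-D{doc_serial:04d}"
                    doc_serial += 1
                    malformed = cfg.salting and rng.random() < cfg.fraction_malformed
                    doc, gold = generate_annotated_document(
                        rng,
                        doc_id,
                        pid,
                        index_date - timedelta(days=day),
                        per_doc_quotes[j],
                        delimiter_mix=cfg.delimiter_mix,
                        salting=cfg.salting,
                        malformed=malformed,
                    )
                    window_docs.append(doc)
                    gold_spans[doc_id] = gold
                documents.extend(window_docs)
                # token totals follow the rendered text, not the count draw
                doc_tokens_total = sum(count_tokens(doc.text) for doc in window_docs)
                for _ in range(int(d["f2f"][i])):
                    appointments.append(
                        Appointment(index_date - timedelta(days=int(rng.integers(w_start, w_end + 1))), True)
                    )
                for _ in range(int(d["dna"][i])):
                    appointments.append(
                        Appointment(index_date - timedelta(days=int(rng.integers(w_start, w_end + 1))), False)
                    )
                if bool(d["has_stay"][i]):
                    s_off = int(d["stay_start"][i])
                    length = int(d["stay_len"][i])
                    s_date = index_date - timedelta(days=s_off)
                    stays.append((s_date, s_date + timedelta(days=length)))
            window_counts[(pid, period)] = dict(
                n_documents=k,
                n_quotes=int(d["n_quotes"][i]) if k else 0,
                n_tokens=doc_tokens_total,
                any_quote=int(k > 0 and d["n_quotes"][i] > 0),
                face_to_face=int(d["f2f"][i]),
                dna=int(d["dna"][i]),
                bed_days=int(d["bed_days"][i]),
            )
        # filler documents in the 31-60 day gap exercise the 'neither' window
        if cfg.render_text and cfg.filler_docs_mean > 0:
            for _ in range(int(rng.poisson(cfg.filler_docs_mean))):
                day = int(rng.integers(w.case_end + 1, w.control_start))
                doc_id = f"{pid}-D{doc_serial:04d}"
                doc_serial += 1
                doc, gold = generate_annotated_document(
                    rng,
                    doc_id,
                    pid,
                    index_date - timedelta(days=day),
                    int(rng.random() < cfg.p_quote_doc_control),
                    delimiter_mix=cfg.delimiter_mix,
                    salting=cfg.salting,
                )
                documents.append(doc)
                gold_spans[doc_id] = gold
        code = _QUALIFYING_CODES[int(rng.integers(0, len(_QUALIFYING_CODES)))]
        admissions.append(
            AdmissionRecord(
                patient_id=pid,
                admission_date=index_date,
                discharge_date=index_date + timedelta(days=int(rng.integers(1, 5))),
                icd_codes=(code, "F32"),
            )
        )
        timelines.append(
            PatientTimeline(
                patient_id=pid,
                index_date=index_date,
                documents=documents,
                appointments=appointments,
                inpatient_stays=stays,
            )
        )

    true_parameters = {
        "config": {
            k: (v.isoformat() if isinstance(v, date) else v)
            for k, v in vars(cfg).items()
            if not isinstance(v, WindowConfig)
        },
        "window_prevalence_case": window_prevalence(
            cfg.docs_per_window_mean, cfg.p_quote_doc_case, cfg.require_both_windows
        ),
        "window_prevalence_control": window_prevalence(
            cfg.docs_per_window_mean, cfg.p_quote_doc_control, cfg.require_both_windows
        ),
        "implied_pair_or": implied_pair_or(cfg),
    }
    return SyntheticCorpus(
        timelines=timelines,
        gold_spans=gold_spans,
        admissions=admissions,
        window_counts=window_counts,
        true_parameters=true_parameters,
    )


def pairs_from_counts(corpus: SyntheticCorpus) -> list[MatchedPairRecord]:
    """Matched pairs assembled directly from the generator's per-window
    count draws (the fast path for simulation studies; identical in law
    to extracting rendered documents and building pairs)."""
    pairs: list[MatchedPairRecord] = []
    for tl in corpus.timelines:
        summaries = {}
        ok = True
        for period in (Period.CASE, Period.CONTROL):
            c = corpus.window_counts[(tl.patient_id, period)]
            if c["n_documents"] < 1:
                ok = False
                break
            summaries[period] = PeriodSummary(
                patient_id=tl.patient_id,
                period=period,
                n_documents=c["n_documents"],
                n_quotes=c["n_quotes"],
                n_tokens=c["n_tokens"],
                quotes_per_token=_qpt(c["n_quotes"], c["n_tokens"]),
                any_quote=c["any_quote"],
                face_to_face=c["face_to_face"],
                dna=c["dna"],
                bed_days=c["bed_days"],
            )
        if ok:
            pairs.append(
                MatchedPairRecord(tl.patient_id, case=summaries[Period.CASE], control=summaries[Period.CONTROL])
            )
    return pairs
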