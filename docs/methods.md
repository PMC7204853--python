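# Methods

## Quoted-speech extraction

The extractor scans each document left to right, outside-in. Five
characters form the delimiter inventory, in four classes that pair only
with themselves: straight double `"` (self-pairing), curly double
`“`→`”`, straight single `'` (self-pairing), curly single `‘`→`’`.
Cross-style pairing (e.g. `“ … "`) is rejected by construction: on
messy clinical text it manufactures far more false positives than it
recovers, and a missed mismatched quote is the cheaper error.

Single-quote characters are first screened as apostrophes. A single
quote is an apostrophe, never a delimiter, when a letter is immediately
to its left and either (a) a letter is immediately to its right
(`rock'n'roll`) or (b) one of the contraction suffixes
`{c, d, e, m, n, s, t, ve, re, ll, all}` follows, ending at a non-letter
boundary (`can't`, `we've`, `y'all`). The same screen applies to
candidate closers, so `…patients's…` cannot end a quotation. A straight
single quote outside any quotation that trails a word
(`the patients' needs`) is also treated as an apostrophe: with no opener
pending it can only be a possessive. A curly `’` with no pending `‘`
likewise never opens.

Once an opener is accepted, the scanner looks for a closer of the same
class. Any other quote characters encountered meanwhile belong to the
quotation (subquotation absorption). For the curly classes — whose
opener and closer are distinct glyphs — a nesting counter is kept, so
`“a “b” c”` yields the single outer span; the self-pairing straight
classes cannot nest and close at the first non-apostrophe occurrence.
The nesting counter is this package's reading of "inner quotations are
absorbed": without it a nested curly quotation would truncate the outer
span at the inner closer.

A candidate is accepted only if its content is at most
`max_quote_chars` (default 1500) characters; otherwise the opener is
treated as stray and scanning resumes immediately after it — runaway
candidates are discarded, not truncated, because an unclosed quote
should contribute nothing rather than a 1500-character prefix. Spans
whose whitespace-trimmed content entirely matches the email pattern
(`local@domain` with a dotted domain) or URL pattern (`scheme://…` or
`www.…`) are removed. Offsets are 0-based half-open; `content` excludes
the delimiters. Input is processed as-is (no Unicode normalisation);
typographic quotes outside the inventory (`„`, `«`) are ignored.

Word tokens are maximal alphanumeric runs (`[A-Za-z0-9]+`,
configurable); `quotes_per_token = n_quotes / n_tokens` normalises
exposure for text volume, with 0/0 defined as 0 and quotes-without-
tokens an error.

## Span evaluation

A prediction is a true positive only when its (start, end) offsets
exactly equal a gold span — the strictest reproducible criterion, with
no partial credit. Metrics: precision `tp/(tp+fp)`, recall
`tp/(tp+fn)`, F their harmonic mean, and accuracy `tp/(tp+fp+fn)`, a
Jaccard-style agreement over the union of predicted and gold spans (the
definition is an inference: it reproduces published whole-number
accuracies from their precision/recall companions to rounding).
Corpus-level scores are micro-averaged (counts pooled over documents
before ratios), so document order is immaterial.

## Cohort construction

* **Qualifying event.** An admission qualifies when any of its ICD-10
  codes falls in X60–X84 (intentional self-harm), Y10–Y34 (undetermined
  intent) or Y87 (sequelae), comparing the 3-character category after
  stripping dots/suffixes — subcodes inherit the category — and the
  admission and discharge dates differ (the at-least-24-hours proxy at
  day resolution).
* **Index date.** Admission date of the earliest qualifying admission
  inside the configurable study date range (default open); ties broken
  by longest stay, then input order.
* **Windows.** Day arithmetic on calendar dates, no time-of-day. With
  `d = index_date − event_date` in whole days: case iff `1 ≤ d ≤ 30`,
  control iff `61 ≤ d ≤ 90`, both boundaries inclusive; the index day
  and the 31–60-day gap belong to neither window. All summaries are
  invariant under translating a patient's entire timeline.
* **Bed-days.** Day-level interval intersection: a stay [start, end]
  occupies the nights of start … end−1, and a window's bed-day count is
  the number of distinct window dates so occupied (≤ 30; a same-day
  stay contributes none). Partial-overlap handling is otherwise
  unspecified in the source design and this is the package's choice.
* **Inclusion.** One matched pair per patient with ≥ 1 document in both
  windows; every exclusion is tallied by reason in an audit record.

## Matched-pair inference

The paired t-test is the textbook statistic on case-minus-control
differences with a t-distribution 95% CI on n−1 df. Identical vectors
return the null result (t = 0, p = 1); constant nonzero differences
raise a degenerate-input error, since zero sample variance around a
nonzero mean supports no t-based inference.

Conditional logistic regression uses the 1:1 conditional likelihood,
equivalent to an intercept-free logit on within-pair differences with
all responses 1. Numerical choices: Newton–Raphson from β = 0 with
analytic score and observed information; convergence when
max |score| < 1e-8 or max |step| < 1e-10; hard cap 50 iterations
(non-convergence raises, carrying the last iterate). Pairs with an
all-zero difference row contribute a constant −log 2 to the likelihood
and are excluded, reported via `n_informative_pairs` /
`n_dropped_pairs`. Complete separation is detected two ways — a
diverging iterate (‖β‖∞ > 30) or a converged log-likelihood above
−1e-6 (every pair predicted perfectly) — and raises rather than
returning an artefact of the stopping rule. Standard errors are Wald,
from the inverse observed information at the optimum; intervals
`exp(β ± 1.96·SE)`; p-values normal two-sided. Profile-likelihood or
exact conditional intervals are out of scope.

For one binary exposure the estimator collapses to the discordant-pair
closed form `OR = n10/n01`, `SE(log OR) = √(1/n10 + 1/n01)`; the
iterative fit is verified against this identity to better than six
significant figures, and against statsmodels' `ConditionalLogit` for
the multivariable case. Both the binary (`any_quote`) and
length-normalised (`quotes_per_token`) exposure codings are supported;
covariates enter as raw within-pair count differences, unscaled, so
ORs are per unit difference.

One unit ambiguity is inherited from the source context: a reported
mean "quotations per token" of 0.16 is implausibly high for a literal
per-word rate. The package implements the literal definition and takes
no position on the original unit; no reproduced quantity depends on it.

## Synthetic-EHR generator

The generator emulates the *structure* of a mental-health record
cohort, not clinical language. Defaults were fixed once from the
reported cohort statistics and are the package's standing study
conditions:

| parameter | default | basis |
|---|---|---|
| `n_patients` | 1503 | analysed cohort size |
| `docs_per_window_mean` | 14.7 | mean documents per 30-day window |
| `p_quote_doc_control` | 0.060 | back-solved so window prevalence ≈ 58.3% |
| `p_quote_doc_case` | 0.064 | back-solved so window prevalence ≈ 61.1% |
| `quotes_per_quoting_doc_mean` | 0.7 | quote count = 1 + Poisson(0.7) per quoting document |
| `face_to_face_rate_*` | 2.47 / 2.92 | control/case appointment means |
| `dna_rate_*` | 0.38 / 0.47 | control/case missed-appointment means |
| `stay_probability`, `stay_mean_length` | 0.20, 10 | ≈ 2.3 bed-days per window on average |

Document counts per window are Poisson, zero-truncated when an
inclusion-ready cohort is requested, so the both-windows rule is
satisfied by construction. Each document quotes independently with the
window-specific probability; the implied window prevalence
`P = 1 − E[(1−p)^K]` is evaluated by numerical summation over the count
distribution, and the implied pair-level discordant OR
`odds(P_case)/odds(P_control)` is recorded in `true_parameters` rather
than assumed in closed form. `case_probability_for_pair_or` inverts the
mapping (Brent's method) to calibrate a target OR. Inpatient stays are
clipped to their own window so the generator's per-window draws and the
cohort builder's summaries agree exactly.

Rendered documents are assembled from clinical-style clause templates
over a small vocabulary, with quotations injected at recorded offsets
across a configurable mix of delimiter classes (curly-double quotes
occasionally carry a nested subquotation, absorbed into the gold span).
Salting interleaves the traps the extractor must reject — contraction
and possessive clauses, a stray curly closer, email/URL-only quotes,
and (at rate `fraction_malformed`) a document-final unclosed quote
followed by > 1500 quote-free characters — none of which enter the gold
standard. Dates are anchored at an arbitrary origin (2010-01-01 by
default); translation invariance of the analysis makes the choice
immaterial.

With `render_text=False` the generator stops at the per-window counts,
vectorised across patients (a sum of n independent 1 + Poisson(m)
quote counts is n + Poisson(nm), and token totals add the same way, so
the two modes share one generative law; token totals in count mode are
drawn as 20 + Poisson(100) per document rather than counted from text).
This is the path used for repeated-simulation studies — e.g. 500
replicates of a 2000-patient cohort for Wald-interval calibration run
in well under a minute — while the rendered path, verified to
reproduce the drawn counts exactly through the full extract/build
pipeline, carries the text-level guarantees across to it.

What passing on synthetic data does *not* show: the generator draws the
two windows independently within a patient (real cohorts show positive
dependence of quotation presence across windows), makes quote
probability independent of document length and of the covariates, and
contains no realistic clinical language, misspellings, OCR noise or
clinician-specific quoting styles. Extraction performance of 1.0 on the
round-trip is a correctness check of the rules, not an estimate of
performance on real clinical text, where grammatically inconsistent
quoting (dropped or mismatched marks) is the dominant error source and
is deliberately not "repaired" by the extractor. Speaker attribution of
quotations is out of scope throughout.

## Pipeline

`run_pipeline` executes extract → build-pairs → fit, validating stage
outputs as it goes, and writes spans, the pair table, the exclusion
audit, the fit report and a manifest (SHA-256 of the configuration,
seed, package version, exclusion counts). Re-running with the same
configuration reproduces identical outputs. Errors name the failing
stage; malformed JSONL inputs name the offending line.
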