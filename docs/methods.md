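# Methods

## Model and procedure

`wellsauto` implements the two-tier Wells prediction rule for pulmonary
embolism as a deterministic, rule-based extraction pipeline over a single
emergency-department encounter anchored at the CTPA order time
(`index_order_time`). The governing assumption throughout is **pre-order
temporality**: the automated score may use only information that was in the
record strictly before the order, because that is all a real-time decision
aid could have seen. Records timestamped exactly at the order time are
excluded — they are taken to be spawned by the order itself. Problem-list
entries with no documented time are counted as pre-index by default
(problem lists commonly lack onset dates); `include_undated=False` excludes
them.

The score is carried internally in integer half-point units (3 pts = 6,
1.5 pts = 3, 1 pt = 2) so the strict `score > 4` tier boundary is exact and
immune to floating-point drift. The boundary matters in practice: with
gestalt assumed, gestalt + hemoptysis = 4.0 is *PE unlikely*, and any single
additional component of weight ≥ 1 pushes the encounter over.

**Gestalt.** The "PE as/more likely than alternative diagnosis" item cannot
be extracted from data; it is assumed positive for every scored encounter on
the grounds that a clinician who ordered a CTPA had high enough suspicion.
This raises the floor of every automated score to 3 points and is an
explicit, disable-able configuration flag (`gestalt_assumed`), not a
hard-coded constant.

## Text components

The DVT-signs lexicon is generated, not curated: each of 8 descriptors
(3 prefix: "edema to", "swollen", "pain in"; 5 suffix: "swelling",
"swollen", "edema", "pain", "discomfort") is paired with each of 6
lower-extremity anatomic surface terms ("le", "lower extremity", "leg",
"lower leg", "thigh", "calf") and 4 laterality slots (left, right,
bilateral, none), laterality placed immediately before the anatomic term.
This yields 192 distinct phrases with no collisions. "swollen" is
intentionally present in both descriptor positions ("swollen leg" and
"leg swollen" are both idiomatic). The pairing/ordering scheme is this
package's own design choice: it is the unique arrangement of the published
term categories that reproduces the published phrase count, and clinical
word order fixes the laterality placement. Abbreviated surface forms
("l", "r", "b/l", "bl", "le") are not enumerated as separate phrases;
the matcher folds them onto canonical tokens via a configurable synonym map
at search time, which keeps the lexicon compact while matching the
abbreviation-heavy dialect of triage notes. Whether the original process
enumerated abbreviation variants as distinct list entries is unknowable
from the published material; under this design it makes no observable
difference to matching behavior.

Matching normalizes text (lowercase; punctuation except intra-token `/` and
`-` to spaces; whitespace collapsed — an idempotent map), tokenizes, expands
synonyms and hyphens ("blood-tinged" ≡ "blood tinged"), then scans greedily
left-to-right preferring the longest phrase, on token boundaries only
("blegs" never matches "leg"). Free-text and discrete chief-complaint
options are space-joined before matching. The exact normalization applied by
the original process is undocumented; this pipeline is a reconstruction and
is exercised by case/whitespace-invariance and self-recognition property
tests.

**Negation is off by default.** The validated process had no negation
handling and its measured false positives include triage phrases preceded by
words of negation; the default must replicate that behavior. The optional
`window` mode flags a match when a cue from a small NegEx-style list ("no",
"denies", "denied", "without", "not", "neg for", "negative for") occurs
within the 3 tokens preceding it. Cue list and window size are this
package's choices; they are deliberately minimal.

## Structured components

* **Tachycardia** — maximum pre-order heart rate, strictly > 100 bpm.
* **Immobilization/surgery** — any ICU stay or operative note (general
  anesthesia) whose interval overlaps the 30 days before the order, or a
  quadriplegia code (ICD-10 G82.5*, ICD-9 344.0*) documented pre-index.
  An ICU stay counts if any part of the stay overlaps the window.
  No broader immobility heuristic is attempted: bed-bound states described
  only in notes are a documented miss mode of this class of pipeline, and
  the synthetic generator reproduces it rather than papering over it.
* **Prior PE/DVT** — problem-list codes: PE 415.1, 415.11–415.13, 415.19,
  V12.55 (ICD-9), I26.99 (ICD-10); DVT 453.4–453.9 (range with child-code
  coverage: 453.41 ∈ 453.4–453.9), V12.51, I82.409.
* **Active malignancy** — ICD-10 malignant-neoplasm chapter C00–C96.
  Personal-history Z85 codes are excluded: the known false-positive mode of
  problem-list queries is *stale* cancer entries, so the default group
  should not widen toward history codes. All code sets are configurable
  from YAML/JSON and printable for audit (`wellsauto codesets`).

ICD-9 range membership truncates the code to the range's decimal precision
and compares numerically, which is equivalent to enumerating every child
code to two decimal places (the test suite checks exactly that equivalence
against a brute-force enumeration oracle).

## Concordance

A PE-likely encounter's CTPA order is concordant unconditionally; a
PE-unlikely encounter's order is concordant only with a pre-order D-dimer
strictly above the upper limit of normal (default 230 ng/mL; a value exactly
at the limit is normal). When several pre-order D-dimers exist the latest —
most proximate to the ordering decision — governs. Requiring the D-dimer
*order* (rather than its result) to precede the CTPA order is a deliberate
resolution of an ambiguity in the underlying guideline phrasing; it is the
reading consistent with treating "no D-dimer ordered prior to CTPA" as
non-concordant.

## Validation metrics

All rates are exact `Fraction`s; percent strings are produced only at the
reporting boundary, rounding half away from zero — one decimal place for
classification metrics, concordance and yields, and adaptive precision
(one decimal below 10%, integer otherwise) for the component table. Pooled
component accuracy is computed over the six non-gestalt components:
(cells − FN − FP) / cells with cells = 6 × N. Classification metrics with a
zero denominator are reported as absent, never as zero. Cohen's kappa uses
the standard marginal-chance correction and returns 1 when both raters are
constant and identical; it is cross-checked against scikit-learn in tests
and validated against hand-computed and closed-form cases. The kappa of the
original two-clinician chart review is not recomputable (no rater-level data
exist) and is not a package output.

## Synthetic cohorts

The generator emulates the *documented record structure* of an ED encounter
and the *documented failure modes* of a triage-fields-plus-problem-list
pipeline:

* **doc_gap** — a gold-true finding appears only in `provider_note_text`,
  a field the pipeline never reads (dominant false-negative mode);
* **stale entries** — PE/DVT or malignancy codes on the problem list of a
  gold-negative encounter (dominant structured false-positive mode);
* **negated phrases** — "denies ⟨phrase⟩" in triage text (text
  false-positive mode when negation is off);
* **erroneous vitals** — a spurious pre-order tachycardic reading.

Default parameters of `SynthConfig` are the rates observed in the
202-encounter validation cohort the package models (e.g. DVT-sign
prevalence 28/202 with documentation-gap rate 13/28; stale-malignancy rate
8/155; D-dimer ordered in 28/76 unlikely encounters, abnormal in 25/28).
Every encounter also carries post-order distractor records (a heart-rate
spike after the order, occasionally a post-index PE code), so temporal
censoring is continuously exercised: stripping all post-index records must
never change any output.

`paper_mode_cohort` places errors deterministically from a fixed stratum
table rather than sampling, so the published confusion structure — the
component capture table, the 119/7/9/67 classification matrix, per-tier
CTPA yields 20/126 and 6/76, and concordance counts 25/3/48 among the 76
automated-unlikely encounters — is reproduced *exactly*, not in
expectation. The joint distribution of components beyond those audited
marginal counts is unpublished; the stratum table is a minimal consistent
completion (for example, the one DVT-component false positive not
attributable to negation is placed on a gold-likely encounter, the only
placement consistent with both the component table and the classification
audit). The seed varies only surface realization: which lexicon phrase,
which code, which vital values, and record order.

What passing these tests shows — and does not. The synthetic cohorts prove
the pipeline's logic: extraction correctness, temporality, the exact
arithmetic of scores and metrics, and sensitivity/specificity behavior
under known error rates. They do not model real clinical language
(misspellings, novel phrasings, section structure), coding practice
variation across institutions, or correlated comorbidity structure; measured
performance on synthetic data therefore validates the machinery, not the
clinical generalizability of the phrase lists.

## Numerical and design choices

* Score arithmetic in half-point integers; tier test exact.
* Strict inequalities at every published cutoff: HR > 100, score > 4,
  D-dimer > 230.
* Deterministic matcher tie-break: longest phrase first, then
  lexicographically first among canonically identical phrases
  ("pain in le" ≡ "pain in lower extremity" after synonym folding).
* All randomness flows from a single `random.Random(seed)`; cohorts are
  byte-identical across runs for a given seed.
* Problem sizes in the test suite: property tests use cohorts of 150–500;
  parameter-recovery checks use n = 2000, where binomial 95% intervals are
  tight enough to be informative for the default rates.

## Known limitations

* The 192-phrase list is a reconstruction of an unpublished supplementary
  listing from its published generating recipe and count; individual phrases
  could differ from the original even though the construction and totals
  match.
* The institutional malignancy and quadriplegia groupings behind the
  original structured queries are unpublished; the defaults here are
  standard chapter/category groupings and fully overridable.
* "Immobilization ≥ 3 days" has no faithful structured proxy; the extractor
  intentionally under-covers it.
* Guideline concordance uses D-dimer order-time precedence (see above);
  institutions wanting result-time precedence must filter upstream.
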