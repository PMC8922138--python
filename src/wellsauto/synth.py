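"""Synthetic ED-encounter cohorts with chart-review gold annotations.

Real triage notes and problem lists cannot be shared, so testing rests on a
generator that emulates the documented structure of such records *and* the
documented ways an automated process fails on them:

* **documentation gap** — a finding the chart reviewer saw, but only in the
  provider note (``provider_note_text``), which a triage-fields-only pipeline
  never reads: the dominant false-negative mode;
* **stale / erroneous problem-list entries** — PE/DVT or malignancy codes on
  the problem list for encounters where chart review found no such history:
  the dominant structured false-positive mode;
* **negated phrases** — "denies leg swelling" in triage text, a false
  positive for a matcher with no negation handling;
* **erroneous vital entries** — a spurious pre-order tachycardic heart rate.

Every encounter also carries distractor records *after* the CTPA order time
(a post-order heart-rate spike, occasionally a post-index PE code) so the
pre-order temporal censoring is exercised constantly.

Two entry points: :func:`generate_cohort` samples a cohort from configurable
prevalence and error-rate parameters (defaults are the rates observed in the
validation study this package models); :func:`paper_mode_cohort` builds a
fixed 202-encounter cohort whose gold prevalences and injected error counts
are placed deterministically — sampled without replacement, not in
expectation — so the full pipeline reproduces the study's exact confusion
structure.
"""

from __future__ import annotations

import random
from datetime import datetime, timedelta
from typing import Optional

from pydantic import BaseModel, Field, field_validator

from .lexicon import build_dvt_lexicon, build_hemoptysis_lexicon
from .models import (
    CareEvent,
    CareEventKind,
    DDimerResult,
    Encounter,
    GoldAnnotation,
    HeartRateObservation,
    ProblemListEntry,
)
from .scoring import LIKELY_THRESHOLD_HALF, WEIGHTS_HALF_POINTS
from .textmatch import match_phrases

__all__ = ["SynthConfig", "generate_cohort", "paper_mode_cohort", "DISTRACTOR_COMPLAINTS"]

#: Filler chief complaints; verified at build time to contain no lexicon hits.
DISTRACTOR_COMPLAINTS = (
    "chest pain",
    "shortness of breath",
    "syncope",
    "dizziness",
    "cough",
    "palpitations",
    "fever",
    "generalized weakness",
)

_PE_DVT_CODE_POOL = (
    ("ICD-9", "V12.55"),
    ("ICD-10", "I26.99"),
    ("ICD-9", "453.41"),
    ("ICD-10", "I82.409"),
    ("ICD-9", "415.19"),
    ("ICD-9", "V12.51"),
)
_MALIGNANCY_CODE_POOL = (
    ("ICD-10", "C34.90"),
    ("ICD-10", "C50.911"),
    ("ICD-10", "C61"),
    ("ICD-10", "C18.9"),
    ("ICD-10", "C67.2"),
    ("ICD-10", "C90.00"),
)
_BENIGN_CODE_POOL = (
    ("ICD-10", "I10"),
    ("ICD-10", "E11.9"),
    ("ICD-10", "J45.909"),
    ("ICD-10", "K21.9"),
)

_DOC_GAP_NOTES = {
    "dvt_signs": "on exam the right calf is swollen and tender",
    "hemoptysis": "patient reports coughing up blood this morning",
    "immobilization_or_surgery": "s/p hip replacement surgery two weeks ago",
    "prior_pe_dvt": "past medical history significant for pulmonary embolism",
    "active_malignancy": "metastatic colon cancer, currently on chemotherapy",
}

_BASE_TIME = datetime(2019, 5, 15, 12, 0, 0)

_collisions_checked = False


def _assert_no_distractor_collisions() -> None:
    """Distractor complaints must never hit either lexicon (gold-label exactness)."""
    global _collisions_checked
    if _collisions_checked:
        return
    dvt = build_dvt_lexicon()
    hem = build_hemoptysis_lexicon()
    for text in DISTRACTOR_COMPLAINTS:
        for lex in (dvt, hem):
            hits = match_phrases(text, lex)
            if hits:
                raise AssertionError(
                    f"distractor complaint {text!r} collides with lexicon: {hits}"
                )
    _collisions_checked = True


class SynthConfig(BaseModel):
    """Parameters of the synthetic cohort.

    Defaults are the component prevalences and error rates observed in the
    202-encounter validation cohort this package models (e.g. DVT-sign
    prevalence 28/202, DVT documentation-gap rate 13/28, stale-malignancy
    rate 8/155).
    """

    n: int = Field(default=202, ge=1)
    seed: int = 0
    prevalence: dict[str, float] = Field(
        default_factory=lambda: {
            "dvt_signs": 28 / 202,
            "tachycardia": 87 / 202,
            "immobilization_or_surgery": 22 / 202,
            "prior_pe_dvt": 32 / 202,
            "hemoptysis": 7 / 202,
            "active_malignancy": 47 / 202,
        }
    )
    doc_gap_prob: dict[str, float] = Field(
        default_factory=lambda: {
            "dvt_signs": 13 / 28,
            "hemoptysis": 1 / 7,
            "immobilization_or_surgery": 7 / 22,
            "prior_pe_dvt": 3 / 32,
            "active_malignancy": 6 / 47,
        }
    )
    stale_entry_prob: dict[str, float] = Field(
        default_factory=lambda: {
            "prior_pe_dvt": 5 / 170,
            "active_malignancy": 8 / 155,
        }
    )
    negated_phrase_prob: float = 3 / 174
    pe_rate_by_tier: dict[str, float] = Field(
        default_factory=lambda: {"PE_likely": 20 / 128, "PE_unlikely": 6 / 74}
    )
    ddimer_order_prob: float = 28 / 76
    ddimer_abnormal_prob: float = 25 / 28

    @field_validator(
        "prevalence", "doc_gap_prob", "stale_entry_prob", "pe_rate_by_tier"
    )
    @classmethod
    def _probs_in_unit_interval(cls, v: dict[str, float]) -> dict[str, float]:
        for key, p in v.items():
            if not 0 <= p <= 1:
                raise ValueError(f"probability {key}={p} outside [0, 1]")
        return v

    @field_validator("negated_phrase_prob", "ddimer_order_prob", "ddimer_abnormal_prob")
    @classmethod
    def _scalar_in_unit_interval(cls, v: float) -> float:
        if not 0 <= v <= 1:
            raise ValueError(f"probability {v} outside [0, 1]")
        return v


def _gold_tier(gold: dict[str, bool]) -> str:
    half = WEIGHTS_HALF_POINTS["gestalt"] + sum(
        WEIGHTS_HALF_POINTS[k] for k, v in gold.items() if v
    )
    return "PE_likely" if half > LIKELY_THRESHOLD_HALF else "PE_unlikely"


def _build_encounter(
    idx: int,
    rng: random.Random,
    gold: dict[str, bool],
    docgap: set[str],
    stale: set[str],
    negated_dvt: bool,
    spurious: set[str],
    bad_pulse: bool,
    pe: bool,
    ddimer: str,  # "none" | "elevated" | "normal"
    dvt_phrases: list[str],
    hem_phrases: list[str],
) -> tuple[Encounter, GoldAnnotation]:
    index_time = _BASE_TIME + timedelta(minutes=7 * idx)
    eid = f"enc-{idx:04d}"

    complaint_parts: list[str] = []
    options: list[str] = []
    note_parts: list[str] = []
    distractor = DISTRACTOR_COMPLAINTS[rng.randrange(len(DISTRACTOR_COMPLAINTS))]
    # exercise the discrete-options path on alternating encounters
    if idx % 2 == 0:
        complaint_parts.append(distractor)
    else:
        options.append(distractor)

    def add_phrase(pool: list[str], prefix: str = "") -> None:
        phrase = pool[rng.randrange(len(pool))]
        complaint_parts.append(f"{prefix}{phrase}" if prefix else phrase)

    if gold["dvt_signs"]:
        if "dvt_signs" in docgap:
            note_parts.append(_DOC_GAP_NOTES["dvt_signs"])
        else:
            add_phrase(dvt_phrases)
    elif negated_dvt:
        add_phrase(dvt_phrases, prefix="denies ")
    elif "dvt_signs" in spurious:
        add_phrase(dvt_phrases)

    if gold["hemoptysis"]:
        if "hemoptysis" in docgap:
            note_parts.append(_DOC_GAP_NOTES["hemoptysis"])
        else:
            add_phrase(hem_phrases)
    elif "hemoptysis" in spurious:
        add_phrase(hem_phrases)

    # vitals: pre-order baseline, a qualifying pre-order value iff gold says
    # so (or an erroneous entry), and a post-order distractor spike
    hr: list[HeartRateObservation] = [
        HeartRateObservation(time=index_time - timedelta(hours=2), bpm=rng.randint(68, 96))
    ]
    if gold["tachycardia"]:
        hr.append(
            HeartRateObservation(
                time=index_time - timedelta(minutes=45), bpm=rng.randint(104, 138)
            )
        )
    elif bad_pulse:
        hr.append(
            HeartRateObservation(
                time=index_time - timedelta(minutes=30), bpm=rng.randint(120, 145)
            )
        )
    hr.append(
        HeartRateObservation(time=index_time + timedelta(hours=1), bpm=rng.randint(115, 140))
    )

    problems: list[ProblemListEntry] = []
    events: list[CareEvent] = []

    if gold["immobilization_or_surgery"]:
        if "immobilization_or_surgery" in docgap:
            note_parts.append(_DOC_GAP_NOTES["immobilization_or_surgery"])
        else:
            mech = rng.randrange(3)
            if mech == 2:
                problems.append(
                    ProblemListEntry(
                        code_system="ICD-10",
                        code="G82.50",
                        documented_time=index_time - timedelta(days=rng.randint(60, 600)),
                    )
                )
            else:
                kind = CareEventKind.icu_stay if mech == 0 else CareEventKind.operative_note_ga
                start = index_time - timedelta(days=rng.randint(2, 28))
                events.append(
                    CareEvent(
                        kind=kind,
                        time=start,
                        end_time=start + timedelta(days=2)
                        if kind is CareEventKind.icu_stay
                        else None,
                    )
                )
    elif rng.random() < 0.10:
        # out-of-window distractor stay
        start = index_time - timedelta(days=rng.randint(45, 90))
        events.append(
            CareEvent(kind=CareEventKind.icu_stay, time=start, end_time=start + timedelta(days=3))
        )

    def add_code(pool, days_back) -> None:
        system, code = pool[rng.randrange(len(pool))]
        problems.append(
            ProblemListEntry(
                code_system=system,
                code=code,
                documented_time=index_time - timedelta(days=days_back),
            )
        )

    if gold["prior_pe_dvt"] and "prior_pe_dvt" not in docgap:
        add_code(_PE_DVT_CODE_POOL, rng.randint(30, 900))
    elif gold["prior_pe_dvt"]:
        note_parts.append(_DOC_GAP_NOTES["prior_pe_dvt"])
    elif "prior_pe_dvt" in stale:
        add_code(_PE_DVT_CODE_POOL, rng.randint(30, 900))

    if gold["active_malignancy"] and "active_malignancy" not in docgap:
        add_code(_MALIGNANCY_CODE_POOL, rng.randint(10, 200))
    elif gold["active_malignancy"]:
        note_parts.append(_DOC_GAP_NOTES["active_malignancy"])
    elif "active_malignancy" in stale:
        add_code(_MALIGNANCY_CODE_POOL, rng.randint(365, 4000))

    # benign pre-index noise plus an occasional post-index PE code: the
    # latter must never be counted (it postdates the order)
    if rng.random() < 0.5:
        add_code(_BENIGN_CODE_POOL, rng.randint(30, 2000))
    if idx % 10 == 0:
        problems.append(
            ProblemListEntry(
                code_system="ICD-10",
                code="I26.99",
                documented_time=index_time + timedelta(hours=2),
            )
        )

    ddimers: list[DDimerResult] = []
    if ddimer == "elevated":
        ddimers.append(
            DDimerResult(
                order_time=index_time - timedelta(minutes=90),
                value_ng_ml=float(rng.randint(240, 5000)),
            )
        )
    elif ddimer == "normal":
        ddimers.append(
            DDimerResult(
                order_time=index_time - timedelta(minutes=90),
                value_ng_ml=float(rng.randint(60, 229)),
            )
        )

    enc = Encounter(
        encounter_id=eid,
        index_order_time=index_time,
        chief_complaint_text=" and ".join(complaint_parts),
        chief_complaint_options=options,
        heart_rate_series=hr,
        problem_list=problems,
        care_events=events,
        ddimer_results=ddimers,
        ctpa_positive=pe,
        provider_note_text=". ".join(note_parts),
    )
    annotation = GoldAnnotation(
        encounter_id=eid,
        tier=_gold_tier(gold),
        pe_diagnosed=pe,
        **gold,
    )
    return enc, annotation


_COMPONENTS = (
    "dvt_signs",
    "tachycardia",
    "immobilization_or_surgery",
    "prior_pe_dvt",
    "hemoptysis",
    "active_malignancy",
)


def generate_cohort(cfg: SynthConfig) -> tuple[list[Encounter], list[GoldAnnotation]]:
    """Sample a cohort; deterministic (byte-identical) for a given seed."""
    _assert_no_distractor_collisions()
    rng = random.Random(cfg.seed)
    dvt_phrases = sorted(build_dvt_lexicon().phrases)
    hem_phrases = sorted(build_hemoptysis_lexicon().phrases)
    encounters, annotations = [], []
    for i in range(cfg.n):
        gold = {c: rng.random() < cfg.prevalence.get(c, 0.0) for c in _COMPONENTS}
        docgap = {
            c
            for c in _COMPONENTS
            if gold[c] and rng.random() < cfg.doc_gap_prob.get(c, 0.0)
        }
        stale = {
            c
            for c in ("prior_pe_dvt", "active_malignancy")
            if not gold[c] and rng.random() < cfg.stale_entry_prob.get(c, 0.0)
        }
        negated = (not gold["dvt_signs"]) and rng.random() < cfg.negated_phrase_prob
        tier = _gold_tier(gold)
        pe = rng.random() < cfg.pe_rate_by_tier.get(tier, 0.0)
        ddimer = "none"
        if tier == "PE_unlikely" and rng.random() < cfg.ddimer_order_prob:
            ddimer = "elevated" if rng.random() < cfg.ddimer_abnormal_prob else "normal"
        enc, ann = _build_encounter(
            i,
            rng,
            gold,
            docgap=docgap,
            stale=stale,
            negated_dvt=negated,
            spurious=set(),
            bad_pulse=False,
            pe=pe,
            ddimer=ddimer,
            dvt_phrases=dvt_phrases,
            hem_phrases=hem_phrases,
        )
        encounters.append(enc)
        annotations.append(ann)
    return encounters, annotations


def _paper_strata() -> list[dict]:
    """The fixed 202-row stratum table behind :func:`paper_mode_cohort`.

    Marginals reproduce the validation study's component table (gold-positive
    counts 28/87/22/32/7/47; capture counts 15/87/15/29/6/41; false positives
    4/1/0/5/1/8), its classification confusion matrix (119, 7, 9, 67), the
    CTPA yields per automated tier (20/126 and 6/76) and the concordance
    counts among automated-unlikely encounters (25 elevated D-dimer, 3
    normal, 48 none).
    """
    D, T, I, P, H, M = (
        "dvt_signs",
        "tachycardia",
        "immobilization_or_surgery",
        "prior_pe_dvt",
        "hemoptysis",
        "active_malignancy",
    )
    rows: list[dict] = []

    def add(count: int, gold: set[str], error: Optional[str] = None) -> list[dict]:
        new = [
            {
                "gold": set(gold),
                "error": error,
                "pe": False,
                "ddimer": "none",
            }
            for _ in range(count)
        ]
        rows.extend(new)
        return new

    # -- gold PE-likely, classification false negatives (auto drops below 4)
    add(5, {D}, "docgap_dvt")  # DVT signs only in provider note
    add(2, {I}, "docgap_immob")  # recent surgery only in provider note
    add(2, {P}, "docgap_prior")  # PE history absent from problem list
    # -- gold PE-likely, component FN without tier flip (second component holds)
    add(8, {D, T}, "docgap_dvt")
    add(5, {I, T}, "docgap_immob")
    add(1, {P, T}, "docgap_prior")
    # -- gold PE-likely, component FP without tier flip
    add(1, {T}, "spurious_dvt")  # phrase present, review judged non-DVT
    add(2, {T}, "stale_prior")
    # -- gold PE-likely, error-free (auto agrees)
    s9 = add(15, {D, T, M})
    s10 = add(12, {I, T})
    s11 = add(43, {T})
    add(3, {I})
    s13 = add(29, {P})
    for row in s9:
        row["pe"] = True  # 15 of the 20 PE diagnoses among auto-likely
    for row in s11[:6]:
        row["gold"].add(H)
    for row in s11[6:11]:
        row["pe"] = True  # the other 5
    for row in s13[:26]:
        row["gold"].add(M)
    # -- gold PE-unlikely, classification false positives
    add(3, set(), "negated_dvt")  # negated phrase, matcher has no negation
    add(1, set(), "bad_pulse")  # erroneous vitals entry
    add(3, set(), "stale_prior")  # erroneous PE/DVT problem-list entries
    # -- gold PE-unlikely, component errors without tier flip
    add(8, set(), "stale_malig")  # resolved cancers still coded
    add(1, set(), "spurious_hemoptysis")
    add(1, {H}, "docgap_hemoptysis")
    add(6, {M}, "docgap_malig")
    # -- gold PE-unlikely, error-free
    s21 = add(51, set())
    for row in s21[:6]:
        row["pe"] = True  # the 6 PE diagnoses among auto-unlikely
    for row in s21[6:31]:
        row["ddimer"] = "elevated"  # 25 concordant unlikely orders
    for row in s21[31:34]:
        row["ddimer"] = "normal"  # 3 non-concordant: normal D-dimer

    assert len(rows) == 202
    return rows


_ERROR_FIELDS = {
    "docgap_dvt": {"docgap": {"dvt_signs"}},
    "docgap_immob": {"docgap": {"immobilization_or_surgery"}},
    "docgap_prior": {"docgap": {"prior_pe_dvt"}},
    "docgap_hemoptysis": {"docgap": {"hemoptysis"}},
    "docgap_malig": {"docgap": {"active_malignancy"}},
    "stale_prior": {"stale": {"prior_pe_dvt"}},
    "stale_malig": {"stale": {"active_malignancy"}},
    "negated_dvt": {"negated_dvt": True},
    "spurious_dvt": {"spurious": {"dvt_signs"}},
    "spurious_hemoptysis": {"spurious": {"hemoptysis"}},
    "bad_pulse": {"bad_pulse": True},
}


def paper_mode_cohort(seed: int = 0) -> tuple[list[Encounter], list[GoldAnnotation]]:
    """The fixed 202-encounter replication cohort.

    Error placements are deterministic (the stratum table), so the pipeline's
    confusion structure on this cohort is exact, not in expectation; the seed
    varies only surface realization (phrase choice, code choice, vital
    values, record order).
    """
    _assert_no_distractor_collisions()
    rng = random.Random(seed)
    rows = _paper_strata()
    rng.shuffle(rows)
    dvt_phrases = sorted(build_dvt_lexicon().phrases)
    hem_phrases = sorted(build_hemoptysis_lexicon().phrases)
    encounters, annotations = [], []
    for i, row in enumerate(rows):
        gold = {c: c in row["gold"] for c in _COMPONENTS}
        extra = {
            "docgap": set(),
            "stale": set(),
            "negated_dvt": False,
            "spurious": set(),
            "bad_pulse": False,
        }
        if row["error"] is not None:
            extra.update(_ERROR_FIELDS[row["error"]])
        enc, ann = _build_encounter(
            i,
            rng,
            gold,
            docgap=extra["docgap"],
            stale=extra["stale"],
            negated_dvt=extra["negated_dvt"],
            spurious=extra["spurious"],
            bad_pulse=extra["bad_pulse"],
            pe=row["pe"],
            ddimer=row["ddimer"],
            dvt_phrases=dvt_phrases,
            hem_phrases=hem_phrases,
        )
        encounters.append(enc)
        annotations.append(ann)
    return encounters, annotations
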