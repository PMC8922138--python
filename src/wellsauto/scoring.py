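"""Wells score assembly, two-tier classification, and guideline concordance.

The seven Wells components and their weights:

====================================  ======
clinical signs/symptoms of DVT        3
PE as/more likely than alternatives   3 (clinical gestalt; assumed positive,
                                         since a CTPA was in fact ordered)
heart rate > 100 bpm                  1.5
immobilization >= 3 days or surgery
  in the previous 4 weeks             1.5
previously diagnosed PE or DVT        1.5
hemoptysis                            1
active malignancy                     1
====================================  ======

Two-tier stratification: "PE likely" when the score is strictly greater than
4, else "PE unlikely". Scores are carried internally in half-point integer
units so the tier boundary is exact.

A CTPA order is guideline concordant when the encounter is PE likely, or PE
unlikely with a pre-order D-dimer above the upper limit of normal
(> 230 ng/mL by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

from .lexicon import Lexicon, build_dvt_lexicon, build_hemoptysis_lexicon
from .models import COMPONENT_NAMES, Encounter
from .structured import (
    CodeSet,
    DEFAULT_CODESETS,
    Evidence,
    extract_active_malignancy,
    extract_immobilization,
    extract_prior_pe_dvt,
    extract_tachycardia,
)
from .textmatch import Match, NegationMode, component_flag, match_phrases

__all__ = [
    "WEIGHTS_HALF_POINTS",
    "LIKELY_THRESHOLD_HALF",
    "Component",
    "WellsComponents",
    "WellsResult",
    "assemble_components",
    "compute_wells_score",
    "assess_concordance",
]

Tier = Literal["PE_likely", "PE_unlikely"]

#: Component weights in half-point units (3 pts == 6, 1.5 pts == 3, 1 pt == 2).
WEIGHTS_HALF_POINTS: dict[str, int] = {
    "dvt_signs": 6,
    "gestalt": 6,
    "tachycardia": 3,
    "immobilization_or_surgery": 3,
    "prior_pe_dvt": 3,
    "hemoptysis": 2,
    "active_malignancy": 2,
}

#: "PE likely" means score > 4 points, i.e. > 8 half-points.
LIKELY_THRESHOLD_HALF = 8


@dataclass(frozen=True)
class Component:
    name: str
    value: bool
    evidence: Optional[Evidence] = None
    matches: tuple[Match, ...] = ()

    @property
    def weight(self) -> float:
        return WEIGHTS_HALF_POINTS[self.name] / 2


@dataclass(frozen=True)
class WellsComponents:
    """The seven criterion booleans with per-component provenance."""

    components: tuple[Component, ...]

    def __post_init__(self) -> None:
        names = tuple(c.name for c in self.components)
        if names != COMPONENT_NAMES:
            raise ValueError(f"expected components {COMPONENT_NAMES}, got {names}")

    def __getitem__(self, name: str) -> Component:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def value(self, name: str) -> bool:
        return self[name].value

    def as_dict(self) -> dict[str, bool]:
        return {c.name: c.value for c in self.components}


@dataclass(frozen=True)
class WellsResult:
    score_half: int  # total in half-point units, exact

    @property
    def score(self) -> float:
        return self.score_half / 2

    @property
    def tier(self) -> Tier:
        return "PE_likely" if self.score_half > LIKELY_THRESHOLD_HALF else "PE_unlikely"


def assemble_components(
    enc: Encounter,
    dvt_lexicon: Lexicon | None = None,
    hemoptysis_lexicon: Lexicon | None = None,
    codesets: dict[str, CodeSet] | None = None,
    negation_mode: NegationMode = "off",
    gestalt_assumed: bool = True,
    include_undated: bool = True,
) -> WellsComponents:
    """Derive all seven components for one encounter.

    Text components come from phrase search over the combined chief-complaint
    fields; the four structured components from the vitals/problem-list/event
    extractors; gestalt is assumed true unless ``gestalt_assumed`` is False.
    """
    if enc.index_order_time is None:
        raise ValueError(
            f"encounter {enc.encounter_id}: index_order_time required for scoring"
        )
    if dvt_lexicon is None:
        dvt_lexicon = build_dvt_lexicon()
    if hemoptysis_lexicon is None:
        hemoptysis_lexicon = build_hemoptysis_lexicon()
    if codesets is None:
        codesets = DEFAULT_CODESETS

    text = enc.combined_chief_complaint()
    synonym_map = dvt_lexicon.synonym_map
    dvt_matches = tuple(
        match_phrases(text, dvt_lexicon, synonym_map, negation_mode=negation_mode)
    )
    hem_matches = tuple(
        match_phrases(text, hemoptysis_lexicon, synonym_map, negation_mode=negation_mode)
    )

    def text_component(name: str, matches: tuple[Match, ...]) -> Component:
        value = component_flag(matches, negation_mode)
        ev = None
        if matches:
            supporting = [m for m in matches if not m.negated] or list(matches)
            ev = Evidence("chief_complaint", f"matched {supporting[0].phrase!r}")
        return Component(name, value, evidence=ev, matches=matches)

    tach, tach_ev = extract_tachycardia(enc)
    immob, immob_ev = extract_immobilization(
        enc, codesets["quadriplegia"], include_undated
    )
    prior, prior_ev = extract_prior_pe_dvt(
        enc, codesets["pe"], codesets["dvt"], include_undated
    )
    malig, malig_ev = extract_active_malignancy(
        enc, codesets["malignancy"], include_undated
    )

    gestalt_ev = (
        Evidence("assumption", "gestalt assumed positive: CTPA was ordered")
        if gestalt_assumed
        else None
    )
    return WellsComponents(
        components=(
            text_component("dvt_signs", dvt_matches),
            Component("gestalt", gestalt_assumed, evidence=gestalt_ev),
            Component("tachycardia", tach, evidence=tach_ev),
            Component("immobilization_or_surgery", immob, evidence=immob_ev),
            Component("prior_pe_dvt", prior, evidence=prior_ev),
            text_component("hemoptysis", hem_matches),
            Component("active_malignancy", malig, evidence=malig_ev),
        )
    )


def compute_wells_score(components: WellsComponents) -> WellsResult:
    """Weighted sum of the true components, in exact half-point units."""
    half = sum(
        WEIGHTS_HALF_POINTS[c.name] for c in components.components if c.value
    )
    return WellsResult(score_half=half)


def assess_concordance(
    result: WellsResult,
    enc: Encounter,
    ddimer_uln: float = 230.0,
) -> tuple[bool, str]:
    """Guideline concordance of the CTPA order.

    PE-likely encounters are concordant outright. PE-unlikely encounters are
    concordant only if a D-dimer ordered before the CTPA order was above the
    upper limit of normal (strictly greater than ``ddimer_uln``; exactly at
    the limit counts as within normal range). When several pre-order D-dimers
    exist the latest — most proximate to the ordering decision — is used.
    """
    if ddimer_uln <= 0:
        raise ValueError("ddimer_uln must be positive")
    if result.tier == "PE_likely":
        return True, "pe_likely"
    pre = [
        d
        for d in enc.ddimer_results
        if enc.index_order_time is not None and d.order_time < enc.index_order_time
    ]
    if not pre:
        return False, "no_ddimer"
    latest = max(pre, key=lambda d: d.order_time)
    if latest.value_ng_ml > ddimer_uln:
        return True, "elevated_ddimer"
    return False, "normal_ddimer"
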