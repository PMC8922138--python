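"""Pydantic record types for one ED encounter and its chart-review truth.

An :class:`Encounter` is everything the automated process may read for one ED
visit, anchored at the CTPA order time (``index_order_time``): triage
chief-complaint text and discrete options, a timestamped heart-rate series,
the coded problem list, care events (ICU stays, operative notes with general
anesthesia), D-dimer orders/results and the CTPA outcome. The
``provider_note_text`` field exists only to model the documentation gap — the
scoring pipeline never reads it, exactly as a triage-field-only process never
reads the provider's note.
"""

from __future__ import annotations

from datetime import datetime
from enum import Enum
from typing import Optional

from pydantic import BaseModel, Field, field_validator


class CareEventKind(str, Enum):
    icu_stay = "icu_stay"
    operative_note_ga = "operative_note_ga"


class HeartRateObservation(BaseModel):
    time: datetime
    bpm: int = Field(gt=0)


class ProblemListEntry(BaseModel):
    code_system: str  # "ICD-9" or "ICD-10"
    code: str
    documented_time: Optional[datetime] = None  # None: undated entry

    @field_validator("code")
    @classmethod
    def _normalize_code(cls, v: str) -> str:
        return v.strip().upper()

    @field_validator("code_system")
    @classmethod
    def _normalize_system(cls, v: str) -> str:
        system = v.strip().upper().replace("ICD9", "ICD-9").replace("ICD10", "ICD-10")
        if system not in ("ICD-9", "ICD-10"):
            raise ValueError(f"unknown code system: {v!r}")
        return system


class CareEvent(BaseModel):
    kind: CareEventKind
    time: datetime
    end_time: Optional[datetime] = None  # ICU stays are intervals


class DDimerResult(BaseModel):
    order_time: datetime
    value_ng_ml: float = Field(ge=0)


class Encounter(BaseModel):
    """One ED visit's machine-readable record, anchored at the CTPA order."""

    encounter_id: str
    index_order_time: Optional[datetime] = None
    chief_complaint_text: str = ""
    chief_complaint_options: list[str] = Field(default_factory=list)
    heart_rate_series: list[HeartRateObservation] = Field(default_factory=list)
    problem_list: list[ProblemListEntry] = Field(default_factory=list)
    care_events: list[CareEvent] = Field(default_factory=list)
    ddimer_results: list[DDimerResult] = Field(default_factory=list)
    ctpa_positive: Optional[bool] = None
    provider_note_text: str = ""

    def combined_chief_complaint(self) -> str:
        """Free text and discrete options space-joined, as searched."""
        parts = [self.chief_complaint_text, *self.chief_complaint_options]
        return " ".join(p for p in parts if p)


COMPONENT_NAMES = (
    "dvt_signs",
    "gestalt",
    "tachycardia",
    "immobilization_or_surgery",
    "prior_pe_dvt",
    "hemoptysis",
    "active_malignancy",
)


class GoldAnnotation(BaseModel):
    """Chart-review truth for one encounter: components, tier, PE outcome."""

    encounter_id: str
    dvt_signs: bool
    gestalt: bool = True
    tachycardia: bool
    immobilization_or_surgery: bool
    prior_pe_dvt: bool
    hemoptysis: bool
    active_malignancy: bool
    tier: str  # "PE_likely" | "PE_unlikely"
    pe_diagnosed: bool = False

    def component(self, name: str) -> bool:
        if name not in COMPONENT_NAMES:
            raise KeyError(name)
        return getattr(self, name)
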