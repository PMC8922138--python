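"""Structured-data extractors for the four non-text Wells components.

Each extractor honors strict pre-index temporality: only records timestamped
*before* the CTPA order time count (a record stamped exactly at the order time
is taken to have been spawned by the order itself). Problem-list entries with
no documented time are treated as pre-index by default — problem lists often
lack onset dates — with an ``include_undated`` switch to exclude them.

ICD-9 range semantics follow category coverage: a range like 453.4-453.9
contains every child code whose truncation to the range's precision falls in
the range (453.41, 453.9, 453.99, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from decimal import Decimal, InvalidOperation
from typing import Optional

from .models import CareEventKind, Encounter, ProblemListEntry

__all__ = [
    "CodeSet",
    "Evidence",
    "code_in_set",
    "extract_tachycardia",
    "extract_immobilization",
    "extract_prior_pe_dvt",
    "extract_active_malignancy",
    "PE_CODES",
    "DVT_CODES",
    "MALIGNANCY_CODES",
    "QUADRIPLEGIA_CODES",
    "DEFAULT_CODESETS",
    "TACHYCARDIA_BPM",
    "IMMOBILIZATION_WINDOW_DAYS",
]

TACHYCARDIA_BPM = 100  # strict: a component hit needs bpm > 100
IMMOBILIZATION_WINDOW_DAYS = 30


@dataclass(frozen=True)
class CodeSet:
    """A named set of diagnosis codes with exact, range and prefix members."""

    name: str
    icd9_exact: tuple[str, ...] = ()
    icd9_ranges: tuple[tuple[str, str], ...] = ()
    icd10_exact: tuple[str, ...] = ()
    icd10_prefixes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for low, high in self.icd9_ranges:
            if Decimal(low) > Decimal(high):
                raise ValueError(f"ICD-9 range low {low} > high {high}")


def _truncate(value: Decimal, places: int) -> Decimal:
    q = Decimal(1).scaleb(-places) if places > 0 else Decimal(1)
    return value.quantize(q, rounding="ROUND_DOWN")


def _in_icd9_range(code: str, low: str, high: str) -> bool:
    try:
        value = Decimal(code)
    except InvalidOperation:
        return False  # V/E codes never range-match
    places = -Decimal(low).as_tuple().exponent
    return Decimal(low) <= _truncate(value, max(places, 0)) <= Decimal(high)


def _prefix_match(code: str, prefix: str) -> bool:
    if code == prefix:
        return True
    if not code.startswith(prefix):
        return False
    rest = code[len(prefix) :]
    return rest[0] == "." or rest[0].isdigit()


def code_in_set(code_system: str, code: str, codeset: CodeSet) -> bool:
    """Membership test with exact, ICD-10-prefix and ICD-9-range semantics."""
    code = code.strip().upper()
    system = code_system.strip().upper().replace("ICD9", "ICD-9").replace("ICD10", "ICD-10")
    if system == "ICD-9":
        if code in codeset.icd9_exact:
            return True
        return any(_in_icd9_range(code, lo, hi) for lo, hi in codeset.icd9_ranges)
    if system == "ICD-10":
        if code in codeset.icd10_exact:
            return True
        return any(_prefix_match(code, p) for p in codeset.icd10_prefixes)
    raise ValueError(f"unknown code system: {code_system!r}")


# Default code sets. PE/DVT history codes are the query lists of the automated
# process; quadriplegia and malignancy are standard groupings (malignant
# neoplasms C00-C96; personal-history Z85 codes deliberately excluded so stale
# resolved cancers enter only through C-coded problem-list entries).
PE_CODES = CodeSet(
    name="pe_history",
    icd9_exact=("415.1", "415.11", "415.12", "415.13", "415.19", "V12.55"),
    icd10_exact=("I26.99",),
)
DVT_CODES = CodeSet(
    name="dvt_history",
    icd9_exact=("V12.51",),
    icd9_ranges=(("453.4", "453.9"),),
    icd10_exact=("I82.409",),
)
MALIGNANCY_CODES = CodeSet(
    name="active_malignancy",
    icd10_prefixes=tuple(f"C{i:02d}" for i in range(97)),
)
QUADRIPLEGIA_CODES = CodeSet(
    name="quadriplegia",
    icd9_ranges=(("344.0", "344.0"),),
    icd10_prefixes=("G82.5",),
)

DEFAULT_CODESETS: dict[str, CodeSet] = {
    "pe": PE_CODES,
    "dvt": DVT_CODES,
    "malignancy": MALIGNANCY_CODES,
    "quadriplegia": QUADRIPLEGIA_CODES,
}


@dataclass(frozen=True)
class Evidence:
    """Provenance for one component decision."""

    source: str
    detail: str
    time: Optional[datetime] = None


def _pre_index_entries(
    enc: Encounter, include_undated: bool
) -> list[ProblemListEntry]:
    assert enc.index_order_time is not None
    out = []
    for entry in enc.problem_list:
        if entry.documented_time is None:
            if include_undated:
                out.append(entry)
        elif entry.documented_time < enc.index_order_time:
            out.append(entry)
    return out


def extract_tachycardia(enc: Encounter) -> tuple[bool, Evidence]:
    """Heart rate > 100 bpm, using the maximum observation before the order."""
    pre = [o for o in enc.heart_rate_series if o.time < enc.index_order_time]
    if not pre:
        return False, Evidence("heart_rate_series", "no pre-order observations")
    best = max(pre, key=lambda o: o.bpm)
    hit = best.bpm > TACHYCARDIA_BPM
    return hit, Evidence(
        "heart_rate_series", f"max pre-order HR {best.bpm} bpm", best.time
    )


def extract_immobilization(
    enc: Encounter,
    quadriplegia_set: CodeSet = QUADRIPLEGIA_CODES,
    include_undated: bool = True,
) -> tuple[bool, Evidence]:
    """ICU stay or operative note (general anesthesia) in the prior 30 days,
    or a quadriplegia diagnosis documented pre-index.

    An ICU stay counts if its interval overlaps the 30-day window at all.
    """
    window_start = enc.index_order_time - timedelta(days=IMMOBILIZATION_WINDOW_DAYS)
    for event in enc.care_events:
        end = event.end_time or event.time
        if event.time < enc.index_order_time and end >= window_start:
            return True, Evidence("care_events", f"{event.kind.value}", event.time)
    for entry in _pre_index_entries(enc, include_undated):
        if code_in_set(entry.code_system, entry.code, quadriplegia_set):
            return True, Evidence(
                "problem_list",
                f"quadriplegia code {entry.code_system} {entry.code}",
                entry.documented_time,
            )
    return False, Evidence("care_events", "no qualifying event in window")


def extract_prior_pe_dvt(
    enc: Encounter,
    pe_set: CodeSet = PE_CODES,
    dvt_set: CodeSet = DVT_CODES,
    include_undated: bool = True,
) -> tuple[bool, Evidence]:
    """Previously diagnosed PE or DVT on the pre-index problem list."""
    for entry in _pre_index_entries(enc, include_undated):
        for cs in (pe_set, dvt_set):
            if code_in_set(entry.code_system, entry.code, cs):
                return True, Evidence(
                    "problem_list",
                    f"{cs.name} code {entry.code_system} {entry.code}",
                    entry.documented_time,
                )
    return False, Evidence("problem_list", "no PE/DVT history code pre-index")


def extract_active_malignancy(
    enc: Encounter,
    malignancy_set: CodeSet = MALIGNANCY_CODES,
    include_undated: bool = True,
) -> tuple[bool, Evidence]:
    """Malignancy-group diagnosis on the pre-index problem list."""
    for entry in _pre_index_entries(enc, include_undated):
        if code_in_set(entry.code_system, entry.code, malignancy_set):
            return True, Evidence(
                "problem_list",
                f"malignancy code {entry.code_system} {entry.code}",
                entry.documented_time,
            )
    return False, Evidence("problem_list", "no malignancy code pre-index")
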