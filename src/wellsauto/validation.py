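"""Accuracy metrics against chart-review gold annotations.

Every rate is carried as an exact integer fraction (``fractions.Fraction``)
and converted to a rounded percent string only at the reporting boundary, so
printed tables are reproducible from their count fractions. Rounding is half
away from zero; classification metrics are printed to one decimal place,
component-table rates to one decimal below 10% and to the nearest integer
percent otherwise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

from .models import COMPONENT_NAMES, GoldAnnotation
from .scoring import WellsComponents, WellsResult

__all__ = [
    "Rate",
    "ConfusionCounts",
    "ComponentMetric",
    "ClassificationMetrics",
    "MetricsReport",
    "round_half_away",
    "percent_string",
    "component_metrics",
    "classification_metrics",
    "cohen_kappa",
    "ctpa_yield",
    "evaluate",
]

#: Components pooled for overall component accuracy (gestalt excluded: it is
#: assumed positive everywhere and would inflate agreement).
SCORED_COMPONENTS = tuple(n for n in COMPONENT_NAMES if n != "gestalt")


def round_half_away(x: Fraction, decimals: int = 0) -> Fraction:
    """Round to ``decimals`` places, halves away from zero, exactly."""
    scale = Fraction(10) ** decimals
    scaled = x * scale
    sign = -1 if scaled < 0 else 1
    n = abs(scaled)
    whole = n.numerator // n.denominator
    if (n - whole) >= Fraction(1, 2):
        whole += 1
    return Fraction(sign * whole, 1) / scale


def _format(x: Fraction, decimals: int) -> str:
    r = round_half_away(x, decimals)
    if decimals == 0:
        return str(int(r))
    return f"{float(r):.{decimals}f}"


@dataclass(frozen=True)
class Rate:
    """An exact count fraction with its printed-percent rendering."""

    numerator: int
    denominator: int

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)

    @property
    def value(self) -> float:
        return self.numerator / self.denominator

    def percent(self, decimals: Optional[int] = None) -> str:
        return percent_string(self.fraction, decimals)

    def percent_value(self, decimals: int = 1) -> float:
        return float(round_half_away(self.fraction * 100, decimals))

    def __str__(self) -> str:
        return f"{self.numerator}/{self.denominator} ({self.percent()}%)"


def percent_string(rate: Fraction, decimals: Optional[int] = None) -> str:
    """Render a rate in [0, 1] as a percent string.

    With ``decimals=None`` the precision is adaptive: one decimal place below
    10%, nearest integer at or above; exact 0 and 1 print as "0" and "100".
    """
    pct = rate * 100
    if decimals is None:
        if pct == 0:
            return "0"
        if pct == 100:
            return "100"
        decimals = 1 if pct < 10 else 0
    return _format(pct, decimals)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts for the PE-likely classification."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(
        cls, gold: Sequence[bool], auto: Sequence[bool]
    ) -> "ConfusionCounts":
        if len(gold) != len(auto):
            raise ValueError("label lists must have equal length")
        tp = sum(1 for g, a in zip(gold, auto) if g and a)
        fp = sum(1 for g, a in zip(gold, auto) if not g and a)
        fn = sum(1 for g, a in zip(gold, auto) if g and not a)
        tn = sum(1 for g, a in zip(gold, auto) if not g and not a)
        return cls(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class ComponentMetric:
    name: str
    n: int
    present: int  # gold-positive count
    captured: int  # true positives
    erroneous: int  # false positives

    @property
    def absent(self) -> int:
        return self.n - self.present

    @property
    def prevalence(self) -> Rate:
        return Rate(self.present, self.n)

    @property
    def sensitivity(self) -> Optional[Rate]:
        return Rate(self.captured, self.present) if self.present else None

    @property
    def false_positive_rate(self) -> Optional[Rate]:
        return Rate(self.erroneous, self.absent) if self.absent else None

    @property
    def false_negatives(self) -> int:
        return self.present - self.captured


def component_metrics(
    gold: Sequence[GoldAnnotation],
    auto: Mapping[str, WellsComponents],
) -> tuple[dict[str, ComponentMetric], Rate]:
    """Per-component capture/error rates plus pooled accuracy.

    ``auto`` maps encounter_id to the automated components; every gold
    encounter must be present. Pooled accuracy covers the six non-gestalt
    components: (total cells - FN - FP) / total cells.
    """
    missing = [g.encounter_id for g in gold if g.encounter_id not in auto]
    if missing:
        raise ValueError(f"no automated components for encounters: {missing[:5]}")
    n = len(gold)
    metrics: dict[str, ComponentMetric] = {}
    total_fn = total_fp = 0
    for name in COMPONENT_NAMES:
        present = captured = erroneous = 0
        for g in gold:
            gv = g.component(name)
            av = auto[g.encounter_id].value(name)
            if gv:
                present += 1
                captured += av
            elif av:
                erroneous += 1
        metrics[name] = ComponentMetric(
            name=name, n=n, present=present, captured=captured, erroneous=erroneous
        )
        if name in SCORED_COMPONENTS:
            total_fn += present - captured
            total_fp += erroneous
    cells = len(SCORED_COMPONENTS) * n
    pooled = Rate(cells - total_fn - total_fp, cells) if cells else Rate(0, 1)
    return metrics, pooled


@dataclass(frozen=True)
class ClassificationMetrics:
    accuracy: Rate
    sensitivity: Optional[Rate]
    specificity: Optional[Rate]
    ppv: Optional[Rate]
    npv: Optional[Rate]

    def as_percent_dict(self) -> dict[str, Optional[float]]:
        return {
            k: (r.percent_value(1) if r is not None else None)
            for k, r in (
                ("accuracy", self.accuracy),
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("ppv", self.ppv),
                ("npv", self.npv),
            )
        }


def classification_metrics(cc: ConfusionCounts) -> ClassificationMetrics:
    """Standard 2x2 metrics; rates with a zero denominator are absent (None)."""
    if cc.total == 0:
        raise ValueError("empty confusion matrix")

    def rate(num: int, den: int) -> Optional[Rate]:
        return Rate(num, den) if den else None

    return ClassificationMetrics(
        accuracy=Rate(cc.tp + cc.tn, cc.total),
        sensitivity=rate(cc.tp, cc.tp + cc.fn),
        specificity=rate(cc.tn, cc.tn + cc.fp),
        ppv=rate(cc.tp, cc.tp + cc.fp),
        npv=rate(cc.tn, cc.tn + cc.fn),
    )


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's chance-corrected agreement between two raters.

    kappa = (p_o - p_e) / (1 - p_e), with p_e from the raters' marginal label
    distributions. When p_e == 1 (both raters constant and identical) the
    agreement is perfect and kappa is 1.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences must have equal length")
    if not labels_a:
        raise ValueError("label sequences must be non-empty")
    n = len(labels_a)
    p_o = Fraction(sum(1 for a, b in zip(labels_a, labels_b) if a == b), n)
    ca, cb = Counter(labels_a), Counter(labels_b)
    p_e = sum(
        Fraction(ca[k], n) * Fraction(cb[k], n) for k in set(ca) | set(cb)
    )
    if p_e == 1:
        return 1.0
    return float((p_o - p_e) / (1 - p_e))


def ctpa_yield(
    results: Mapping[str, WellsResult],
    gold: Sequence[GoldAnnotation],
) -> dict[str, Optional[Rate]]:
    """PE diagnoses per CTPA exam, stratified by automated tier.

    Returns yields for "PE_likely", "PE_unlikely" and "overall"; a stratum
    with no encounters yields None.
    """
    strata: dict[str, list[GoldAnnotation]] = {"PE_likely": [], "PE_unlikely": []}
    for g in gold:
        if g.encounter_id not in results:
            raise ValueError(f"no automated result for encounter {g.encounter_id}")
        strata[results[g.encounter_id].tier].append(g)
    out: dict[str, Optional[Rate]] = {}
    for tier, members in strata.items():
        out[tier] = (
            Rate(sum(g.pe_diagnosed for g in members), len(members))
            if members
            else None
        )
    out["overall"] = Rate(sum(g.pe_diagnosed for g in gold), len(gold)) if gold else None
    return out


@dataclass(frozen=True)
class Discrepancy:
    """One encounter where the automated tier disagrees with chart review."""

    encounter_id: str
    gold_tier: str
    auto_tier: str
    component_diffs: dict[str, tuple[bool, bool]]  # name -> (gold, auto)


@dataclass
class MetricsReport:
    n: int
    per_component: dict[str, ComponentMetric]
    pooled_component_accuracy: Rate
    confusion: ConfusionCounts
    classification: ClassificationMetrics
    yields: dict[str, Optional[Rate]]
    concordance: Optional[Rate]
    discrepancies: list[Discrepancy] = field(default_factory=list)
    kappa: Optional[float] = None

    def to_dict(self) -> dict:
        def rate_dict(r: Optional[Rate], decimals=None) -> Optional[dict]:
            if r is None:
                return None
            return {
                "numerator": r.numerator,
                "denominator": r.denominator,
                "percent": r.percent(decimals),
            }

        return {
            "n": self.n,
            "components": {
                name: {
                    "present": m.present,
                    "captured": m.captured,
                    "erroneous": m.erroneous,
                    "prevalence": rate_dict(m.prevalence),
                    "sensitivity": rate_dict(m.sensitivity),
                    "false_positive_rate": rate_dict(m.false_positive_rate),
                }
                for name, m in self.per_component.items()
            },
            "pooled_component_accuracy": rate_dict(self.pooled_component_accuracy),
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
                "tn": self.confusion.tn,
            },
            "classification": {
                k: (rate_dict(r, 1) if r else None)
                for k, r in (
                    ("accuracy", self.classification.accuracy),
                    ("sensitivity", self.classification.sensitivity),
                    ("specificity", self.classification.specificity),
                    ("ppv", self.classification.ppv),
                    ("npv", self.classification.npv),
                )
            },
            "ctpa_yield": {k: rate_dict(r, 1) for k, r in self.yields.items()},
            "concordance": rate_dict(self.concordance, 1),
            "kappa": self.kappa,
            "discrepancies": [
                {
                    "encounter_id": d.encounter_id,
                    "gold_tier": d.gold_tier,
                    "auto_tier": d.auto_tier,
                    "component_diffs": {
                        k: {"gold": g, "auto": a}
                        for k, (g, a) in d.component_diffs.items()
                    },
                }
                for d in self.discrepancies
            ],
        }

    def to_text(self) -> str:
        """Human-readable tables mirroring a component/confusion/metrics report."""
        lines = [f"Cohort: {self.n} encounters", "", "Component capture:"]
        header = f"  {'component':<28}{'present':>12}{'captured':>12}{'erroneous':>12}"
        lines.append(header)
        for name, m in self.per_component.items():
            sens = f"{m.captured}/{m.present}" if m.present else "-"
            fpr = f"{m.erroneous}/{m.absent}" if m.absent else "-"
            lines.append(
                f"  {name:<28}{f'{m.present}/{m.n}':>12}{sens:>12}{fpr:>12}"
            )
        pooled = self.pooled_component_accuracy
        lines += [
            f"  pooled accuracy (excl. gestalt): {pooled} ",
            "",
            "Classification confusion (rows: automated, cols: chart review):",
            f"  likely:   TP={self.confusion.tp:<5} FP={self.confusion.fp}",
            f"  unlikely: FN={self.confusion.fn:<5} TN={self.confusion.tn}",
            "",
            "Classification metrics:",
        ]
        for k, v in self.classification.as_percent_dict().items():
            lines.append(f"  {k:<12} {v if v is not None else 'absent'}%")
        lines.append("")
        lines.append("CTPA yield by automated tier:")
        for k, r in self.yields.items():
            lines.append(f"  {k:<12} {r if r is not None else 'absent'}")
        if self.concordance is not None:
            lines.append(f"Guideline concordance: {self.concordance}")
        if self.kappa is not None:
            lines.append(f"Cohen kappa (auto vs chart tier): {self.kappa:.2f}")
        lines.append(f"Discrepant classifications: {len(self.discrepancies)}")
        return "\n".join(lines)


def evaluate(
    gold: Sequence[GoldAnnotation],
    auto_components: Mapping[str, WellsComponents],
    results: Mapping[str, WellsResult],
    concordant: Optional[Mapping[str, bool]] = None,
) -> MetricsReport:
    """Full validation report for one cohort."""
    per_component, pooled = component_metrics(gold, auto_components)
    gold_labels = [g.tier == "PE_likely" for g in gold]
    auto_labels = [results[g.encounter_id].tier == "PE_likely" for g in gold]
    confusion = ConfusionCounts.from_labels(gold_labels, auto_labels)
    discrepancies = []
    for g in gold:
        auto_tier = results[g.encounter_id].tier
        if auto_tier != g.tier:
            comps = auto_components[g.encounter_id]
            diffs = {
                name: (g.component(name), comps.value(name))
                for name in COMPONENT_NAMES
                if g.component(name) != comps.value(name)
            }
            discrepancies.append(
                Discrepancy(
                    encounter_id=g.encounter_id,
                    gold_tier=g.tier,
                    auto_tier=auto_tier,
                    component_diffs=diffs,
                )
            )
    concordance = None
    if concordant is not None:
        flags = [concordant[g.encounter_id] for g in gold]
        concordance = Rate(sum(flags), len(flags)) if flags else None
    kappa = cohen_kappa(gold_labels, auto_labels) if gold else None
    return MetricsReport(
        n=len(gold),
        per_component=per_component,
        pooled_component_accuracy=pooled,
        confusion=confusion,
        classification=classification_metrics(confusion),
        yields=ctpa_yield(results, gold),
        concordance=concordance,
        discrepancies=discrepancies,
        kappa=kappa,
    )
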