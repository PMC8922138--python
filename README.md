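# wellsauto

Automated two-tier **Wells score** calculation for pulmonary-embolism (PE)
risk assessment from electronic-health-record (EHR) data, with a full
validation harness and a synthetic-encounter generator.

## The problem

Computed-tomography pulmonary angiography (CTPA) is the gold-standard test
for PE, but carries contrast and radiation risk. The Wells criteria estimate
pretest probability so that low-risk patients can be ruled out with a
D-dimer instead of imaging. Manual score entry is a major barrier to clinical
decision support, so `wellsauto` computes the score automatically from data
already in the record — including the two components that live in free text —
using only information recorded **before** the CTPA order.

The seven components and weights:

| component | points | source |
|---|---|---|
| clinical signs/symptoms of DVT | 3 | phrase search over triage chief-complaint fields |
| PE as/more likely than alternatives (gestalt) | 3 | assumed positive (a CTPA was ordered) |
| heart rate > 100 bpm | 1.5 | max pre-order vital-sign value |
| immobilization ≥ 3 days / surgery ≤ 4 weeks | 1.5 | ICU stays, operative notes (GA), quadriplegia codes |
| previously diagnosed PE or DVT | 1.5 | problem-list ICD-9/ICD-10 code sets |
| hemoptysis | 1 | fixed 7-phrase lexicon |
| active malignancy | 1 | problem-list malignancy code group (C00–C96) |

Total score > 4 ⇒ **PE likely**; otherwise **PE unlikely**. A CTPA order is
*guideline concordant* if the patient is PE likely, or PE unlikely with a
pre-order D-dimer > 230 ng/mL.

The DVT-sign detector is a combinatorial keyword lexicon: every pairing of a
descriptor ("pain in", "swelling", "edema", …) with a lower-extremity
anatomic term ("leg", "thigh", "calf", "LE", …) and a laterality slot
(left/right/bilateral/none) — 8 × 6 × 4 = **192 phrases**, matched on token
boundaries after normalization and synonym folding ("b/l" → "bilateral",
"le" → "lower extremity"). Negation scoping is off by default (mirroring the
validated process) and available as an explicit `window` mode.

## Worked example

```python
from datetime import datetime, timedelta
from wellsauto import (Encounter, assemble_components, compute_wells_score,
                       assess_concordance)
from wellsauto.models import HeartRateObservation, ProblemListEntry

t0 = datetime(2019, 5, 20, 12, 0)   # CTPA order time
enc = Encounter(
    encounter_id="demo",
    index_order_time=t0,
    chief_complaint_text="shortness of breath and left leg swelling",
    heart_rate_series=[HeartRateObservation(time=t0 - timedelta(hours=1), bpm=112)],
    problem_list=[ProblemListEntry(code_system="ICD-10", code="C34.90",
                                   documented_time=t0 - timedelta(days=40))],
)
comps = assemble_components(enc)
result = compute_wells_score(comps)
print({n: v for n, v in comps.as_dict().items() if v})
print(result.score, result.tier)
print(assess_concordance(result, enc))
```

prints

```
{'dvt_signs': True, 'gestalt': True, 'tachycardia': True, 'active_malignancy': True}
8.5 PE_likely
(True, 'pe_likely')
```

— the triage phrase "left leg swelling" (3), the assumed gestalt (3), the
pre-order heart rate of 112 (1.5) and the lung-cancer problem-list code (1)
sum to 8.5 points, which is above the 4-point cutoff, so the encounter is
PE likely and the CTPA order is concordant without any D-dimer.

From the shell the same pipeline runs end to end on a synthetic cohort:

```bash
wellsauto synth -o cohort --paper-mode --seed 1
wellsauto validate -e cohort/encounters.jsonl -g cohort/gold.csv -o report
```

which writes per-encounter scores (`scores.csv`), evidence provenance
(`evidence.jsonl`) and a metrics report (`metrics.json`, `metrics.txt`) with
per-component sensitivity / false-positive rates, the classification
confusion matrix, CTPA yield per tier and the concordance rate.

## Synthetic cohorts

No real encounter data ship with the package. `wellsauto.synth` generates
cohorts with chart-review-style gold annotations and configurable error
modes — findings documented only in provider notes (false negatives for a
triage-field pipeline), stale or erroneous problem-list entries (false
positives), negated triage phrases and erroneous vitals entries.
`paper_mode_cohort` is a fixed 202-encounter cohort whose error placements
are deterministic, giving an exactly reproducible end-to-end confusion
structure; `generate_cohort` samples cohorts of any size for property and
parameter-recovery testing.

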