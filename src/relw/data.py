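"""Bundled example datasets: a published COVID-19 cohort.

Two counting datasets from a retrospective cohort of 112 COVID-19 patients
accompany the package, one over patient symptoms and one over chest-CT
findings, together with the weight tables published alongside them.  They
serve as worked examples throughout the documentation and as the reference
inputs of ``scripts/acceptance.py``.

Notes
-----
* The symptom cohort distinguishes three fever grades (low 37.3–38.0 °C,
  moderate 38.1–39.0 °C, high > 39.0 °C) as separate binary variables;
  grade labels are harmonised to the "Low/Moderate/High-grade fever" form.
* ``covid_symptom_weights`` is the published percent table for the symptom
  cohort; it equals (to printed 1-dp precision) what
  :func:`relw.weights.relative_weights` computes from the counts, and sums
  to exactly 100.0%.
* ``covid_ct_weights`` is the published percent table for the CT findings.
  Its 19 percents sum to 103.2%, not 100%; it is deliberately loaded
  verbatim (no renormalisation), which is why the sum-of-present and
  complement scoring modes disagree on it.  The published derivation of
  these percents from the per-variable count ranges is not stated and is
  not reconstructed here.
* ``covid_ct_weight_bounds`` carries the per-variable minimum/maximum
  prevalence percents reported for the CT findings (reader-dependent count
  ranges), as an example of the weight-bounds dataset dialect.
"""

from __future__ import annotations

from .dataset_io import CountingDataset, VariableRecord
from .weights import WeightTable, load_supplied_weights

__all__ = [
    "covid_symptom_counts",
    "covid_symptom_weights",
    "covid_ct_weights",
    "covid_ct_weight_bounds",
]

#: cohort size of the symptom dataset
COVID_TOTAL_PATIENTS = 112

_FEVER = "fever grade"

# (name, group, patient count) — counts sum to 279
_SYMPTOM_COUNTS = (
    ("Low-grade fever (37.3–38.0)", _FEVER, 46),
    ("Moderate-grade fever (38.1–39.0)", _FEVER, 31),
    ("High-grade fever (>39.0)", _FEVER, 7),
    ("Dizziness", None, 2),
    ("Palpitation", None, 2),
    ("Nausea and vomiting", None, 4),
    ("Throat pain", None, 4),
    ("Headache", None, 8),
    ("Abdominal pain and diarrhea", None, 14),
    ("Expectoration", None, 15),
    ("Dyspnea", None, 18),
    ("Myalgia", None, 18),
    ("Chest distress", None, 24),
    ("Fatigue", None, 38),
    ("Dry Cough", None, 48),
)

# (name, published relative weight in %) — sums to 100.0
_SYMPTOM_WEIGHTS_PCT = (
    ("Low-grade fever (37.3–38.0)", _FEVER, 16.5),
    ("Moderate-grade fever (38.1–39.0)", _FEVER, 11.1),
    ("High-grade fever (>39.0)", _FEVER, 2.5),
    ("Dizziness", None, 0.7),
    ("Palpitation", None, 0.7),
    ("Nausea and vomiting", None, 1.4),
    ("Throat pain", None, 1.4),
    ("Headache", None, 2.9),
    ("Abdominal pain and diarrhea", None, 5.0),
    ("Expectoration", None, 5.4),
    ("Dyspnea", None, 6.5),
    ("Myalgia", None, 6.5),
    ("Chest distress", None, 8.6),
    ("Fatigue", None, 13.6),
    ("Dry Cough", None, 17.2),
)

_LESIONS = "distribution of pulmonary lesions"
_INVOLVEMENT = "involvement of the lung"

# (name, group, published relative weight in %) — sums to 103.2
_CT_WEIGHTS_PCT = (
    ("No lesion", _LESIONS, 3.2),
    ("Peripheral", _LESIONS, 13.1),
    ("Central", _LESIONS, 0.3),
    ("Diffuse", _LESIONS, 5.2),
    ("No involvement", _INVOLVEMENT, 3.2),
    ("Single lobe", _INVOLVEMENT, 5.0),
    ("Unilateral multilobe", _INVOLVEMENT, 0.4),
    ("Bilateral multilobe", _INVOLVEMENT, 13.5),
    ("GGO", None, 18.5),
    ("Crazy-paving pattern", None, 10.0),
    ("Consolidation", None, 9.4),
    ("Linear opacities", None, 7.3),
    ("Air bronchogram", None, 6.3),
    ("Cavitation", None, 0.0),
    ("Bronchiectasis", None, 4.4),
    ("Pleural effusion", None, 2.8),
    ("Pericardial effusion", None, 0.3),
    ("Lymphadenopathy", None, 0.0),
    ("Pneumothorax", None, 0.3),
)

# (name, group, min prevalence %, max prevalence %) across readers
_CT_WEIGHT_BOUNDS_PCT = (
    ("No lesion", _LESIONS, 1.7, 21.2),
    ("Peripheral", _LESIONS, 52.4, 63.8),
    ("Central", _LESIONS, 0.0, 2.1),
    ("Diffuse", _LESIONS, 12.7, 44.1),
    ("No involvement", _INVOLVEMENT, 1.7, 21.2),
    ("Single lobe", _INVOLVEMENT, 1.5, 34.0),
    ("Unilateral multilobe", _INVOLVEMENT, 0.0, 2.9),
    ("Bilateral multilobe", _INVOLVEMENT, 42.5, 95.6),
    ("GGO", None, 76.5, 98.1),
    ("Crazy-paving pattern", None, 36.1, 62.7),
    ("Consolidation", None, 25.5, 75.0),
    ("Linear opacities", None, 6.3, 83.1),
    ("Air bronchogram", None, 17.0, 50.0),
    ("Cavitation", None, 0.0, 0.0),
    ("Bronchiectasis", None, 6.3, 45.2),
    ("Pleural effusion", None, 4.2, 27.9),
    ("Pericardial effusion", None, 0.0, 4.4),
    ("Lymphadenopathy", None, 0.0, 0.0),
    ("Pneumothorax", None, 0.0, 3.8),
)


def covid_symptom_counts() -> CountingDataset:
    """Symptom counting dataset: 15 variables, counts summing to 279,
    cohort of 112 patients."""
    return CountingDataset(
        variables=tuple(
            VariableRecord(name=n, group=g, count=c) for n, g, c in _SYMPTOM_COUNTS
        ),
        total_patients=COVID_TOTAL_PATIENTS,
        source_kind="symptoms",
        name="covid-symptoms",
    )


def covid_symptom_weights() -> WeightTable:
    """Published relative-weight table for the symptom cohort (Σ = 100.0%)."""
    dataset = CountingDataset(
        variables=tuple(
            VariableRecord(name=n, group=g, weight_pct=p)
            for n, g, p in _SYMPTOM_WEIGHTS_PCT
        ),
        total_patients=COVID_TOTAL_PATIENTS,
        source_kind="symptoms",
        name="covid-symptom-weights",
    )
    return load_supplied_weights(dataset)


def covid_ct_weights() -> WeightTable:
    """Published relative-weight table for the 19 chest-CT findings
    (Σ = 103.2%, loaded verbatim)."""
    dataset = CountingDataset(
        variables=tuple(
            VariableRecord(name=n, group=g, weight_pct=p)
            for n, g, p in _CT_WEIGHTS_PCT
        ),
        source_kind="image_features",
        name="covid-ct-weights",
    )
    return load_supplied_weights(dataset)


def covid_ct_weight_bounds() -> CountingDataset:
    """Chest-CT findings with reader-dependent min/max prevalence bounds."""
    return CountingDataset(
        variables=tuple(
            VariableRecord(name=n, group=g, weight_min_pct=lo, weight_max_pct=hi)
            for n, g, lo, hi in _CT_WEIGHT_BOUNDS_PCT
        ),
        source_kind="image_features",
        name="covid-ct-weight-bounds",
    )
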