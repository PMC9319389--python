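"""Scoring: worked examples, complementarity, modes, brute-force oracle."""

import itertools
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from relw.dataset_io import (
    CountingDataset,
    DatasetValidationError,
    PresenceProfile,
    VariableRecord,
    read_profile,
)
from relw.scoring import explain, score, score_addends
from relw.weights import relative_weights, render_percent

# chest-CT findings observed in the published worked example
CT_EXAMPLE_PRESENT = [
    "GGO",
    "Bronchiectasis",
    "Pericardial effusion",
    "Consolidation",
    "Bilateral multilobe",
    "Peripheral",
]

# the printed addend list of the published symptom worked example; it lists
# five percent terms for four named symptoms (the 17.2% term appears twice)
SYMPTOM_EXAMPLE_ADDENDS = [
    "Dry Cough",
    "Low-grade fever (37.3–38.0)",
    "Headache",
    "Dry Cough",
    "Myalgia",
]


def _normalized_table(counts):
    ds = CountingDataset(
        variables=tuple(
            VariableRecord(name=f"v{i}", count=c) for i, c in enumerate(counts)
        )
    )
    return relative_weights(ds)


class TestWorkedExamples:
    def test_ct_example_scores(self, ct_weights):
        profile = read_profile(CT_EXAMPLE_PRESENT, ct_weights.dataset)
        result = score(profile, ct_weights)
        assert result.positive_lr == Fraction(592, 1000)
        assert result.positive_percent() == "59.2%"
        assert result.negative_percent() == "40.8%"
        assert not result.warnings

    def test_ct_example_ranking(self, ct_weights):
        profile = read_profile(CT_EXAMPLE_PRESENT, ct_weights.dataset)
        present = score(profile, ct_weights).present_contributions
        assert present[0].name == "GGO"
        assert render_percent(present[0].weight) == "18.5%"
        assert present[-1].name == "Pericardial effusion"
        assert render_percent(present[-1].weight) == "0.3%"

    def test_symptom_example_addend_sum(self, symptom_weights):
        total = score_addends(symptom_weights, SYMPTOM_EXAMPLE_ADDENDS)
        assert render_percent(total) == "60.3%"
        assert render_percent(1 - total) == "39.7%"

    def test_symptom_example_as_plain_profile(self, symptom_weights):
        # scoring the four distinct symptoms once each (no repeated addend)
        profile = read_profile(sorted(set(SYMPTOM_EXAMPLE_ADDENDS)), symptom_weights.dataset)
        assert score(profile, symptom_weights).positive_percent() == "43.1%"

    def test_all_absent(self, symptom_weights):
        profile = read_profile([], symptom_weights.dataset)
        result = score(profile, symptom_weights)
        assert result.positive_lr == 0
        assert result.negative_lr == 1

    def test_all_present_normalized_table(self, symptom_weights):
        profile = read_profile(
            list(symptom_weights.dataset.names), symptom_weights.dataset
        )
        assert score(profile, symptom_weights).positive_lr == 1

    def test_out_of_range_warning_on_non_normalized_table(self, ct_weights):
        profile = read_profile(list(ct_weights.dataset.names), ct_weights.dataset)
        result = score(profile, ct_weights)
        assert result.positive_lr == Fraction(1032, 1000)  # not clamped
        assert result.warnings

    def test_dataset_mismatch_rejected(self, symptom_weights, ct_weights):
        profile = read_profile([], ct_weights.dataset)
        with pytest.raises(DatasetValidationError, match="different datasets"):
            score(profile, symptom_weights)

    def test_unknown_addend_rejected(self, symptom_weights):
        with pytest.raises(DatasetValidationError, match="unknown"):
            score_addends(symptom_weights, ["Dry Cough", "Sneezing"])


class TestScoreProperties:
    @given(
        counts=st.lists(st.integers(min_value=0, max_value=100), min_size=1, max_size=12),
        bits=st.integers(min_value=0),
    )
    def test_complementarity_exact(self, counts, bits):
        if sum(counts) == 0:
            counts[0] = 1
        table = _normalized_table(counts)
        names = table.dataset.names
        presence = {n: bool((bits >> i) & 1) for i, n in enumerate(names)}
        result = score(PresenceProfile(table.dataset, presence), table)
        assert result.positive_lr + result.negative_lr == 1

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=100), min_size=2, max_size=12),
        bits=st.integers(min_value=0),
        extra=st.integers(min_value=0),
    )
    def test_monotone_in_present_set(self, counts, bits, extra):
        if sum(counts) == 0:
            counts[0] = 1
        table = _normalized_table(counts)
        names = table.dataset.names
        k = len(names)
        extra_var = names[extra % k]
        presence = {n: bool((bits >> i) & 1) for i, n in enumerate(names)}
        presence[extra_var] = False
        base = score(PresenceProfile(table.dataset, presence), table)
        presence[extra_var] = True
        bigger = score(PresenceProfile(table.dataset, presence), table)
        assert bigger.positive_lr >= base.positive_lr

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=100), min_size=1, max_size=12),
        bits=st.integers(min_value=0),
    )
    def test_modes_agree_on_normalized_tables(self, counts, bits):
        if sum(counts) == 0:
            counts[0] = 1
        table = _normalized_table(counts)
        names = table.dataset.names
        profile = PresenceProfile(
            table.dataset, {n: bool((bits >> i) & 1) for i, n in enumerate(names)}
        )
        assert (
            score(profile, table, mode="sum_present").positive_lr
            == score(profile, table, mode="complement").positive_lr
        )

    def test_permutation_invariance(self, symptom_counts):
        table = relative_weights(symptom_counts)
        names = symptom_counts.names
        reversed_ds = CountingDataset(
            variables=tuple(reversed(symptom_counts.variables)),
            total_patients=symptom_counts.total_patients,
        )
        reversed_table = relative_weights(reversed_ds)
        present = ["Dry Cough", "Headache", "Fatigue"]
        a = score(read_profile(present, symptom_counts), table)
        b = score(read_profile(present, reversed_ds), reversed_table)
        assert a.positive_lr == b.positive_lr

    @pytest.mark.parametrize("counts", [[3, 1, 4, 1, 5], [10, 0, 2, 7, 6, 9, 1]])
    def test_matches_brute_force_oracle_all_profiles(self, counts):
        """Exhaustive cross-check: every profile of a small dataset scores
        identically to an independent subset-sum enumeration."""
        table = _normalized_table(counts)
        names = table.dataset.names
        total = sum(counts)
        for mask in itertools.product([False, True], repeat=len(names)):
            presence = dict(zip(names, mask))
            expected = Fraction(
                sum(c for c, m in zip(counts, mask) if m), total
            )
            result = score(PresenceProfile(table.dataset, presence), table)
            assert result.positive_lr == expected


class TestExplain:
    def test_cumulative_column_ends_at_positive_lr(self, symptom_weights):
        profile = read_profile(
            ["Dry Cough", "Headache", "Fatigue"], symptom_weights.dataset
        )
        result = score(profile, symptom_weights)
        report = explain(result)
        lines = [l for l in report.splitlines() if " present " in l]
        assert lines[-1].split()[-1] == result.positive_percent()

    def test_all_absent_report(self, symptom_weights):
        result = score(read_profile([], symptom_weights.dataset), symptom_weights)
        report = explain(result)
        assert "(no variables present)" in report
        assert "-LR = 100.0%" in report

    def test_top_contributor_listed_first(self, ct_weights):
        profile = read_profile(CT_EXAMPLE_PRESENT, ct_weights.dataset)
        report = explain(score(profile, ct_weights))
        present_lines = [l for l in report.splitlines() if " present " in l]
        assert present_lines[0].startswith("GGO")
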