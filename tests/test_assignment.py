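import math

import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from skinktrace.alignment import InputError
from skinktrace.assignment import (
    AssignmentThresholds,
    HaplotypeSourceClassifier,
    LocalityError,
    RegionEquivalence,
    batch_classify,
    classify_detection,
    nearest_reference,
    score_prediction,
)


def _mutate(seq, changes):
    chars = list(seq)
    for pos, base in changes.items():
        chars[pos] = base
    return "".join(chars)


@pytest.fixture
def fitted(toy_panel):
    return HaplotypeSourceClassifier().fit(toy_panel)


class TestNearestReference:
    def test_identical_query_ranks_first_at_zero(self, fitted, toy_panel):
        ranked = nearest_reference(toy_panel.native_haplotypes[2].sequence, toy_panel)
        assert ranked[0][0] == "B1" and ranked[0][3] == 0.0

    def test_ties_at_minimum_all_reported(self, toy_panel, fitted):
        # query exactly between B1 and B2 (differs from each at one site)
        b1 = toy_panel.native_haplotypes[2].sequence
        b2 = toy_panel.native_haplotypes[3].sequence
        diff_site = next(i for i in range(len(b1)) if b1[i] != b2[i])
        other = next(b for b in "ACGT" if b not in (b1[diff_site], b2[diff_site]))
        query = _mutate(b1, {diff_site: other})
        ranked = fitted.nearest_reference(query)
        top = ranked[0][3]
        tied = [r[0] for r in ranked if math.isclose(r[3], top, abs_tol=1e-12)]
        assert set(tied) == {"B1", "B2"}

    def test_mutated_query_still_finds_its_source(self, fitted, toy_panel):
        src = toy_panel.native_haplotypes[3]
        query = _mutate(src.sequence, {2: "A" if src.sequence[2] != "A" else "C"})
        ranked = fitted.nearest_reference(query)
        assert ranked[0][0] == src.label and ranked[0][1] == src.locality


class TestClassificationCascade:
    def test_established_haplotype_inside_range_is_local_resident(self, fitted, toy_panel):
        nz = toy_panel.established_haplotypes[0][1]
        res = fitted.classify(nz, "Auckland")
        assert res.category == "local-resident" and res.tier == "identical"
        assert res.caveat == "local-or-same-source"

    def test_established_haplotype_outside_range_is_jump_dispersal(self, fitted, toy_panel):
        nz = toy_panel.established_haplotypes[0][1]
        res = fitted.classify(nz, "Christchurch")
        assert res.category == "within-country-movement"

    def test_closely_related_haplotype_goes_to_source_region_tier(self, fitted, toy_panel):
        nz = toy_panel.established_haplotypes[0][1]
        near = _mutate(nz, {7: "A" if nz[7] != "A" else "G"})  # 1/60 ~ 1.7% > 0.3%
        clf = HaplotypeSourceClassifier(close_tol=0.02).fit(toy_panel)
        res = clf.classify(near, "Christchurch")
        assert res.category == "within-country-movement"
        assert res.tier == "close"
        assert res.inferred_source == "Tenterfield"

    def test_divergent_haplotype_is_new_arrival_with_source(self, fitted, toy_panel):
        b2 = toy_panel.native_haplotypes[3].sequence
        res = fitted.classify(b2, "Auckland")
        assert res.category == "new-arrival"
        assert res.inferred_source == "Brisbane"

    def test_unknown_locality_raises_when_list_supplied(self, toy_panel):
        panel = toy_panel.__class__(
            native_haplotypes=toy_panel.native_haplotypes,
            established_haplotypes=toy_panel.established_haplotypes,
            established_localities=toy_panel.established_localities,
            source_region_label=toy_panel.source_region_label,
            known_localities=frozenset({"Christchurch"}),
        )
        clf = HaplotypeSourceClassifier().fit(panel)
        with pytest.raises(LocalityError):
            clf.classify(panel.established_haplotypes[0][1], "Atlantis")

    def test_identical_to_established_never_new_arrival_for_any_thresholds(
        self, toy_panel
    ):
        nz = toy_panel.established_haplotypes[0][1]
        for close_tol in (0.0, 1e-6, 0.003, 0.05, 0.5):
            res = classify_detection(
                nz, "Auckland", toy_panel, AssignmentThresholds(0.0, close_tol)
            )
            assert res.category != "new-arrival"

    def test_zero_close_tol_disables_tier_two(self, toy_panel):
        nz = toy_panel.established_haplotypes[0][1]
        near = _mutate(nz, {7: "A" if nz[7] != "A" else "G"})
        res = classify_detection(near, "Auckland", toy_panel, AssignmentThresholds(0, 0))
        assert res.tier != "close" and res.category == "new-arrival"

    # the panel fixture is immutable, so reuse across examples is safe
    @settings(suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(st.floats(min_value=0.0, max_value=0.3), st.floats(min_value=0.0, max_value=0.3))
    def test_raising_close_tol_never_creates_new_arrivals(self, toy_panel, tol_a, tol_b):
        lo, hi = sorted([tol_a, tol_b])
        nz = toy_panel.established_haplotypes[0][1]
        query = _mutate(nz, {3: "A" if nz[3] != "A" else "G"})
        cat_lo = classify_detection(
            query, "Auckland", toy_panel, AssignmentThresholds(0, lo)
        ).category
        cat_hi = classify_detection(
            query, "Auckland", toy_panel, AssignmentThresholds(0, hi)
        ).category
        if cat_lo != "new-arrival":
            assert cat_hi != "new-arrival"

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(InputError):
            AssignmentThresholds(identical_tol=0.01, close_tol=0.001)


class TestScorePrediction:
    EQ = RegionEquivalence.from_pairs(
        exact=[("Caboolture", "Brisbane (North)")],
        near=[("Brisbane", "Gold Coast-Lamington NP")],
    )

    @pytest.mark.parametrize(
        "predicted, confirmed, tier",
        [
            ("Caboolture", "Brisbane (North)", "exact"),
            ("Brisbane", "Gold Coast-Lamington NP", "near"),
            ("Brisbane", "Sydney", "far"),
            ("Brisbane", "Brisbane (South)", "exact"),  # bare name vs sub-region
            ("Brisbane (North)", "Brisbane (South)", "near"),  # different sub-regions
            ("Sydney?", "Sydney", "exact"),  # trailing qualifier stripped
            ("Adelaide or Brisbane", "Brisbane", "exact"),  # best alternative
            ("Unknown", "Sydney", "no-prediction"),
            (None, "Sydney", "no-prediction"),
        ],
    )
    def test_tier_assignment(self, predicted, confirmed, tier):
        assert score_prediction(confirmed, predicted, self.EQ) == tier

    def test_pair_in_both_tiers_rejected(self):
        with pytest.raises(InputError):
            RegionEquivalence.from_pairs(
                exact=[("A", "B")], near=[("B", "A")]
            )


class TestBatchClassify:
    def test_mixed_batch_counts_match_truth(self, toy_panel):
        nz = toy_panel.established_haplotypes[0][1]
        b1 = toy_panel.native_haplotypes[2].sequence
        queries = [("d1", nz), ("d2", nz), ("d3", b1)]
        locs = pd.DataFrame(
            {
                "detection_id": ["d1", "d2", "d3"],
                "locality": ["Auckland", "Dunedin", "Auckland"],
                "predicted_origin": [None, None, "Sydney"],
            }
        )
        table, counts = batch_classify(queries, locs, toy_panel)
        assert counts == {
            "local-resident": 1,
            "within-country-movement": 1,
            "new-arrival": 1,
        }
        row = table.set_index("detection_id").loc["d3"]
        assert row.prediction_tier == "exact"

    def test_empty_query_set_gives_empty_table(self, toy_panel):
        locs = pd.DataFrame({"detection_id": [], "locality": []})
        table, counts = batch_classify([], locs, toy_panel)
        assert table.empty and counts == {}

    def test_per_row_errors_do_not_abort_the_batch(self, toy_panel):
        nz = toy_panel.established_haplotypes[0][1]
        queries = [("good", nz), ("orphan", nz)]
        locs = pd.DataFrame({"detection_id": ["good"], "locality": ["Auckland"]})
        table, counts = batch_classify(queries, locs, toy_panel)
        assert counts["local-resident"] == 1 and counts["error"] == 1
        assert table.set_index("detection_id").loc["orphan"].error is not None
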