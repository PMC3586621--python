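import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.linalg import expm

from skinktrace.alignment import AlignedSequenceSet, InputError
from skinktrace.distances import (
    BaseComposition,
    SubstitutionCounts,
    base_composition,
    composition_homogeneity_test,
    count_site_patterns,
    distance_matrix,
    jc_distance,
    k2p_distance,
    read_distance_matrix,
    site_summary,
    trn_distance,
    write_distance_matrix,
)

UNIFORM = BaseComposition(0.25, 0.25, 0.25, 0.25, 1000)


def tn93_joint_proportions(pi, alpha1, alpha2, beta, t):
    """Independent oracle: expected P1/P2/Q at divergence t under the TN93
    rate matrix, via the matrix exponential.  The matrix is normalised so
    that t is the expected number of substitutions per site."""
    R = np.zeros((4, 4))  # order A, C, G, T
    for x in range(4):
        for y in range(4):
            if x == y:
                continue
            if {x, y} == {0, 2}:
                w = alpha1
            elif {x, y} == {1, 3}:
                w = alpha2
            else:
                w = beta
            R[x, y] = w * pi[y]
    np.fill_diagonal(R, -R.sum(axis=1))
    R /= -(pi * np.diag(R)).sum()
    J = np.diag(pi) @ expm(R * t)
    P1 = J[0, 2] + J[2, 0]
    P2 = J[1, 3] + J[3, 1]
    Q = J.sum() - np.trace(J) - P1 - P2
    return P1, P2, Q


class TestBaseComposition:
    def test_uniform_single_sequence(self):
        comp = base_composition(AlignedSequenceSet((("s", "ACGT"),)))
        assert comp.as_dict() == pytest.approx({"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25})

    def test_two_sequence_direct_count(self):
        comp = base_composition(AlignedSequenceSet((("a", "AAAA"), ("b", "GGGG"))))
        assert (comp.freq_A, comp.freq_G, comp.freq_C, comp.freq_T) == (0.5, 0.5, 0, 0)

    def test_matches_character_histogram_on_random_set(self):
        rng = np.random.default_rng(0)
        records = tuple(
            (f"s{i}", "".join(rng.choice(list("ACGTN-"), 50))) for i in range(100)
        )
        aln = AlignedSequenceSet(records)
        comp = base_composition(aln)
        tally = Counter("".join(aln.sequences))
        total = sum(tally[b] for b in "ACGT")
        for base, freq in comp.as_dict().items():
            assert freq == pytest.approx(tally[base] / total)
        assert comp.counted_sites == total

    def test_all_ambiguous_raises(self):
        with pytest.raises(InputError):
            base_composition(AlignedSequenceSet((("s", "NN--"),)))


class TestHomogeneityTest:
    def test_identical_sequences_are_perfectly_homogeneous(self):
        aln = AlignedSequenceSet(tuple((f"s{i}", "ACGTAACC") for i in range(6)))
        res = composition_homogeneity_test(aln)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 3 * (6 - 1)

    def test_df_scales_with_sequence_count(self):
        # 195 sequences is the panel size whose test carries 582 df
        aln = AlignedSequenceSet(tuple((f"s{i}", "ACGT") for i in range(195)))
        assert composition_homogeneity_test(aln).df == 582

    def test_statistic_matches_hand_built_contingency_table(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(5)]
        aln = AlignedSequenceSet(tuple((f"s{i}", s) for i, s in enumerate(seqs)))
        obs = np.array([[s.count(b) for b in "ACGT"] for s in seqs], dtype=float)
        pooled = obs.sum(axis=0) / obs.sum()
        exp = obs.sum(axis=1, keepdims=True) * pooled
        manual = ((obs - exp) ** 2 / exp)[exp > 0].sum()
        assert composition_homogeneity_test(aln).statistic == pytest.approx(manual)

    def test_invariant_under_sequence_reordering(self, tiny_alignment):
        stat = composition_homogeneity_test(tiny_alignment).statistic
        rev = AlignedSequenceSet(tuple(reversed(tiny_alignment.records)))
        assert composition_homogeneity_test(rev).statistic == pytest.approx(stat)


class TestSitePatternCounting:
    def test_identical_sequences(self):
        c = count_site_patterns("ACGT", "ACGT")
        assert (c.P1, c.P2, c.Q) == (0, 0, 0)

    def test_single_purine_transition(self):
        c = count_site_patterns("AG", "GG")
        assert (c.P1, c.P2, c.Q, c.compared_sites) == (0.5, 0, 0, 2)

    def test_gapped_pair_hand_enumeration(self):
        # comparable columns: A/G (purine transition), C/T (pyrimidine
        # transition), G/G, T/T; the -/A and N/C columns are excluded
        c = count_site_patterns("ACGT-N", "GTGTAC")
        assert c.compared_sites == 4
        assert (c.P1, c.P2, c.Q) == (0.25, 0.25, 0)

    def test_no_comparable_sites_raises(self):
        with pytest.raises(InputError):
            count_site_patterns("NNNN", "ACGT")


class TestClosedFormDistances:
    def test_zero_difference_gives_zero(self):
        assert jc_distance(0.0) == (0.0, "ok")
        assert k2p_distance(0.0, 0.0) == (0.0, "ok")

    def test_jc_closed_form(self):
        d, flag = jc_distance(0.3)
        assert flag == "ok"
        assert d == pytest.approx(-0.75 * math.log(1 - 0.4), abs=1e-12)

    def test_saturation_flagged(self):
        assert jc_distance(0.8)[1] == "saturated"
        assert k2p_distance(0.1, 0.6)[1] == "saturated"


class TestTN93:
    def test_zero_counts_give_zero(self):
        d, flag = trn_distance(SubstitutionCounts(0, 0, 0, 100), UNIFORM)
        assert (d, flag) == (0.0, "ok")

    def test_reduces_to_k2p_under_uniform_composition(self):
        counts = SubstitutionCounts(0.05, 0.05, 0.06, 1000)
        d_trn, _ = trn_distance(counts, UNIFORM)
        d_k2p, _ = k2p_distance(0.10, 0.06)
        assert abs(d_trn - d_k2p) <= 1e-12

    def test_saturation_when_log_argument_nonpositive(self):
        # Q = 2 gR gY makes w3 = 0
        counts = SubstitutionCounts(0.0, 0.0, 0.5, 1000)
        assert trn_distance(counts, UNIFORM)[1] == "saturated"

    def test_degenerate_composition_without_that_class_is_fine(self):
        comp = BaseComposition(0.5, 0.25, 0.0, 0.25, 100)  # no G at all
        d, flag = trn_distance(SubstitutionCounts(0.0, 0.04, 0.02, 100), comp)
        assert flag == "ok" and d > 0

    def test_degenerate_composition_with_observed_class_raises(self):
        comp = BaseComposition(0.5, 0.25, 0.0, 0.25, 100)
        with pytest.raises(InputError):
            trn_distance(SubstitutionCounts(0.01, 0.0, 0.0, 100), comp)

    def test_agrees_with_matrix_exponential_oracle(self):
        rng = np.random.default_rng(20)
        for _ in range(100):
            pi = rng.dirichlet([8, 8, 8, 8])
            alpha1, alpha2 = rng.uniform(2, 40, 2)
            t = rng.uniform(0.005, 0.5)
            P1, P2, Q = tn93_joint_proportions(pi, alpha1, alpha2, 1.0, t)
            comp = BaseComposition(*pi, counted_sites=1000)
            d, flag = trn_distance(SubstitutionCounts(P1, P2, Q, 1000), comp)
            assert flag == "ok"
            assert abs(d - t) <= 1e-9

    @given(
        st.integers(0, 40), st.integers(0, 40), st.integers(0, 40),
    )
    def test_correction_never_shrinks_below_p_distance(self, n1, n2, nq):
        counts = SubstitutionCounts(n1 / 200, n2 / 200, nq / 200, 200)
        d, flag = trn_distance(counts, UNIFORM)
        if flag == "ok":
            assert d >= counts.p - 1e-12


class TestDistanceMatrix:
    def test_identical_haplotypes_distance_zero(self):
        aln = AlignedSequenceSet((("a", "ACGTACGT"), ("b", "ACGTACGT")))
        dm = distance_matrix(aln, model="p")
        assert dm[("a", "b")] == 0.0

    def test_symmetry_and_zero_diagonal(self, tiny_alignment):
        dm = distance_matrix(tiny_alignment, model="tn93")
        assert np.array_equal(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_cells_match_per_pair_recomputation(self, tiny_alignment):
        dm = distance_matrix(tiny_alignment, model="tn93")
        comp = base_composition(tiny_alignment)
        seqs = dict(tiny_alignment.records)
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                if i < j:
                    d, _ = trn_distance(count_site_patterns(seqs[a], seqs[b]), comp)
                    assert dm.values[i, j] == pytest.approx(d, abs=1e-15)

    def test_roundtrip_through_tab_delimited_file(self, tmp_path, tiny_alignment):
        dm = distance_matrix(tiny_alignment, model="tn93")
        path = tmp_path / "dm.tsv"
        write_distance_matrix(dm, path, precision=10)
        back = read_distance_matrix(path)
        assert back.labels == dm.labels
        assert np.allclose(back.values, dm.values, atol=1e-9)


class TestSiteSummary:
    def test_identical_sequences_have_no_variation(self):
        aln = AlignedSequenceSet(tuple((f"s{i}", "ACGTACGT") for i in range(4)))
        s = site_summary(aln)
        assert (s.variable_sites, s.parsimony_informative_sites) == (0, 0)

    def test_definitional_columns(self):
        # column patterns: AAAT variable-only, AATT informative, AAAA constant
        aln = AlignedSequenceSet(
            (("s1", "AAA"), ("s2", "AAA"), ("s3", "ATA"), ("s4", "TTA"))
        )
        s = site_summary(aln)
        assert s.total_sites == 3
        assert s.variable_sites == 2
        assert s.parsimony_informative_sites == 1

    def test_matches_exhaustive_column_classification(self):
        rng = np.random.default_rng(9)
        records = tuple(
            (f"s{i}", "".join(rng.choice(list("ACGTN-"), 50))) for i in range(10)
        )
        aln = AlignedSequenceSet(records)
        s = site_summary(aln)
        variable = informative = 0
        for col in zip(*aln.sequences):
            states = Counter(c for c in col if c in "ACGT")
            if len(states) >= 2:
                variable += 1
                if sum(1 for v in states.values() if v >= 2) >= 2:
                    informative += 1
        assert (s.variable_sites, s.parsimony_informative_sites) == (variable, informative)
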