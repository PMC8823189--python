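"""Blinded inference: divergence criterion, relative variance, clustering,
constrained grouping and the marker-based intervention call."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
from hypothesis import given
from hypothesis import strategies as st

from decondseq.blinded import (
    BlindedAnalysis,
    GroupPrediction,
    classify_change,
    consistent_trend_genes,
    divergent_genes_for_pair,
    final_blinded_gene_set,
    hierarchical_cluster,
    intersect_gene_lists,
    linkage_to_newick,
    pearson_distance,
    predict_intervention,
    predict_two_groups,
    relative_variance,
    top_k_by_relative_variance,
)
from decondseq.datatypes import FoldChangeTable
from decondseq.normalize import compute_log2_fold_changes
from decondseq.simulate import SimulationConfig, simulate_study

from .conftest import make_sheet

THETA = 0.585

# representative log2FC values per change class (including the boundary)
CLASS_VALUES = {
    "up": [THETA, THETA + 0.5, 1.0],
    "down": [-THETA, -THETA - 0.5, -1.0],
    "no_change": [0.0, 0.3, -0.3, THETA - 1e-9],
}


def divergent_oracle(class1: str, class2: str) -> bool:
    """Brute-force inclusion rule: one subject changed, the other showing
    no change or the opposite trend (symmetric)."""
    changed = lambda c: c != "no_change"  # noqa: E731

    def one_way(a, b):
        return changed(a) and (b == "no_change" or (changed(b) and b != a))

    return one_way(class1, class2) or one_way(class2, class1)


class TestClassifyChange:
    def test_boundary_is_inclusive(self):
        assert classify_change(THETA, THETA) == "up"
        assert classify_change(-THETA, THETA) == "down"

    def test_zero_is_no_change(self):
        assert classify_change(0.0) == "no_change"

    def test_band_is_symmetric(self):
        # the no-change band is (-theta, theta): open at both ends in log2 space
        for v in (0.1, 0.5, 0.584):
            assert classify_change(v) == "no_change"
            assert classify_change(-v) == "no_change"
        assert classify_change(0.586) == "up"
        assert classify_change(-0.586) == "down"

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_change(float("nan"))


class TestDivergenceCriterion:
    def test_full_grid_matches_enumeration_oracle(self):
        """Exhaustive 3x3 classification grid with boundary representatives."""
        for c1, c2 in itertools.product(CLASS_VALUES, CLASS_VALUES):
            for v1, v2 in itertools.product(CLASS_VALUES[c1], CLASS_VALUES[c2]):
                s1 = pd.Series({"g": v1})
                s2 = pd.Series({"g": v2})
                got = "g" in divergent_genes_for_pair(s1, s2, THETA)
                assert got == divergent_oracle(c1, c2), (c1, v1, c2, v2)

    def test_specific_cases(self):
        s1 = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0, "d": 0.3})
        s2 = pd.Series({"a": 0.1, "b": -0.7, "c": 1.0, "d": -0.3})
        out = divergent_genes_for_pair(s1, s2)
        assert out == {"a", "b"}  # changed-vs-flat and opposing included

    @given(
        st.lists(
            st.tuples(st.floats(-3, 3, allow_nan=False), st.floats(-3, 3, allow_nan=False)),
            min_size=1,
            max_size=20,
        )
    )
    def test_symmetric_in_subject_order(self, values):
        idx = [f"g{i}" for i in range(len(values))]
        s1 = pd.Series([a for a, _ in values], index=idx)
        s2 = pd.Series([b for _, b in values], index=idx)
        assert divergent_genes_for_pair(s1, s2) == divergent_genes_for_pair(s2, s1)

    def test_invariant_to_gene_order(self):
        s1 = pd.Series({"a": 1.0, "b": 0.0, "c": -1.0})
        s2 = pd.Series({"a": 0.0, "b": 1.0, "c": 1.0})
        perm = ["c", "a", "b"]
        assert divergent_genes_for_pair(s1, s2) == divergent_genes_for_pair(
            s1.loc[perm], s2.loc[perm]
        )


class TestConsistentTrend:
    def test_unanimous_included_broken_excluded(self):
        fc = pd.DataFrame(
            {
                "s1": [1.0, 1.0, 1.0, -1.0],
                "s2": [1.0, 0.0, 1.0, -1.0],
                "s3": [1.0, 1.0, -1.0, -1.0],
            },
            index=["all_up", "one_flat", "mixed_sign", "all_down"],
        )
        assert consistent_trend_genes(fc) == {"all_up", "all_down"}


class TestRelativeVariance:
    def test_constant_vector_scores_zero(self):
        assert relative_variance([5, 5, 5, 5]) == 0.0

    def test_hand_computed_oracle(self):
        # var([2,4,6,8], ddof=1) = 20/3; mean = 5
        assert relative_variance([2, 4, 6, 8]) == pytest.approx((20 / 3) / 5)

    def test_all_zeros_excluded(self):
        assert np.isnan(relative_variance([0, 0, 0, 0]))

    def test_top_k_ranking_and_ties(self):
        matrix = pd.DataFrame(
            {
                "s1": [2.0, 1.0, 10.0, 2.0],
                "s2": [4.0, 1.0, 10.0, 4.0],
                "s3": [6.0, 1.0, 10.0, 6.0],
                "s4": [8.0, 1.0, 10.0, 8.0],
            },
            index=["gB", "gC", "gD", "gA"],
        )
        # gA and gB tie exactly; lexicographic winner first
        assert top_k_by_relative_variance(matrix, ["s1", "s2", "s3", "s4"], 1) == ["gA"]
        full = top_k_by_relative_variance(matrix, ["s1", "s2", "s3", "s4"], 4)
        assert full == ["gA", "gB", "gC", "gD"]

    def test_k_exceeding_scored_genes_rejected(self):
        matrix = pd.DataFrame({"s1": [1.0, 0.0], "s2": [2.0, 0.0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="exceeds"):
            top_k_by_relative_variance(matrix, ["s1", "s2"], 2)

    @given(st.integers(1, 8), st.integers(0, 2**31 - 1))
    def test_top_k_lists_nested_in_k(self, k, seed):
        rng = np.random.default_rng(seed)
        matrix = pd.DataFrame(
            rng.lognormal(0, 1, size=(10, 4)),
            index=[f"g{i}" for i in range(10)],
            columns=list("abcd"),
        )
        smaller = top_k_by_relative_variance(matrix, list("abcd"), k)
        larger = top_k_by_relative_variance(matrix, list("abcd"), k + 1)
        assert set(smaller) <= set(larger)
        assert larger[:k] == smaller


class TestSetAlgebra:
    def test_intersections(self):
        assert intersect_gene_lists([{"A", "B"}, {"B", "C"}]) == {"B"}
        assert intersect_gene_lists([{"A"}, {"B"}]) == set()
        assert intersect_gene_lists([{"A", "B"}]) == {"A", "B"}
        assert final_blinded_gene_set({"A", "B"}, {"B", "C"}) == {"B"}


class TestPearsonDistance:
    def test_perfect_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_distance(x, 2 * x + 1) == pytest.approx(0.0)

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson_distance(x, -x) == pytest.approx(2.0)

    def test_orthogonal_vectors(self):
        assert pearson_distance([1, -1, 1, -1], [1, 1, -1, -1]) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_distance([1, 1, 1], [1, 2, 3])


class TestHierarchicalClustering:
    def _block_distance(self):
        labels = ["a1", "a2", "b1", "b2"]
        d = np.full((4, 4), 0.9)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.15
        return pd.DataFrame(d, index=labels, columns=labels)

    def test_two_samples_join_at_their_distance(self):
        dist = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["x", "y"], columns=["x", "y"])
        linkage, labels = hierarchical_cluster(dist)
        assert labels == ["x", "y"]
        assert linkage[0, 2] == pytest.approx(0.4)

    def test_planted_blocks_merge_first(self):
        linkage, labels = hierarchical_cluster(self._block_distance())
        first = {labels[int(linkage[0, 0])], labels[int(linkage[0, 1])]}
        second = {labels[int(linkage[1, 0])], labels[int(linkage[1, 1])]}
        assert first == {"a1", "a2"}
        assert second == {"b1", "b2"}

    def test_merge_heights_invariant_under_permutation(self):
        dist = self._block_distance()
        perm = ["b2", "a1", "b1", "a2"]
        l1, _ = hierarchical_cluster(dist)
        l2, _ = hierarchical_cluster(dist.loc[perm, perm])
        assert np.allclose(sorted(l1[:, 2]), sorted(l2[:, 2]))

    def test_newick_export_contains_all_leaves(self):
        linkage, labels = hierarchical_cluster(self._block_distance())
        nwk = linkage_to_newick(linkage, labels)
        assert nwk.endswith(";") and all(lab in nwk for lab in labels)


class TestTwoGroupPrediction:
    def test_single_pair_splits_trivially(self):
        sheet = make_sheet([("1A", "Pair 1", "M", "control"), ("1B", "Pair 1", "M", "exercise")])
        dist = pd.DataFrame(
            [[0.0, 0.5], [0.5, 0.0]], index=["1A", "1B"], columns=["1A", "1B"]
        )
        pred = predict_two_groups(dist, sheet)
        assert pred.partition() == frozenset({frozenset({"1A"}), frozenset({"1B"})})

    def test_violating_pair_repaired_with_lower_cost_move(self):
        """Both members of pair 1 land in one cluster; the cheaper move wins."""
        sheet = make_sheet(
            [
                ("s1", "Pair 1", "M", "control"),
                ("s2", "Pair 1", "M", "exercise"),
                ("s3", "Pair 2", "M", "control"),
                ("s4", "Pair 2", "M", "exercise"),
            ]
        )
        labels = ["s1", "s2", "s3", "s4"]
        d = pd.DataFrame(0.1, index=labels, columns=labels)
        for lab, v in (("s1", 0.6), ("s2", 0.4), ("s3", 0.7)):
            d.loc[lab, "s4"] = d.loc["s4", lab] = v
        np.fill_diagonal(d.values, 0.0)
        pred = predict_two_groups(d, sheet)
        # the raw cut isolates s4, violating pair 1's constraint
        assert pred.pair_constraint_ok == {"Pair 1": False, "Pair 2": True}
        # brute force: moving s2 (cost 0.4) beats moving s1 (cost 0.6)
        assert pred.partition() == frozenset(
            {frozenset({"s1", "s3"}), frozenset({"s2", "s4"})}
        )
        for pair, members in {"Pair 1": ("s1", "s2"), "Pair 2": ("s3", "s4")}.items():
            assert pred.group_of(members[0]) != pred.group_of(members[1])

    def test_recovers_planted_partition_on_synthetic_studies(self):
        """Moderate-size planted two-group studies are recovered reliably."""
        hits = 0
        n_seeds = 6
        for seed in range(n_seeds):
            cfg = SimulationConfig(n_genes=2000, n_deg_control=80, n_deg_exercise=10,
                                   n_shared_same_direction=3, n_shared_opposing=2,
                                   include_female_trio=False, seed=seed)
            matrix, sheet, catalog, truth = simulate_study(cfg)
            hidden = sheet.drop(columns=["intervention"]).assign(intervention="control")
            est = BlindedAnalysis(top_k=300).fit(matrix_renorm(matrix, catalog), hidden, catalog)
            truth_part = frozenset(
                (
                    frozenset(s for s, g in truth.intervention.items() if g == "control"),
                    frozenset(s for s, g in truth.intervention.items() if g == "exercise"),
                )
            )
            hits += est.prediction_.partition() == truth_part
        assert hits >= n_seeds - 1


def matrix_renorm(matrix, catalog):
    from decondseq.normalize import renormalize_coding_tpm

    return renormalize_coding_tpm(matrix, catalog)


class TestInterventionCall:
    def _fc(self, a_vals, b_vals):
        values = pd.DataFrame(
            {"1A": a_vals, "1B": b_vals, "2A": a_vals, "2B": b_vals},
            index=["XIRP1", "TNFRSF12A", "HSPB1"],
        )
        return FoldChangeTable(values=values, epsilon=0.01)

    def _prediction(self):
        return GroupPrediction(
            group_a=["1A", "2A"], group_b=["1B", "2B"], pair_constraint_ok={}
        )

    def test_markers_up_in_control_label_the_up_group(self):
        fc = self._fc([1.0, 0.8, 0.5], [-0.2, -0.1, -0.4])
        pred = predict_intervention(
            self._prediction(), fc, {"XIRP1": 1, "TNFRSF12A": 1, "HSPB1": 1}
        )
        assert pred.intervention_of == {"A": "control", "B": "exercise"}
        assert not pred.uncalled

    def test_flipping_expected_signs_flips_the_label(self):
        fc = self._fc([1.0, 0.8, 0.5], [-0.2, -0.1, -0.4])
        pred = predict_intervention(
            self._prediction(), fc, {"XIRP1": -1, "TNFRSF12A": -1, "HSPB1": -1}
        )
        assert pred.intervention_of == {"A": "exercise", "B": "control"}

    def test_symmetric_zero_vote_is_uncalled(self):
        fc = self._fc([0.0, 0.0, 0.0], [0.0, 0.0, 0.0])
        pred = predict_intervention(self._prediction(), fc, {"XIRP1": 1})
        assert pred.uncalled and pred.intervention_of == {"A": None, "B": None}

    def test_missing_markers_rejected(self):
        fc = self._fc([1.0, 0.8, 0.5], [-0.2, -0.1, -0.4])
        with pytest.raises(Exception, match="marker"):
            predict_intervention(self._prediction(), fc, {"NOPE": 1})


class TestBlindedPipelineConsistency:
    def test_noiseless_final_set_equals_planted_control_degs(self):
        """With no noise, planted control DEGs are the only divergent genes
        and dominate relative variance, so the final blinded set recovers
        them exactly."""
        cfg = SimulationConfig(
            n_genes=300, n_deg_control=25, n_deg_exercise=0,
            n_shared_same_direction=0, n_shared_opposing=0,
            noise_sd=0.0, baseline_subject_sd=0.0, baseline_log_sd=0.3,
            effect_mean=1.5, effect_sd=0.1,  # every planted effect clears theta
            include_female_trio=False, marker_genes=("XIRP1",), seed=2,
        )
        matrix, sheet, catalog, truth = simulate_study(cfg)
        hidden = sheet.drop(columns=["intervention"]).assign(intervention="control")
        est = BlindedAnalysis(top_k=25).fit(matrix_renorm(matrix, catalog), hidden, catalog)
        assert est.divergence_consistent_ == truth.deg_set("control")
        assert est.final_genes_ == truth.deg_set("control")
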