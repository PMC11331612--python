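"""Frequencies, correspondence analysis, classical MDS, within-group spread."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from mtclades import (
    classical_mds,
    correspondence_analysis,
    frequency_table,
    leaf_distance_matrix,
    max_clade_partition,
    representative_reduction,
    simulate_tree,
    within_group_distances,
)
from mtclades.errors import MtCladesError


def _gt(samples, pops, groups, scheme="g"):
    return pd.DataFrame({"sample_id": samples, "population": pops, scheme: groups})


class TestFrequencyTable:
    def test_hand_countable(self):
        gt = _gt(["a", "b", "c", "d"], ["P1", "P1", "P2", "P2"], ["X", "Y", "X", "Y"])
        counts, freqs = frequency_table(gt, "g")
        assert (counts.values == 1).all()
        assert (freqs.values == 0.5).all()

    def test_single_population(self):
        gt = _gt(["a", "b", "c"], ["P1"] * 3, ["X", "X", "Y"])
        counts, freqs = frequency_table(gt, "g")
        assert counts.shape == (1, 2)
        assert freqs.loc["P1", "X"] == pytest.approx(2 / 3)

    def test_rows_sum_to_population_sizes_and_one(self):
        rng = np.random.default_rng(0)
        gt = _gt(
            [f"s{i}" for i in range(200)],
            rng.choice(["P1", "P2", "P3"], 200),
            rng.choice(list("ABCD"), 200),
        )
        counts, freqs = frequency_table(gt, "g")
        assert counts.values.sum() == 200
        assert np.allclose(freqs.sum(axis=1), 1, atol=1e-12)

    def test_unknown_scheme_column(self):
        with pytest.raises(MtCladesError):
            frequency_table(_gt(["a"], ["P"], ["X"]), "nope")

    def test_recovers_generator_frequencies(self):
        """Empirical group frequencies sit within 3 SE of the Dirichlet truth."""
        from mtclades import assign_populations

        n_per_pop = 500
        pa = assign_populations(
            [f"s{i}" for i in range(3 * n_per_pop)], n_pops=3,
            concentration=5.0, seed=7,
        )
        gt = pd.DataFrame(
            {
                "sample_id": list(pa.population_of),
                "population": list(pa.population_of.values()),
                "g": [pa.sampled_group_of[s] for s in pa.population_of],
            }
        )
        _, freqs = frequency_table(gt, "g")
        truth = pa.true_frequencies
        for pop in truth.index:
            for grp in truth.columns:
                p = truth.loc[pop, grp]
                se = np.sqrt(p * (1 - p) / n_per_pop)
                observed = freqs.loc[pop, grp] if grp in freqs.columns else 0.0
                assert abs(observed - p) <= 3 * se + 1e-9, (pop, grp)


class TestCorrespondenceAnalysis:
    def test_independent_table_has_zero_inertia(self):
        row = np.array([1.0, 2.0, 3.0])
        col = np.array([4.0, 5.0])
        ct = pd.DataFrame(np.outer(row, col))
        res = correspondence_analysis(ct)
        assert res.total_inertia == pytest.approx(0, abs=1e-12)
        assert res.n_dimensions == 0

    def test_diagonal_table_maximal_association(self):
        ct = pd.DataFrame(np.diag([10.0, 10.0, 10.0]))
        res = correspondence_analysis(ct)
        # chi-squared = 60 on n = 30 -> inertia 2 = min(I, J) - 1
        assert res.total_inertia == pytest.approx(2.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_total_inertia_equals_chisq_over_n(self, seed):
        rng = np.random.default_rng(seed)
        ct = pd.DataFrame(rng.integers(1, 40, size=(4, 6)).astype(float))
        res = correspondence_analysis(ct)
        chi2 = chi2_contingency(ct.values, correction=False)[0]
        assert res.total_inertia == pytest.approx(chi2 / ct.values.sum(), abs=1e-10)

    def test_inertia_invariant_under_permutation_and_scale(self):
        rng = np.random.default_rng(3)
        ct = pd.DataFrame(rng.integers(1, 30, size=(5, 4)).astype(float))
        base = correspondence_analysis(ct)
        perm = ct.iloc[rng.permutation(5), rng.permutation(4)]
        assert correspondence_analysis(perm).total_inertia == pytest.approx(
            base.total_inertia, abs=1e-12
        )
        scaled = correspondence_analysis(ct * 7.5)
        assert np.allclose(scaled.row_coords.values, base.row_coords.values, atol=1e-10)

    def test_zero_rows_pruned(self):
        ct = pd.DataFrame([[5.0, 1.0], [0.0, 0.0], [2.0, 4.0]])
        res = correspondence_analysis(ct)
        assert list(res.row_coords.index) == [0, 2]

    def test_inertias_non_increasing(self):
        rng = np.random.default_rng(5)
        ct = pd.DataFrame(rng.integers(1, 50, size=(6, 6)).astype(float))
        res = correspondence_analysis(ct)
        assert (np.diff(res.inertia) <= 1e-12).all()
        assert res.n_dimensions <= min(ct.shape) - 1


class TestClassicalMds:
    def test_collinear_points_recovered_in_1d(self):
        d = pd.DataFrame([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = classical_mds(d, k=1)
        got = np.abs(res.coords.values[:, 0] - res.coords.values[1, 0])
        np.testing.assert_allclose(sorted(got), [0, 1, 1], atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_on_euclidean_input(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(10, 2))
        d = pd.DataFrame(np.linalg.norm(pts[:, None] - pts[None, :], axis=-1))
        res = classical_mds(d, k=2)
        got = np.linalg.norm(
            res.coords.values[:, None] - res.coords.values[None, :], axis=-1
        )
        assert np.abs(got - d.values).max() < 1e-9

    def test_tree_metric_reports_negative_eigenvalues(self):
        # a clock-like tree metric is Euclidean; breaking ultrametricity by
        # rescaling branches gives an additive but non-Euclidean metric
        from mtclades import Phylogeny

        tree = simulate_tree(15, seed=0, target_diameter=0.01)
        rng = np.random.default_rng(0)
        for node in tree.postorder:
            if node.branch_length is not None:
                node.branch_length *= float(rng.uniform(0.2, 3.0))
        d = leaf_distance_matrix(Phylogeny(tree.root))
        res = classical_mds(d, k=2)
        assert res.eigenvalues.min() < -1e-6 * res.eigenvalues.max()
        assert res.coords.shape == (15, 2)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_k_truncated_with_warning(self):
        d = pd.DataFrame([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.warns(UserWarning, match="truncating"):
            res = classical_mds(d, k=3)
        assert res.coords.shape[1] < 3


class TestWithinGroupDistances:
    def test_pair_of_two(self):
        d = pd.DataFrame(
            [[0, 0.004], [0.004, 0]], index=["a", "b"], columns=["a", "b"]
        )
        gt = _gt(["a", "b"], ["P", "P"], ["X", "X"])
        summary, dists = within_group_distances(d, gt, "g")
        row = summary.set_index("group").loc["X"]
        assert row["n_pairs"] == 1
        assert row["mean_distance"] == row["max_distance"] == pytest.approx(0.004)

    def test_singleton_group_empty_distribution(self):
        d = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        summary, dists = within_group_distances(d, _gt(["a"], ["P"], ["X"]), "g")
        assert summary.iloc[0]["n_pairs"] == 0
        assert len(dists["X"]) == 0

    def test_missing_sample_named(self):
        d = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        with pytest.raises(MtCladesError, match="zz"):
            within_group_distances(d, _gt(["zz"], ["P"], ["X"]), "g")

    def test_max_clade_groups_respect_threshold(self):
        """The dashed-line property: within-cluster distances never exceed t."""
        tree = simulate_tree(50, seed=17, target_diameter=0.01)
        d = leaf_distance_matrix(tree)
        for t in (0.006, 0.004, 0.002):
            part = max_clade_partition(tree, t)
            gt = pd.DataFrame(
                {
                    "sample_id": list(part.assignment),
                    "population": "P",
                    "tc": [str(c) for c in part.assignment.values()],
                }
            )
            summary, _ = within_group_distances(d, gt, "tc")
            assert (summary["max_distance"].dropna() <= t + 1e-12).all()


class TestRepresentativeReduction:
    def test_all_identical_tuples(self):
        gt = _gt(["c", "a", "b"], ["P"] * 3, ["X"] * 3)
        reps, reduced = representative_reduction(gt, ["g"])
        assert reps == ["a"]  # lexicographically smallest id
        assert len(reduced) == 1

    def test_all_distinct_tuples(self):
        gt = _gt(["a", "b", "c"], ["P"] * 3, ["X", "Y", "Z"])
        reps, _ = representative_reduction(gt, ["g"])
        assert reps == ["a", "b", "c"]

    def test_covers_every_combination_once(self):
        rng = np.random.default_rng(9)
        gt = pd.DataFrame(
            {
                "sample_id": [f"s{i:03d}" for i in range(150)],
                "population": rng.choice(["P1", "P2"], 150),
                "sc": rng.choice(["L", "M"], 150),
                "scl": rng.choice(["L0", "L1", "M"], 150),
            }
        )
        reps, reduced = representative_reduction(gt, ["sc", "scl"])
        expected_classes = set(map(tuple, gt[["sc", "scl"]].values))
        assert len(reps) == len(expected_classes)
        assert set(map(tuple, reduced[["sc", "scl"]].values)) == expected_classes
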