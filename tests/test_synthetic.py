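"""Generator correctness: reproducibility, calibration, internal consistency."""

import numpy as np
import pytest

from mtclades import (
    assign_populations,
    classify_names,
    label_haplogroups,
    leaf_distance_matrix,
    make_bundle,
    pairwise_differences,
    parse_name,
    simulate_tree,
    write_newick,
)
from mtclades.errors import MtCladesError
from mtclades.synthetic import simulate_msa

from conftest import clade_leafsets


class TestSimulateTree:
    def test_two_leaves_is_a_cherry_with_target_diameter(self):
        tree = simulate_tree(2, seed=0, target_diameter=0.004)
        d = leaf_distance_matrix(tree)
        assert d.values.max() == pytest.approx(0.004, abs=1e-9)

    @pytest.mark.parametrize("model", ["yule", "kingman"])
    def test_seeded_reproducibility(self, model):
        a = simulate_tree(30, model=model, seed=42, target_diameter=0.01)
        b = simulate_tree(30, model=model, seed=42, target_diameter=0.01)
        assert write_newick(a) == write_newick(b)

    def test_diameter_rescaling(self):
        tree = simulate_tree(100, seed=1, target_diameter=0.01)
        assert leaf_distance_matrix(tree).values.max() == pytest.approx(0.01, abs=1e-9)

    def test_invalid_parameters(self):
        with pytest.raises(MtCladesError):
            simulate_tree(1, seed=0)
        with pytest.raises(MtCladesError):
            simulate_tree(5, target_diameter=0.0, seed=0)
        with pytest.raises(MtCladesError):
            simulate_tree(5, model="bd", seed=0)


class TestLabelHaplogroups:
    def test_zero_rates_all_strict(self):
        tree = simulate_tree(50, seed=3, target_diameter=0.01)
        rates = {k: 0.0 for k in ("apostrophe", "plus_at", "consecutive_upper", "consecutive_lower")}
        leaf_map, _, book = label_haplogroups(tree, irregularity_rates=rates, seed=3)
        summary = classify_names(list(leaf_map.values()))
        assert summary.counts["strict_cladistic"] == summary.total
        assert all(v == 0 for v in book.leaf_flag_counts.values())

    def test_injection_bookkeeping_matches_classifier(self):
        """Injected irregularity counts are recovered exactly by the parser."""
        tree = simulate_tree(200, seed=9, target_diameter=0.01)
        rates = {"apostrophe": 0.1, "plus_at": 0.15,
                 "consecutive_upper": 0.3, "consecutive_lower": 0.08}
        leaf_map, _, book = label_haplogroups(
            tree, hierarchy_depth=5, irregularity_rates=rates, seed=4
        )
        summary = classify_names(list(leaf_map.values()))
        assert summary.counts["has_apostrophe"] == book.leaf_flag_counts["apostrophe"]
        assert summary.counts["has_symbols"] == book.leaf_flag_counts["plus_at"]
        assert summary.counts["consecutive_upper"] == book.leaf_flag_counts["consecutive_upper"]
        assert summary.counts["consecutive_lower"] == book.leaf_flag_counts["consecutive_lower"]

    def test_names_resolve_and_are_clade_consistent(self, bundle):
        """The MRCA name of any clade's leaves is an ancestor of each member."""
        h = bundle.hierarchy
        for name in bundle.leaf_haplogroups.values():
            h.resolve(name)
        leaf_hg = bundle.leaf_haplogroups
        for node, leaves in clade_leafsets(bundle.tree):
            if node.is_leaf:
                continue
            names = [leaf_hg[leaf] for leaf in leaves]
            mrca = h.mrca(names)
            for name in names:
                assert h.is_ancestor_or_self(mrca, name)

    def test_seeded_reproducibility(self):
        tree = simulate_tree(40, seed=5, target_diameter=0.01)
        a = label_haplogroups(tree, seed=6)
        b = label_haplogroups(tree, seed=6)
        assert a[0] == b[0]
        assert a[1].names == b[1].names


class TestAssignPopulations:
    def test_single_population(self):
        pa = assign_populations(["a", "b", "c"], n_pops=1, seed=0)
        assert set(pa.population_of.values()) == {"POP1"}

    def test_large_concentration_near_uniform(self):
        """With a huge concentration the sampled groups approach uniformity."""
        leaves = [f"s{i}" for i in range(2000)]
        pa = assign_populations(leaves, n_pops=1, concentration=1e6, seed=1, n_groups=4)
        counts = np.array(
            [sum(g == f"G{j + 1}" for g in pa.sampled_group_of.values()) for j in range(4)]
        )
        se = np.sqrt(0.25 * 0.75 / 2000)
        assert (np.abs(counts / 2000 - 0.25) <= 3 * se).all()

    def test_seeded_reproducibility(self):
        leaves = [f"s{i}" for i in range(50)]
        a = assign_populations(leaves, n_pops=3, seed=9)
        b = assign_populations(leaves, n_pops=3, seed=9)
        assert a.population_of == b.population_of
        assert a.true_frequencies.equals(b.true_frequencies)


class TestSimulateMsa:
    def test_zero_rate_identical_sequences(self):
        tree = simulate_tree(8, seed=2, target_diameter=0.01)
        msa = simulate_msa(tree, n_sites=100, rate=0.0, seed=2)
        assert len({msa.sequence(s) for s in msa.ids}) == 1

    def test_cherry_p_distance_matches_closed_form(self):
        """Cherry divergence matches (3/4)(1 - e^(-4l/3)) within 3 SE."""
        from mtclades import read_newick

        ell = 0.05
        tree = read_newick(f"(A:{ell / 2},B:{ell / 2});")
        msa = simulate_msa(tree, n_sites=10_000, rate=1.0, seed=5)
        p = pairwise_differences(msa, mode="p").loc["A", "B"]
        expected = 0.75 * (1 - np.exp(-4 * ell / 3))
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(p - expected) <= 3 * se

    def test_seeded_reproducibility(self):
        tree = simulate_tree(10, seed=7, target_diameter=0.01)
        a = simulate_msa(tree, n_sites=300, rate=1.0, seed=8)
        b = simulate_msa(tree, n_sites=300, rate=1.0, seed=8)
        assert all(a.sequence(s) == b.sequence(s) for s in a.ids)


class TestBundle:
    def test_bundle_is_internally_consistent(self, bundle):
        assert set(bundle.msa.ids) == set(bundle.tree.leaf_labels)
        assert set(bundle.leaf_haplogroups) == set(bundle.tree.leaf_labels)
        assert set(bundle.populations.population_of) == set(bundle.tree.leaf_labels)
        for name in bundle.leaf_haplogroups.values():
            parse_name(name)
            bundle.hierarchy.resolve(name)

    def test_bundle_feeds_every_analysis(self, bundle):
        """A bundle flows through grouping, clustering, addressing, metrics."""
        from mtclades import (
            assign_addresses,
            correspondence_analysis,
            classical_mds,
            frequency_table,
            max_clade_partition,
            within_group_distances,
        )
        from mtclades.nomenclature import annotate_groupings

        gt = annotate_groupings(bundle.grouping_table())
        part = max_clade_partition(bundle.tree, 0.004)
        gt["tc_0.004"] = [str(part.assignment[s]) for s in gt["sample_id"]]
        counts, _ = frequency_table(gt, "scl")
        if counts.shape[0] >= 2 and counts.shape[1] >= 2:
            correspondence_analysis(counts)
        d = pairwise_differences(bundle.msa)
        classical_mds(d, k=2)
        within_group_distances(d, gt, "scl")
        addresses = assign_addresses(bundle.tree)
        assert len(addresses) == len(bundle.tree)

    def test_same_seed_same_bundle(self):
        a = make_bundle(n_leaves=20, n_pops=2, n_sites=100, seed=5)
        b = make_bundle(n_leaves=20, n_pops=2, n_sites=100, seed=5)
        assert write_newick(a.tree) == write_newick(b.tree)
        assert a.leaf_haplogroups == b.leaf_haplogroups
        assert a.populations.population_of == b.populations.population_of
        assert all(a.msa.sequence(s) == b.msa.sequence(s) for s in a.msa.ids)
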