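"""Edit network, Poisson-binomial top-node selection, tree reconstruction."""

import itertools

import numpy as np
import pytest
from scipy import stats

from deamtrace import bulk_tree as bt


def unique_edit_tree(depth, edits_per_division=2):
    """Deterministic noiseless lineage: every division introduces unique
    edits; returns (barcodes, truth SampleTree)."""
    barcodes = {"R": frozenset()}
    parent = {"R": None}
    frontier = ["R"]
    counter = itertools.count()
    for _g in range(depth):
        nxt = []
        for mom in frontier:
            for c in "01":
                child = mom + c
                own = frozenset(f"e{next(counter):04d}" for _ in range(edits_per_division))
                barcodes[child] = barcodes[mom] | own
                parent[child] = mom
                nxt.append(child)
        frontier = nxt
    return barcodes, bt.SampleTree(parent=parent)


class TestEditNetwork:
    def test_shared_edit_expression(self):
        net = bt.build_edit_network({"a": {"e1"}, "b": {"e1", "e2"}})
        assert net.expressing["e1"] == frozenset({"a", "b"})
        assert frozenset({"e1", "e2"}) in net.edges

    def test_disjoint_barcodes_no_edges(self):
        net = bt.build_edit_network({"a": {"e1"}, "b": {"e2"}})
        assert net.edges == set()

    @pytest.mark.parametrize("seed", [0, 1])
    def test_edges_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        barcodes = {
            f"n{i}": frozenset(f"e{j}" for j in range(12) if rng.random() < 0.3)
            for i in range(15)
        }
        net = bt.build_edit_network(barcodes)
        expected = set()
        for x, y in itertools.combinations(net.edits, 2):
            if any(x in b and y in b for b in barcodes.values()):
                expected.add(frozenset((x, y)))
        assert net.edges == expected


class TestFindClades:
    def test_four_planted_clades(self):
        # four groups of samples; within a clade edits co-occur in most
        # samples, across clades only via one noisy bridge sample
        barcodes = {}
        for c in range(4):
            edits = {f"c{c}e{k}" for k in range(4)}
            for s in range(4):
                barcodes[f"g{c}s{s}"] = frozenset(edits)
        barcodes["noise"] = frozenset({"c0e0", "c1e0"})
        net = bt.build_edit_network(barcodes)
        clades = bt.find_clades(net, min_overlap=0.3)
        assert len(clades) == 4
        assert {len(c) for c in clades} == {4}

    def test_threshold_zero_equals_plain_components(self):
        barcodes = {"a": {"e1", "e2"}, "b": {"e2", "e3"}, "c": {"e4"}}
        net = bt.build_edit_network(barcodes)
        clades = bt.find_clades(net, min_overlap=0.0)
        assert sorted(clades, key=min) == [
            frozenset({"e1", "e2", "e3"}),
            frozenset({"e4"}),
        ]

    def test_fully_shared_single_component(self):
        barcodes = {f"s{i}": {"e1", "e2", "e3"} for i in range(4)}
        net = bt.build_edit_network(barcodes)
        assert bt.find_clades(net, min_overlap=0.5) == [frozenset({"e1", "e2", "e3"})]


class TestDetectionRate:
    def test_three_of_four_neighbour_expressers(self):
        # neighbours of x are expressed by 4 nodes, 3 of which carry x
        barcodes = {
            "n1": {"x", "y"},
            "n2": {"x", "y"},
            "n3": {"x", "y"},
            "n4": {"y"},
        }
        net = bt.build_edit_network(barcodes)
        assert bt.detection_rate("x", net) == pytest.approx(0.75)

    def test_fully_co_expressed(self):
        net = bt.build_edit_network({"n1": {"x", "y"}, "n2": {"x", "y"}})
        assert bt.detection_rate("x", net) == 1.0

    def test_isolated_edit_errors(self):
        net = bt.build_edit_network({"n1": {"x"}, "n2": {"y", "z"}})
        with pytest.raises(ValueError):
            bt.detection_rate("x", net)


class TestPairwiseEditProbability:
    def test_zero_rate(self):
        assert bt.pairwise_edit_probability(0.0, 5) == 0.0

    def test_certain(self):
        assert bt.pairwise_edit_probability(1.0, 1) == 1.0

    def test_half_two_cells(self):
        assert bt.pairwise_edit_probability(0.5, 2) == pytest.approx(0.75)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bt.pairwise_edit_probability(1.5, 1)


class TestPoissonBinomialCdf:
    def test_two_coins(self):
        assert bt.poisson_binomial_cdf([0.5, 0.5], 1) == pytest.approx(0.75)

    def test_all_zero(self):
        assert bt.poisson_binomial_cdf([0.0, 0.0], 0) == 1.0

    def test_matches_binomial_closed_form(self):
        probs = [0.3] * 8
        for k in range(9):
            assert bt.poisson_binomial_cdf(probs, k) == pytest.approx(
                stats.binom.cdf(k, 8, 0.3)
            )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.random(10)
        # brute force over all 2^10 outcomes
        pmf = np.zeros(11)
        for bits in itertools.product([0, 1], repeat=10):
            p = np.prod([pi if b else 1 - pi for pi, b in zip(probs, bits)])
            pmf[sum(bits)] += p
        for k in range(11):
            assert bt.poisson_binomial_cdf(probs, k) == pytest.approx(pmf[: k + 1].sum())

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            bt.poisson_binomial_cdf([0.5], 2)


class TestSelectTopNode:
    def test_single_edit_clade(self):
        net = bt.build_edit_network({"a": {"x"}, "b": {"x"}})
        assert bt.select_top_node({"x"}, net) == "x"

    def test_ancestral_edit_wins(self):
        # root edit expressed everywhere; subtree edits only below
        barcodes, _ = unique_edit_tree(2)
        del barcodes["R"]
        net = bt.build_edit_network(barcodes)
        # edits of node R0 (generation 1) are expressed by R0, R00, R01
        clade = barcodes["R00"] | barcodes["R01"]
        top = bt.select_top_node(clade, net)
        assert top in barcodes["R0"]  # a generation-1 edit

    def test_observed_degree_feeds_cdf(self):
        # candidate with all potential connections realised scores exactly 1
        barcodes = {f"n{i}": {"top", f"leaf{i}"} for i in range(4)}
        net = bt.build_edit_network(barcodes)
        assert bt.select_top_node(set(net.edits), net) == "top"


class TestReconstructTree:
    def test_noiseless_two_generations_exact(self):
        barcodes, truth = unique_edit_tree(2)
        tree = bt.reconstruct_tree(barcodes)
        recon = bt.derive_sample_tree(tree, barcodes)
        acc = bt.placement_accuracy(recon, truth)
        assert acc.accuracy == 1.0

    @pytest.mark.parametrize("depth", [3, 4, 5])
    def test_noiseless_deep_trees_exact(self, depth):
        barcodes, truth = unique_edit_tree(depth)
        tree = bt.reconstruct_tree(barcodes)
        recon = bt.derive_sample_tree(tree, barcodes)
        assert bt.placement_accuracy(recon, truth).accuracy == 1.0

    def test_misassignment_by_chance_overlap(self):
        # a daughter that stole most of the wrong mother's novel edits is
        # placed under the wrong mother (documented failure mode)
        barcodes, truth = unique_edit_tree(2, edits_per_division=4)
        wrong_mom, true_mom = "R1", "R0"
        victim = "R00"
        own_novel = sorted(barcodes[victim] - barcodes[true_mom])
        # the victim's sequenced barcode ends up dominated by the wrong
        # mother's edits plus one genuine own edit
        barcodes[victim] = barcodes[wrong_mom] | {own_novel[0]}
        tree = bt.reconstruct_tree(barcodes)
        recon = bt.derive_sample_tree(tree, barcodes)
        assert truth.parent[victim] == true_mom
        assert recon.parent[victim] == wrong_mom
        # ... while an unperturbed sibling stays put
        assert recon.parent["R01"] == true_mom

    def test_input_order_invariance(self):
        barcodes, _ = unique_edit_tree(3)
        items = list(barcodes.items())
        t1 = bt.reconstruct_tree(dict(items))
        t2 = bt.reconstruct_tree(dict(reversed(items)))
        assert t1.sample_parent == t2.sample_parent
        assert t1.parent == t2.parent

    def test_empty_network_degenerate(self):
        barcodes = {"a": frozenset(), "b": frozenset()}
        tree = bt.reconstruct_tree(barcodes)
        assert tree.roots == []
        assert tree.root_sample in {"a", "b"}

    def test_too_few_barcodes(self):
        with pytest.raises(ValueError):
            bt.reconstruct_tree({"a": {"e"}})

    def test_noise_degrades_accuracy_monotonically(self):
        # swapping barcode content between random node pairs lowers mean
        # placement accuracy (paired seeds)
        def noisy_accuracy(n_swaps, seed):
            barcodes, truth = unique_edit_tree(4, edits_per_division=2)
            rng = np.random.default_rng(seed)
            nodes = [n for n in barcodes if n != "R"]
            for _ in range(n_swaps):
                a, b = rng.choice(nodes, size=2, replace=False)
                ea = sorted(barcodes[a])
                eb = sorted(barcodes[b])
                if not ea or not eb:
                    continue
                barcodes[a] = (barcodes[a] - {ea[0]}) | {eb[0]}
            tree = bt.reconstruct_tree(barcodes)
            recon = bt.derive_sample_tree(tree, barcodes)
            return bt.placement_accuracy(recon, truth).accuracy

        seeds = range(25)
        clean = np.mean([noisy_accuracy(0, s) for s in seeds])
        light = np.mean([noisy_accuracy(3, s) for s in seeds])
        heavy = np.mean([noisy_accuracy(12, s) for s in seeds])
        assert clean >= light >= heavy
        assert clean > heavy


class TestPlacementAccuracy:
    def test_identical_trees(self):
        _, truth = unique_edit_tree(3)
        assert bt.placement_accuracy(truth, truth).accuracy == 1.0

    def test_thirty_five_of_thirty_six(self):
        parent = {"n0": None}
        for i in range(1, 36):
            parent[f"n{i}"] = f"n{i - 1}"
        truth = bt.SampleTree(parent=parent)
        moved = dict(parent)
        moved["n35"] = "n33"  # one node placed at the wrong depth
        acc = bt.placement_accuracy(bt.SampleTree(parent=moved), truth)
        assert acc.correct == 35 and acc.total == 36
        assert acc.accuracy == pytest.approx(0.972, abs=5e-4)

    def test_star_versus_chain(self):
        chain = {"a": None, "b": "a", "c": "b", "d": "c"}
        star = {"a": None, "b": "a", "c": "a", "d": "a"}
        acc = bt.placement_accuracy(
            bt.SampleTree(parent=star), bt.SampleTree(parent=chain)
        )
        # only the root and its true first child survive
        assert acc.correct == 2

    def test_sample_mismatch(self):
        with pytest.raises(ValueError):
            bt.placement_accuracy(
                bt.SampleTree(parent={"a": None}),
                bt.SampleTree(parent={"b": None}),
            )
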