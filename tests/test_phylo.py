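"""Distances, neighbor joining and branch placement."""

import itertools
import math

import numpy as np
import pytest

from c5nscreen.phylo import (
    BranchAssignment,
    DistanceMatrix,
    PanelEntry,
    ReferencePanel,
    assign_branch,
    distance_matrix,
    nj_tree,
    pairwise_distance,
)
from c5nscreen.synthetic import SynthesisConfig, amplicon_region, synth_alas_gene


class TestPairwiseDistance:
    def test_identical_fragments(self):
        assert pairwise_distance("ACGT", "ACGT") == 0.0

    def test_p_distance_counts_mismatches(self):
        assert pairwise_distance("AAAA", "AAAT") == 0.25

    def test_gap_and_n_columns_excluded(self):
        assert pairwise_distance("AC-GN", "ACTGA") == 0.0
        with pytest.raises(ValueError):
            pairwise_distance("---", "ACG")

    def test_jc69_closed_form_at_quarter(self):
        d = pairwise_distance("AAAA", "AAAT", model="jc69")
        assert d == pytest.approx(-0.75 * math.log(1 - 1 / 3), abs=1e-9)
        assert d == pytest.approx(0.304099, abs=1e-6)

    def test_jc69_saturates(self):
        with pytest.raises(ValueError):
            pairwise_distance("AAAA", "TTTT", model="jc69")

    @pytest.mark.parametrize("seed", range(4))
    def test_axioms_and_jc_exceeds_p(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), 60))
        b = "".join(rng.choice(list("ACGT"), 60))
        p = pairwise_distance(a, b)
        assert p == pairwise_distance(b, a)
        assert pairwise_distance(a, a) == 0.0
        if 0 < p < 0.75:
            assert pairwise_distance(a, b, "jc69") > p


# --- exhaustive-topology oracle -------------------------------------------

def all_unrooted_topologies(taxa):
    """Enumerate unrooted binary topologies as frozensets of splits."""
    if len(taxa) == 3:
        yield []
        return
    # represent a tree as a list of edges between node ids; build by taxon insertion
    def build(tree_edges, next_node, remaining):
        if not remaining:
            yield list(tree_edges)
            return
        taxon = remaining[0]
        for idx in range(len(tree_edges)):
            u, v = tree_edges[idx]
            new = tree_edges[:idx] + tree_edges[idx + 1 :]
            internal = next_node
            new += [(u, internal), (internal, v), (internal, taxon)]
            yield from build(new, next_node + 1, remaining[1:])

    # start from the star on the first three taxa and insert the rest
    seed_edges = [("root", taxa[0]), ("root", taxa[1]), ("root", taxa[2])]
    yield from build(seed_edges, 0, list(taxa[3:]))


def splits_of_edge_list(edges, taxa):
    import networkx as nx

    g = nx.Graph(edges)
    splits = set()
    for u, v in g.edges():
        h = g.copy()
        h.remove_edge(u, v)
        side = {t for t in taxa if t in nx.node_connected_component(h, u)}
        if 2 <= len(side) <= len(taxa) - 2:
            splits.add(frozenset(side) if min(side) <= min(set(taxa) - side) else frozenset(set(taxa) - side))
    return frozenset(splits)


def ls_residual(edges, taxa, dm):
    """Least-squares branch-length fit of a topology to a distance matrix."""
    import networkx as nx

    g = nx.Graph()
    for i, e in enumerate(edges):
        g.add_edge(*e, idx=i)
    pairs = list(itertools.combinations(taxa, 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    idx = {t: i for i, t in enumerate(dm.ids)}
    for r, (a, b) in enumerate(pairs):
        path = nx.shortest_path(g, a, b)
        for u, v in zip(path, path[1:]):
            A[r, g[u][v]["idx"]] = 1.0
        y[r] = dm.values[idx[a], idx[b]]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((A @ x - y) ** 2))


def tree_splits(tree, taxa):
    splits = set()
    names = set(taxa)
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if 2 <= len(side) <= len(names) - 2:
            comp = names - side
            splits.add(frozenset(side) if min(side) <= min(comp) else frozenset(comp))
    return frozenset(splits)


def random_additive_matrix(taxa, rng):
    """Distances from a random binary tree with positive branch lengths."""
    topologies = list(all_unrooted_topologies(taxa))
    edges = topologies[rng.integers(len(topologies))]
    import networkx as nx

    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, weight=float(rng.uniform(0.05, 0.5)))
    n = len(taxa)
    vals = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                d = nx.shortest_path_length(g, a, b, weight="weight")
                vals[i, j] = vals[j, i] = d
    return DistanceMatrix(tuple(taxa), vals), splits_of_edge_list(edges, taxa)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(("a", "b", "c"), np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]))
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    @pytest.mark.parametrize("n_taxa, seed", [(5, 0), (5, 1), (5, 2), (6, 3), (6, 4)])
    def test_recovers_additive_topology_against_exhaustive_search(self, n_taxa, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(n_taxa)]
        dm, true_splits = random_additive_matrix(taxa, rng)
        # oracle: the generating topology is the unique least-squares optimum
        best = min(all_unrooted_topologies(taxa), key=lambda e: ls_residual(e, taxa, dm))
        assert splits_of_edge_list(best, taxa) == true_splits
        assert tree_splits(nj_tree(dm), taxa) == true_splits

    def test_equidistant_matrix_gives_zero_internal_edges(self):
        n = 5
        vals = np.full((n, n), 0.8)
        np.fill_diagonal(vals, 0.0)
        dm = DistanceMatrix(tuple(f"t{i}" for i in range(n)), vals)
        tree = nj_tree(dm)
        for node in tree.non_tips(include_self=False):
            assert node.length == pytest.approx(0.0, abs=1e-12)

    def test_negative_lengths_clamped_with_deficit_on_sister(self):
        # non-additive matrix known to produce a negative NJ limb
        vals = np.array(
            [[0, 0.1, 0.6, 0.6], [0.1, 0, 0.2, 0.6], [0.6, 0.2, 0, 0.1], [0.6, 0.6, 0.1, 0]]
        )
        tree = nj_tree(DistanceMatrix(("a", "b", "c", "d"), vals))
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0.0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]])))


class TestPanel:
    def test_packaged_synthetic_panel_is_valid(self, ref_panel):
        assert ref_panel.fragment_length == 519
        labels = {e.branch_label for e in ref_panel.entries}
        assert {"manumycin", "moenomycin_I", "orange", "blue_I", "blue_II"} <= labels

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            ReferencePanel((PanelEntry("a", "ACGT", "orange"), PanelEntry("b", "ACG", "orange")))

    def test_single_entry_branches_rejected(self):
        with pytest.raises(ValueError):
            ReferencePanel((PanelEntry("a", "ACGT", "orange"),))


class TestAssignBranch:
    def test_identical_to_reference_is_certain(self, ref_panel):
        ref = next(e for e in ref_panel.entries if e.branch_label == "colabomycin")
        out = assign_branch("q", ref.fragment, ref_panel, k=1, seed=1)
        assert out.branch_label == "colabomycin"
        assert out.mean_distance == 0.0
        assert out.support == 1.0
        # default k: still the right branch with full support
        out3 = assign_branch("q", ref.fragment, ref_panel, seed=1)
        assert out3.branch_label == "colabomycin" and out3.support == 1.0

    def test_vote_tie_breaks_toward_smaller_mean_distance(self):
        entries = (
            PanelEntry("a1", "AAAAAAAA", "orange"),
            PanelEntry("a2", "AAAAAAAT", "orange"),
            PanelEntry("b1", "AAAATTTT", "brown"),
            PanelEntry("b2", "AAAATTTA", "brown"),
        )
        panel = ReferencePanel(entries)
        # k=2 nearest: b2 at 0.125 and (tie a1/b1 at 0.25 -> a1 by index);
        # one vote each, brown's vote is closer
        out = assign_branch("q", "AAAATTAA", panel, k=2, bootstrap_B=0, seed=0)
        assert out.branch_label == "brown"
        assert out.mean_distance == pytest.approx((0.125 + 0.25) / 2)

    def test_full_tie_breaks_lexicographically(self):
        entries = (
            PanelEntry("a1", "AAAACCCC", "orange"),
            PanelEntry("a2", "CCCCAAAA", "orange"),
            PanelEntry("b1", "AAAACCCC", "brown"),
            PanelEntry("b2", "CCCCAAAA", "brown"),
        )
        panel = ReferencePanel(entries)
        out = assign_branch("q", "AAAACCCC", panel, k=2, bootstrap_B=0, seed=0)
        assert out.branch_label == "brown"  # identical votes and means; 'brown' < 'orange'

    def test_bootstrap_support_is_deterministic_under_seed(self, ref_panel):
        rec = synth_alas_gene("cALAS_green", SynthesisConfig(seed=8, mutation_rate=0.05))
        frag = amplicon_region(rec.cds)
        a = assign_branch("q", frag, ref_panel, seed=123)
        b = assign_branch("q", frag, ref_panel, seed=123)
        assert (a.branch_label, a.support) == (b.branch_label, b.support)

    def test_cohort_recovery_at_low_mutation(self, ref_panel):
        cfg = SynthesisConfig(seed=5, mutation_rate=0.02)
        hits = total = 0
        for cl in ("cALAS_purple", "cALAS_green", "cALAS_other"):
            for i in range(15):
                rec = synth_alas_gene(cl, cfg, index=i)
                out = assign_branch(rec.strain_id, amplicon_region(rec.cds), ref_panel, seed=3)
                hits += out.branch_label == rec.truth.true_branch
                total += 1
        assert hits / total >= 0.95

    def test_support_degrades_with_mutation_load(self, ref_panel):
        means = []
        for rate in (0.0, 0.05, 0.15):
            cfg = SynthesisConfig(seed=6, mutation_rate=rate)
            sups = []
            for i in range(50):
                rec = synth_alas_gene("cALAS_purple", cfg, index=i)
                sups.append(assign_branch("q", amplicon_region(rec.cds), ref_panel, seed=4).support)
            means.append(float(np.mean(sups)))
        assert means[0] >= means[1] >= means[2]

    def test_invalid_support_rejected(self):
        with pytest.raises(ValueError):
            BranchAssignment("q", "orange", 0.1, 1.5)


class TestDistanceMatrixType:
    def test_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_from_fragments(self):
        dm = distance_matrix(("a", "b", "c"), ("AAAA", "AAAT", "TTTT"))
        assert dm.values[0, 1] == 0.25
        assert dm.values[0, 2] == 1.0
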