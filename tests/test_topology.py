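import collections
import io

import numpy as np
import pytest

from mosaicscan import topology as topo
from mosaicscan import windows_stats as ws
from mosaicscan.errors import ValidationError
from mosaicscan.synthetic_data import SimulationConfig, simulate_genome, group_map_for

import oracles


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def dendropy_nj_topology(dist, labels):
    """Oracle: dendropy's neighbor joining, returned as a set of
    non-trivial bipartitions (frozensets of labels)."""
    import dendropy

    csv = "," + ",".join(labels) + "\n"
    csv += "\n".join(
        labels[i] + "," + ",".join(repr(float(x)) for x in dist[i])
        for i in range(len(labels))
    )
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(io.StringIO(csv))
    tree = pdm.nj_tree()
    out = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        tips = frozenset(l.taxon.label for l in edge.head_node.leaf_iter())
        if 1 < len(tips) < len(labels) - 1:
            out.add(_canon(tips, labels))
    return out


def _canon(side, labels):
    """Canonical form of an unrooted bipartition: the side without the
    first label."""
    if labels[0] in side:
        return frozenset(labels) - side
    return frozenset(side)


def bipartitions_of(root, labels):
    out = set()
    n_tips = len(labels)

    def rec(node):
        if node.is_leaf():
            return frozenset([node.label])
        tips = frozenset()
        for c in node.children:
            tips |= rec(c)
        if node is not root and 1 < len(tips) < n_tips - 1:
            out.add(_canon(tips, labels))
        return tips

    rec(root)
    return out


class TestNeighborJoining:
    def test_additive_p1_p3_clustering(self):
        # distances from a tree where P1 and P3 are sisters
        labels = ["p1", "p2", "p3", "out"]
        d = np.array(
            [
                [0.0, 0.6, 0.2, 1.0],
                [0.6, 0.0, 0.6, 1.0],
                [0.2, 0.6, 0.0, 1.0],
                [1.0, 1.0, 1.0, 0.0],
            ]
        )
        root = topo.neighbor_joining(d, labels)
        assert frozenset(["p2", "out"]) in bipartitions_of(root, labels)
        assert "p1" in root.to_newick() and root.to_newick().endswith(";")

    def test_matches_dendropy_on_random_distances(self, rng):
        for _ in range(15):
            n = int(rng.integers(5, 11))
            pts = rng.random((n, 4))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            labels = [f"t{i}" for i in range(n)]
            mine = bipartitions_of(topo.neighbor_joining(d, labels), labels)
            oracle = dendropy_nj_topology(d, labels)
            assert mine == oracle

    def test_too_few_tips(self):
        with pytest.raises(ValidationError):
            topo.neighbor_joining(np.zeros((1, 1)), ["a"])


# ---------------------------------------------------------------------------
# Window trees
# ---------------------------------------------------------------------------


class TestWindowTrees:
    def test_trailing_partial_window_skipped(self, rng, ten_sample_groups):
        gm = oracles.random_genotype_matrix(rng, 10, 120, miss=0)
        trees = topo.window_trees(gm, ten_sample_groups, snps_per_window=50, seed=0)
        assert len(trees) == 2  # 120 SNPs -> 2 full windows, 20 left over

    def test_star_flag_on_identical_haplotypes(self, rng, ten_sample_groups):
        gm = oracles.random_genotype_matrix(rng, 10, 50, miss=0)
        gm.genotypes[:] = 0
        gm.outgroup[:] = 0
        trees = topo.window_trees(gm, ten_sample_groups, snps_per_window=50, seed=0)
        assert len(trees) == 1 and trees[0].star
        w = topo.topology_weights(trees[0])
        assert w.as_tuple() == pytest.approx((1 / 3, 1 / 3, 1 / 3))
        assert w.majority == "unresolved"

    def test_deterministic_under_seed(self, rng, ten_sample_groups):
        gm = oracles.random_genotype_matrix(rng, 10, 100, miss=0.05)
        t1 = topo.window_trees(gm, ten_sample_groups, seed=5)
        t2 = topo.window_trees(gm, ten_sample_groups, seed=5)
        assert [t.newick for t in t1] == [t.newick for t in t2]

    def test_pseudo_haplotypes_preserve_allele_counts(self, rng, ten_sample_groups):
        gm = oracles.random_genotype_matrix(rng, 10, 50, miss=0.1)
        H, names, tip_groups = topo.pseudo_haplotypes(gm, ten_sample_groups, seed=3)
        for i, s in enumerate(gm.samples):
            h = H[2 * i : 2 * i + 2]
            g = gm.genotypes[i]
            called = g >= 0
            assert np.array_equal(h[:, called].sum(axis=0), g[called])
            assert np.all(h[:, ~called] == -1)


# ---------------------------------------------------------------------------
# Topology weighting
# ---------------------------------------------------------------------------


def weights_from_newick(newick, tip_groups):
    root = topo.tree_from_newick(newick)
    return topo.topology_weights(root, tip_groups=tip_groups)


class TestTopologyWeights:
    def test_one_tip_per_group_unit_weight(self):
        w = weights_from_newick(
            "((p1:1,p3:1):1,(p2:1,out:1):1);",
            {"p1": "P1", "p2": "P2", "p3": "P3", "out": "OUT"},
        )
        assert w.as_tuple() == (0.0, 1.0, 0.0)
        assert w.majority == "topo2"

    def test_two_focal_tips_split(self):
        # one focal tip sister to P1 (topo2 vote), one sister to P2 (topo3)
        w = weights_from_newick(
            "(((p1:1,c1:1):1,(p2:1,c2:1):1):1,out:1);",
            {"p1": "P1", "p2": "P2", "c1": "P3", "c2": "P3", "out": "OUT"},
        )
        assert w.as_tuple() == (0.0, 0.5, 0.5)
        assert w.majority == "unresolved"

    def test_weights_sum_to_one_random_trees(self, rng, ten_sample_groups):
        gm = oracles.random_genotype_matrix(rng, 10, 100, miss=0)
        for t in topo.window_trees(gm, ten_sample_groups, seed=1):
            w = topo.topology_weights(t)
            assert sum(w.as_tuple()) == pytest.approx(1.0, abs=1e-9)

    def test_exact_matches_subsampling_estimate(self, rng, ten_sample_groups):
        """Exact enumeration vs 10,000 random one-tip-per-group draws."""
        gm = oracles.random_genotype_matrix(rng, 10, 50, miss=0)
        trees = topo.window_trees(gm, ten_sample_groups, snps_per_window=50, seed=2)
        t = trees[0]
        exact = topo.topology_weights(t).as_tuple()
        by_group = collections.defaultdict(list)
        for tip, g in t.tip_groups.items():
            by_group[g].append(tip)
        draws = np.zeros(3)
        n = 10_000
        for _ in range(n):
            combo = {g: by_group[g][rng.integers(len(by_group[g]))] for g in by_group}
            sub = topo.topology_weights(
                t.root,
                tip_groups={combo[g]: g for g in combo},
            )
            draws += np.array(sub.as_tuple())
        est = draws / n
        for e, x in zip(est, exact):
            se = max(np.sqrt(x * (1 - x) / n), 1e-4)
            assert abs(e - x) <= 4 * se


class TestMajority:
    def test_above_threshold(self):
        assert topo.majority_topology(topo.TopologyWeights(0.70, 0.20, 0.10)) == "topo1"

    def test_below_threshold_unresolved(self):
        assert (
            topo.majority_topology(topo.TopologyWeights(0.60, 0.30, 0.10))
            == "unresolved"
        )

    def test_boundary_two_thirds_resolves(self):
        w = topo.TopologyWeights(2 / 3, 1 / 6, 1 / 6)
        assert topo.majority_topology(w) == "topo1"


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def seg(chrom, start, end, label):
    return topo.TopologySegment(chrom, start, end, label, support=1.0)


class TestCollapse:
    def test_merge_definition(self):
        out = topo.collapse_adjacent(
            [seg("c", 0, 10, "topo2"), seg("c", 10, 20, "topo2"), seg("c", 20, 30, "topo3")]
        )
        assert [(s.start, s.end, s.label) for s in out] == [
            (0, 20, "topo2"),
            (20, 30, "topo3"),
        ]
        assert out[0].support == 2.0

    def test_alternating_unchanged(self):
        segs = [seg("c", i * 10, i * 10 + 10, l) for i, l in enumerate("ababab")]
        assert len(topo.collapse_adjacent(segs)) == 6

    def test_matches_rle_oracle(self, rng):
        labels = [str(rng.integers(0, 3)) for _ in range(50)]
        segs = [seg("c", i * 10, i * 10 + 10, l) for i, l in enumerate(labels)]
        out = topo.collapse_adjacent(segs)
        assert [(s.label, (s.end - s.start) // 10) for s in out] == oracles.rle_labels(
            labels
        )

    def test_overlap_rejected(self):
        with pytest.raises(ValidationError):
            topo.collapse_adjacent([seg("c", 0, 10, "a"), seg("c", 5, 15, "a")])

    def test_chromosomes_not_merged(self):
        out = topo.collapse_adjacent([seg("c1", 0, 10, "a"), seg("c2", 0, 10, "a")])
        assert len(out) == 2


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


class TestBootstrap:
    def test_degenerate_all_one_label(self):
        wins = [("c", i * 1000, i * 1000 + 1000, "topo2") for i in range(50)]
        props = topo.genome_proportions_bootstrap(wins, block=10_000, reps=200, seed=0)
        assert props["topo2"]["estimate"] == pytest.approx(100.0)
        assert props["topo2"]["lo"] == pytest.approx(100.0)
        assert props["topo2"]["hi"] == pytest.approx(100.0)

    def test_half_half_matches_binomial_interval(self):
        wins = [
            ("c", i * 10_000, i * 10_000 + 10_000, "topo2" if i % 2 == 0 else "topo3")
            for i in range(200)
        ]
        props = topo.genome_proportions_bootstrap(wins, block=20_000, reps=5_000, seed=1)
        # every 20kb block is exactly half topo2 -> no between-block variance
        assert props["topo2"]["estimate"] == pytest.approx(50.0)
        assert props["topo2"]["hi"] - props["topo2"]["lo"] < 1.0
        # block = one window -> binomial variation over 200 blocks
        props2 = topo.genome_proportions_bootstrap(wins, block=10_000, reps=5_000, seed=1)
        p, n = 0.5, 200
        halfwidth = 1.96 * 100 * np.sqrt(p * (1 - p) / n)
        got_half = (props2["topo2"]["hi"] - props2["topo2"]["lo"]) / 2
        assert got_half == pytest.approx(halfwidth, rel=0.25)

    def test_seed_reproducibility(self):
        wins = [
            ("c", i * 1000, i * 1000 + 1000, ["topo1", "topo2", "unresolved"][i % 3])
            for i in range(60)
        ]
        a = topo.genome_proportions_bootstrap(wins, block=5000, reps=500, seed=9)
        b = topo.genome_proportions_bootstrap(wins, block=5000, reps=500, seed=9)
        assert a == b

    def test_labels_sum_to_100(self):
        wins = [
            ("c", i * 1000, i * 1000 + 1000, ["topo1", "topo2", "topo3", "unresolved"][i % 4])
            for i in range(40)
        ]
        props = topo.genome_proportions_bootstrap(wins, block=4000, reps=100, seed=0)
        assert sum(v["estimate"] for v in props.values()) == pytest.approx(100.0, abs=1e-9)

    def test_zero_blocks_error(self):
        with pytest.raises(ValidationError):
            topo.genome_proportions_bootstrap([], reps=10, seed=0)


# ---------------------------------------------------------------------------
# Per-topology divergence
# ---------------------------------------------------------------------------


class TestDxyByTopology:
    def test_empty_input(self, rng, ten_sample_groups):
        gm = oracles.random_genotype_matrix(rng, 10, 10)
        out = topo.dxy_by_topology(gm, ten_sample_groups, [], [], purity=1.0)
        assert out == {"topo1": [], "topo2": [], "topo3": []}

    def test_single_pure_segment_reduces_to_plain_dxy(self, rng, ten_sample_groups):
        gm = oracles.random_genotype_matrix(rng, 10, 100, miss=0)
        trees = topo.window_trees(gm, ten_sample_groups, seed=0)
        weights = [topo.TopologyWeights(0.0, 1.0, 0.0, "topo2") for _ in trees]
        out = topo.dxy_by_topology(gm, ten_sample_groups, trees, weights, purity=1.0)
        assert len(out["topo2"]) == 1  # collapsed into one segment
        segref, val = out["topo2"][0]
        plain = ws.dxy(
            gm, ten_sample_groups, ws.Window(segref.chrom, segref.start, segref.end),
            "P3", "P1",
        )
        assert val == pytest.approx(plain)

    def test_bad_purity(self, rng, ten_sample_groups):
        gm = oracles.random_genotype_matrix(rng, 10, 10)
        with pytest.raises(ValidationError):
            topo.dxy_by_topology(gm, ten_sample_groups, [], [], purity=0.5)

    def test_younger_donor_tracts_have_lower_dxy(self):
        """Recent P1-donor tracts (topo2) must show lower arc-sister D_XY
        than older topo3 tracts."""
        cfg = SimulationConfig(
            chrom_lengths={"chr1": 1_500_000},
            join_high=6e-3,
            class_props={"topo1": 0.0, "topo2": 0.5, "topo3": 0.5, "mixed": 0.0},
            join_low={"topo1": 2e-3, "topo2": 1e-3, "topo3": 3e-3},
            tract_mean_len=30_000,
            n_genes=20,
            seed=42,
        )
        gm, _ = simulate_genome(cfg)
        groups = group_map_for(cfg)
        trees = topo.window_trees(gm, groups, seed=0)
        weights = [topo.topology_weights(t) for t in trees]
        out = topo.dxy_by_topology(gm, groups, trees, weights, purity=1.0)
        assert len(out["topo2"]) > 3 and len(out["topo3"]) > 3

        def wmean(pairs):
            spans = np.array([s.end - s.start for s, _ in pairs], dtype=float)
            vals = np.array([v for _, v in pairs])
            return (spans * vals).sum() / spans.sum()

        assert wmean(out["topo2"]) < wmean(out["topo3"])
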