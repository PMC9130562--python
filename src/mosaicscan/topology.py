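"""Window trees, exact topology weighting, segmentation, and block
bootstrap of genome-wide topology proportions.

Diploid genotypes are split into two pseudo-haplotypes per sample (the
allele order at heterozygous sites is a seeded per-sample-per-site
draw). Neighbor-joining trees are built for non-overlapping blocks of
SNPs, and each tree is weighted by exact enumeration over every
combination of one tip per group: rooting the induced quartet on the
outgroup tip, the combination votes for one of the three rooted species
topologies:

* ``topo1``: (P3, (P2, P1)) - focal group basal
* ``topo2``: (P2, (P3, P1)) - focal group sister to P1
* ``topo3``: ((P3, P2), P1) - focal group sister to P2
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from mosaicscan.errors import ValidationError
from mosaicscan.genomic_io import GenotypeMatrix, GroupMap

TOPO_LABELS = ("topo1", "topo2", "topo3")
UNRESOLVED = "unresolved"


# ---------------------------------------------------------------------------
# Minimal tree structure + neighbor joining
# ---------------------------------------------------------------------------


class TreeNode:
    """A rooted-representation tree node (the root may trifurcate, making
    the tree effectively unrooted)."""

    __slots__ = ("label", "length", "children", "sort_key")

    def __init__(self, label=None, length=0.0, children=None):
        self.label = label
        self.length = length
        self.children = children or []
        self.sort_key = label if label is not None else ""

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf():
            return f"{self.label}:{self.length:.6g}"
        inner = ",".join(c._nwk() for c in self.children)
        return f"({inner}):{self.length:.6g}"


_TRIU: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _triu_cache(m: int) -> tuple[np.ndarray, np.ndarray]:
    if m not in _TRIU:
        _TRIU[m] = np.triu_indices(m, k=1)
    return _TRIU[m]


def neighbor_joining(dist: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Textbook neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of cluster keys (a cluster's key is its smallest tip label).
    """
    n = len(labels)
    if n != dist.shape[0] or dist.shape[0] != dist.shape[1]:
        raise ValidationError("distance matrix / label mismatch")
    if n < 2:
        raise ValidationError("need >= 2 tips")
    nodes = [TreeNode(label=l) for l in labels]
    D = np.zeros((2 * n, 2 * n))
    D[:n, :n] = dist.astype(float)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        act = np.asarray(active)
        sub = D[np.ix_(act, act)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        iu = _triu_cache(m)
        qvals = Q[iu]
        qmin = qvals.min()
        best = None
        for flat in np.nonzero(qvals == qmin)[0]:
            ai, bi = int(iu[0][flat]), int(iu[1][flat])
            ka = nodes[active[ai]].sort_key
            kb = nodes[active[bi]].sort_key
            key = (min(ka, kb), max(ka, kb))
            if best is None or key < best[0]:
                best = (key, ai, bi)
        _, ai, bi = best
        i, j = active[ai], active[bi]
        m2 = m - 2
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[ai] - r[bi]) / (2 * m2) if m2 > 0 else 0.5 * d_ij
        li = min(max(li, 0.0), d_ij)
        lj = d_ij - li
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = li, lj
        parent = TreeNode(children=[ni, nj])
        parent.sort_key = min(ni.sort_key, nj.sort_key)
        nodes.append(parent)
        k = len(nodes) - 1
        rest = np.asarray([x for x in active if x not in (i, j)])
        D[k, rest] = D[rest, k] = 0.5 * (D[i, rest] + D[j, rest] - d_ij)
        active = list(rest) + [k]

    rest = [nodes[i] for i in active]
    if len(active) == 3:
        i, j, k = active
        a, b, c = D[i, j], D[i, k], D[j, k]
        rest[0].length = max(0.0, (a + b - c) / 2)
        rest[1].length = max(0.0, (a + c - b) / 2)
        rest[2].length = max(0.0, (b + c - a) / 2)
    elif len(active) == 2:
        i, j = active
        rest[0].length = rest[1].length = D[i, j] / 2
    root = TreeNode(children=sorted(rest, key=lambda nd: nd.sort_key))
    root.sort_key = root.children[0].sort_key
    return root


def tree_from_newick(newick: str) -> TreeNode:
    """Parse a Newick string into a :class:`TreeNode` (via dendropy)."""
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick")

    def conv(nd) -> TreeNode:
        node = TreeNode(
            label=nd.taxon.label.replace(" ", "_") if nd.taxon else None,
            length=nd.edge.length or 0.0,
            children=[conv(c) for c in nd.child_nodes()],
        )
        return node

    return conv(t.seed_node)


# ---------------------------------------------------------------------------
# Pseudo-haplotypes and window trees
# ---------------------------------------------------------------------------


OUTGROUP_TIP = "outgroup"


def pseudo_haplotypes(
    gm: GenotypeMatrix, groups: GroupMap, seed: int
) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Split diploids into two pseudo-haplotypes each, plus the outgroup.

    Returns ``(H, tip_names, tip_groups)`` where H is (n_tips, n_sites)
    with values 0/1/-1. Heterozygous sites distribute their two alleles
    across the pair of haplotypes in a seeded random order.
    """
    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=gm.genotypes.shape, dtype=np.int8)
    rows = []
    names = []
    tip_groups = {}
    for i, sample in enumerate(gm.samples):
        g = gm.genotypes[i]
        h1 = np.where(g == 2, 1, 0).astype(np.int8)
        h2 = h1.copy()
        het = g == 1
        h1[het] = flips[i, het]
        h2[het] = 1 - flips[i, het]
        miss = g < 0
        h1[miss] = -1
        h2[miss] = -1
        for h, suffix in ((h1, "_1"), (h2, "_2")):
            rows.append(h)
            names.append(sample + suffix)
            tip_groups[sample + suffix] = groups.group_of(sample)
    rows.append(gm.outgroup.astype(np.int8))
    names.append(OUTGROUP_TIP)
    tip_groups[OUTGROUP_TIP] = "OUT"
    return np.vstack(rows), names, tip_groups


@dataclass
class WindowTree:
    chrom: str
    start: int  # genomic span of the SNP block, 0-based half-open
    end: int
    snp_span: tuple[int, int]  # site index range into the matrix
    root: TreeNode
    newick: str
    tip_groups: dict[str, str]
    star: bool = False


def _pairwise_pdist(H: np.ndarray) -> np.ndarray:
    """Proportion of differing SNPs among sites called in both tips.

    Pairs with no shared called site get distance 1.0.
    """
    called = H >= 0
    vals = np.where(called, H, 0).astype(np.int16)
    both = called.astype(np.int16) @ called.astype(np.int16).T
    # differing = sum over shared sites of |a-b| (alleles are 0/1)
    same11 = vals @ vals.T
    ca = (vals * called).sum(axis=1)
    # diff_ij = sum_k called_ik*called_jk*|a_ik - a_jk|
    diff = (vals @ called.astype(np.int16).T) + (called.astype(np.int16) @ vals.T) - 2 * same11
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(both > 0, diff / np.maximum(both, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def window_trees(
    gm: GenotypeMatrix,
    groups: GroupMap,
    snps_per_window: int = 50,
    seed: int = 0,
    step: int | None = None,
) -> list[WindowTree]:
    """Neighbor-joining trees for blocks of ``snps_per_window`` SNPs.

    Blocks are non-overlapping by default (``step`` defaults to the
    window size), never span chromosomes, and a trailing partial block is
    skipped. Windows where fewer than four tips (or any group's last
    tip) have data are skipped; all-identical windows yield a star flag.
    """
    groups.require_nonempty(("P1", "P2", "P3"))
    if step is None:
        step = snps_per_window
    if snps_per_window < 1 or step < 1:
        raise ValidationError("snps_per_window and step must be >= 1")
    H, names, tip_groups = pseudo_haplotypes(gm, groups, seed)
    out = []
    for chrom in gm.chromosomes():
        (cidx,) = np.nonzero(gm.chrom == chrom)
        k = 0
        while k + snps_per_window <= len(cidx):
            block = cidx[k : k + snps_per_window]
            k += step
            Hb = H[:, block]
            usable = (Hb >= 0).any(axis=1)
            keep_groups = {tip_groups[names[i]] for i in np.nonzero(usable)[0]}
            if usable.sum() < 4 or not {"P1", "P2", "P3", "OUT"} <= keep_groups:
                continue
            tips = np.nonzero(usable)[0]
            D = _pairwise_pdist(Hb[tips])
            labels = [names[i] for i in tips]
            star = bool(np.allclose(D, 0.0))
            root = neighbor_joining(D, labels)
            out.append(
                WindowTree(
                    chrom=chrom,
                    start=int(gm.pos[block[0]] - 1),
                    end=int(gm.pos[block[-1]]),
                    snp_span=(int(block[0]), int(block[-1]) + 1),
                    root=root,
                    newick=root.to_newick(),
                    tip_groups={l: tip_groups[l] for l in labels},
                    star=star,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Topology weighting
# ---------------------------------------------------------------------------


@dataclass
class TopologyWeights:
    w1: float
    w2: float
    w3: float
    majority: str = UNRESOLVED

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w1, self.w2, self.w3)


def _edge_bitmasks(root: TreeNode, tip_index: Mapping[str, int]) -> list[int]:
    """Bitmask of tips below each non-root node (one per edge)."""
    masks = []

    def rec(node: TreeNode) -> int:
        if node.is_leaf():
            m = 1 << tip_index[node.label]
        else:
            m = 0
            for c in node.children:
                m |= rec(c)
        if node is not root:
            masks.append(m)
        return m

    rec(root)
    return masks


def topology_weights(
    tree: WindowTree | TreeNode,
    groups: GroupMap | None = None,
    tip_groups: Mapping[str, str] | None = None,
    threshold: float = 2 / 3,
) -> TopologyWeights:
    """Exact enumeration of one-tip-per-group combinations.

    Each combination's induced quartet, rooted on the outgroup tip,
    votes for topo1/topo2/topo3; unresolved quartets split their vote
    equally. Weights are vote fractions.
    """
    if isinstance(tree, WindowTree):
        root = tree.root
        tg = tree.tip_groups
        star = tree.star
    else:
        root = tree
        star = False
        if tip_groups is not None:
            tg = dict(tip_groups)
        elif groups is not None:
            tg = {}
            for leaf in root.leaves():
                name = leaf.label
                base = name.rsplit("_", 1)[0] if name != OUTGROUP_TIP else name
                tg[name] = "OUT" if name == OUTGROUP_TIP else groups.group_of(base)
        else:
            raise ValidationError("tip-to-group mapping required")

    by_group: dict[str, list[str]] = {g: [] for g in ("P1", "P2", "P3", "OUT")}
    for tip, g in tg.items():
        if g in by_group:
            by_group[g].append(tip)
    for g, tips in by_group.items():
        if not tips:
            raise ValidationError(f"no tip for group {g}")

    leaves = [l.label for l in root.leaves()]
    tip_index = {l: i for i, l in enumerate(leaves)}
    masks = _edge_bitmasks(root, tip_index)
    votes = np.zeros(3)
    n_comb = 0
    for a in by_group["P1"]:
        for b in by_group["P2"]:
            for c in by_group["P3"]:
                for o in by_group["OUT"]:
                    n_comb += 1
                    if star:
                        votes += 1 / 3
                        continue
                    quartet = (
                        (1 << tip_index[a])
                        | (1 << tip_index[b])
                        | (1 << tip_index[c])
                        | (1 << tip_index[o])
                    )
                    pair = None
                    ma = 1 << tip_index[a]
                    mb = 1 << tip_index[b]
                    mc = 1 << tip_index[c]
                    mo = 1 << tip_index[o]
                    for m in masks:
                        sub = m & quartet
                        if bin(sub).count("1") != 2:
                            continue
                        if sub in (ma | mb, mc | mo):
                            pair = 0  # (P1,P2) clade => focal basal
                        elif sub in (ma | mc, mb | mo):
                            pair = 1  # (P1,P3) clade
                        elif sub in (mb | mc, ma | mo):
                            pair = 2  # (P2,P3) clade
                        if pair is not None:
                            break
                    if pair is None:
                        votes += 1 / 3
                    else:
                        votes[pair] += 1
    w = votes / n_comb
    tw = TopologyWeights(w1=float(w[0]), w2=float(w[1]), w3=float(w[2]))
    tw.majority = majority_topology(tw, threshold)
    return tw


def majority_topology(w: TopologyWeights, threshold: float = 2 / 3) -> str:
    """Label of the unique topology with weight >= threshold, else
    'unresolved' (>= convention at the boundary)."""
    weights = w.as_tuple()
    tol = 1e-12
    for lbl, val in zip(TOPO_LABELS, weights):
        if val >= threshold - tol:
            return lbl
    return UNRESOLVED


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


@dataclass
class TopologySegment:
    chrom: str
    start: int
    end: int
    label: str
    support: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"empty segment {self}")


def collapse_adjacent(segments: Sequence[TopologySegment]) -> list[TopologySegment]:
    """Run-length merge of consecutive same-label segments per chromosome."""
    prev_end: dict[str, int] = {}
    out: list[TopologySegment] = []
    for seg in segments:
        if seg.chrom in prev_end and seg.start < prev_end[seg.chrom]:
            raise ValidationError(
                f"overlapping segments at {seg.chrom}:{seg.start}"
            )
        prev_end[seg.chrom] = seg.end
        if out and out[-1].chrom == seg.chrom and out[-1].label == seg.label:
            out[-1] = TopologySegment(
                seg.chrom,
                out[-1].start,
                seg.end,
                seg.label,
                out[-1].support + seg.support,
            )
        else:
            out.append(
                TopologySegment(seg.chrom, seg.start, seg.end, seg.label, seg.support)
            )
    return out


def weights_to_segments(
    trees: Sequence[WindowTree],
    weights: Sequence[TopologyWeights],
    threshold: float = 2 / 3,
    purity: float | None = None,
) -> list[TopologySegment]:
    """One segment per window labelled by majority topology (or by the
    >= purity topology when ``purity`` is given; windows failing purity
    are dropped), then collapsed."""
    segs = []
    for t, w in zip(trees, weights):
        if purity is not None:
            vals = w.as_tuple()
            best = int(np.argmax(vals))
            if vals[best] < purity - 1e-12:
                continue
            label = TOPO_LABELS[best]
            support = vals[best]
        else:
            label = majority_topology(w, threshold)
            support = max(w.as_tuple())
        segs.append(TopologySegment(t.chrom, t.start, t.end, label, support))
    return collapse_adjacent(segs)


# ---------------------------------------------------------------------------
# Block bootstrap of genome proportions
# ---------------------------------------------------------------------------


def genome_proportions_bootstrap(
    windows: Sequence[tuple[str, int, int, str]],
    block: int = 1_000_000,
    reps: int = 10_000,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Share of the genome (window bp) per label with percentile CIs from
    resampling genomic blocks of ``block`` bp.

    ``windows``: (chrom, start, end, label) tuples; labels are the three
    topologies plus 'unresolved'. Returns percentages:
    ``label -> {'estimate', 'lo', 'hi'}``.
    """
    if not windows:
        raise ValidationError("no windows to bootstrap")
    labels = list(TOPO_LABELS) + [UNRESOLVED]
    lab_i = {l: i for i, l in enumerate(labels)}
    blocks: dict[tuple[str, int], np.ndarray] = {}
    for chrom, start, end, label in windows:
        key = (chrom, (start + end) // 2 // block)
        row = blocks.setdefault(key, np.zeros(len(labels)))
        row[lab_i[label]] += end - start
    B = np.vstack(list(blocks.values()))
    nb = len(B)
    total = B.sum()
    est = 100.0 * B.sum(axis=0) / total

    rng = np.random.default_rng(seed)
    shares = np.empty((reps, len(labels)))
    chunk = max(1, min(reps, 2_000_000 // max(nb, 1)))
    done = 0
    while done < reps:
        r = min(chunk, reps - done)
        counts = rng.multinomial(nb, np.full(nb, 1 / nb), size=r)
        sums = counts @ B
        shares[done : done + r] = 100.0 * sums / sums.sum(axis=1, keepdims=True)
        done += r
    lo = np.percentile(shares, 2.5, axis=0)
    hi = np.percentile(shares, 97.5, axis=0)
    return {
        l: {"estimate": float(est[i]), "lo": float(lo[i]), "hi": float(hi[i])}
        for i, l in enumerate(labels)
    }


# ---------------------------------------------------------------------------
# Per-topology divergence
# ---------------------------------------------------------------------------


#: which group P3 is compared against within each topology class
DXY_COUNTERPART = {"topo1": "P2", "topo2": "P1", "topo3": "P2"}


def dxy_by_topology(
    gm: GenotypeMatrix,
    groups: GroupMap,
    trees: Sequence[WindowTree],
    weights: Sequence[TopologyWeights],
    purity: float = 1.0,
) -> dict[str, list[tuple[TopologySegment, float]]]:
    """Per-segment D_XY between the focal group and the topology-specific
    counterpart, restricted to windows at the given weight purity.

    Only windows that are consecutive in the window sequence are merged
    into one segment: collapsing across a dropped (impure) window would
    splice foreign-class sequence into the segment span.
    """
    if not 2 / 3 < purity <= 1:
        raise ValidationError("purity must be in (2/3, 1]")
    from mosaicscan import windows_stats as ws

    runs: list[tuple[int, TopologySegment]] = []
    for i, (t, w) in enumerate(zip(trees, weights)):
        vals = w.as_tuple()
        best = int(np.argmax(vals))
        if vals[best] < purity - 1e-12:
            continue
        runs.append(
            (i, TopologySegment(t.chrom, t.start, t.end, TOPO_LABELS[best], vals[best]))
        )
    segs: list[TopologySegment] = []
    prev_i = None
    for i, seg in runs:
        if (
            segs
            and prev_i == i - 1
            and segs[-1].chrom == seg.chrom
            and segs[-1].label == seg.label
        ):
            segs[-1] = TopologySegment(
                seg.chrom, segs[-1].start, seg.end, seg.label,
                segs[-1].support + seg.support,
            )
        else:
            segs.append(seg)
        prev_i = i
    out: dict[str, list[tuple[TopologySegment, float]]] = {l: [] for l in TOPO_LABELS}
    for seg in segs:
        other = DXY_COUNTERPART[seg.label]
        val = ws.dxy(
            gm, groups, ws.Window(seg.chrom, seg.start, seg.end), "P3", other
        )
        if val is not None:
            out[seg.label].append((seg, val))
    return out
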