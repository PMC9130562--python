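"""Self-contained synthetic genomes with known truth.

The genome is partitioned into tracts, each assigned a genealogy class
(topo1 / topo2 / topo3 / mixed) in configured proportions. Within a
tract, haplotypes evolve down a fixed labelled tree: mutations are
placed on branches proportionally to branch length and every descendant
haplotype carries the derived allele. 'mixed' tracts interleave the
three genealogies at a fine grain to produce genuinely unresolved
windows. Gene annotations, a recombination map, candidate lists, and
codon alignments with controlled focal-branch omega are generated
alongside, with all truth recorded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mosaicscan.errors import ValidationError
from mosaicscan import genomic_io as gio
from mosaicscan.coding_evol import CodonAlignment, translate_codon

_NT = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

CLASSES = ("topo1", "topo2", "topo3", "mixed")


@dataclass
class SimulationConfig:
    """Knobs for the synthetic genome generator (all depths are expected
    substitutions per site from the present)."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000,
                                "chr3": 5_000_000, "chr4": 5_000_000}
    )
    samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"P1": 3, "P2": 4, "P3": 3}
    )
    outgroup_name: str = "outgroup"
    class_props: dict[str, float] = field(
        default_factory=lambda: {
            "topo1": 0.1107,
            "topo2": 0.5264,
            "topo3": 0.1570,
            "mixed": 0.2059,
        }
    )
    tract_mean_len: int = 50_000
    tract_min_len: int = 2_000
    mixed_grain: int = 1_000
    group_depth: dict[str, float] = field(
        default_factory=lambda: {"P1": 5e-4, "P2": 5e-4, "P3": 5e-4}
    )
    #: height at which the two sister groups of each class join
    join_low: dict[str, float] = field(
        default_factory=lambda: {"topo1": 2e-3, "topo2": 2e-3, "topo3": 2e-3}
    )
    join_high: float = 4e-3
    mixed_join_low: float = 1e-3
    out_depth: float = 1.25e-2
    mutation_scale: float = 1.0
    # annotation / candidate layer
    n_genes: int = 600
    gene_len_range: tuple[int, int] = (3_000, 9_000)
    candidate_fraction: float = 0.1
    effect_fraction: float = 1.0  # fraction of candidates with planted effects
    effect_pi_factor: float = 0.25
    effect_div_extra: float = 2e-3
    flank: int = 5_000
    recomb_segment_len: int = 100_000
    recomb_lognorm: tuple[float, float] = (0.0, 0.7)
    recomb_corr: float = 0.0
    # coding layer
    n_codons: int = 300
    u_focal: float = 0.12
    u_other: float = 0.03
    omega_background: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        tot = sum(self.class_props.get(c, 0.0) for c in CLASSES)
        if abs(tot - 1.0) > 1e-9:
            raise ValidationError(f"class proportions sum to {tot}, not 1")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValidationError("chromosome lengths must be positive")
        if self.mutation_scale < 0:
            raise ValidationError("mutation scale must be >= 0")


@dataclass
class SimTruth:
    """Planted truth: genealogy segments, per-gene omega, planted flags."""

    segments: pd.DataFrame  # chrom, start, end, label
    genes: pd.DataFrame | None = None  # gene_id, chrom, start, end, candidate, planted
    omega: pd.DataFrame | None = None  # gene_id, omega


# ---------------------------------------------------------------------------
# Haplotype trees per genealogy class
# ---------------------------------------------------------------------------


def _tip_layout(cfg: SimulationConfig) -> tuple[list[str], list[str], dict[str, str]]:
    """(sample names, group display prefixes, sample->group)."""
    display = {"P1": "sin", "P2": "fas", "P3": "arc"}
    samples = []
    sample_group = {}
    for g in ("P1", "P2", "P3"):
        for i in range(cfg.samples_per_group[g]):
            name = f"{display[g]}{i + 1}"
            samples.append(name)
            sample_group[name] = g
    return samples, display, sample_group


def _branch_table(
    cfg: SimulationConfig,
    label: str,
    pi_factor: float = 1.0,
    div_extra: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Branches of the haplotype tree for one genealogy class.

    Returns (lengths, members) where members[b] is a boolean vector over
    [hap tips..., outgroup] marking carriers of a mutation on branch b.
    ``pi_factor`` rescales the focal group's internal depth and
    ``div_extra`` lengthens the focal group's ancestor branch (planted
    candidate effects).
    """
    if label not in ("topo1", "topo2", "topo3"):
        raise ValidationError(f"no branch table for class {label!r}")
    samples, _, sample_group = _tip_layout(cfg)
    n_hap = 2 * len(samples)
    n_tips = n_hap + 1  # + outgroup haploid
    group_tips = {g: [] for g in ("P1", "P2", "P3")}
    for i, s in enumerate(samples):
        group_tips[sample_group[s]] += [2 * i, 2 * i + 1]

    depth = dict(cfg.group_depth)
    depth["P3"] = depth["P3"] * pi_factor

    lengths: list[float] = []
    members: list[np.ndarray] = []

    def add(length: float, tips: Sequence[int]) -> None:
        if length <= 0:
            return
        m = np.zeros(n_tips, dtype=bool)
        m[list(tips)] = True
        lengths.append(length)
        members.append(m)

    # terminal haplotype branches
    for g in ("P1", "P2", "P3"):
        for t in group_tips[g]:
            add(depth[g], [t])
    add(cfg.out_depth, [n_tips - 1])

    if label == "mixed":
        raise ValidationError("mixed uses _mixed_branch_table")
    low = cfg.join_low[label]
    sisters = {"topo1": ("P1", "P2"), "topo2": ("P1", "P3"), "topo3": ("P2", "P3")}[label]
    third = ({"P1", "P2", "P3"} - set(sisters)).pop()
    # group-ancestor branches up to the sister join
    for g in sisters:
        extra = div_extra if g == "P3" else 0.0
        add(low - depth[g] + extra, group_tips[g])
    extra3 = div_extra if third == "P3" else 0.0
    add(cfg.join_high - depth[third] + extra3, group_tips[third])
    # sister-pair ancestor up to the deep join
    pair = group_tips[sisters[0]] + group_tips[sisters[1]]
    add(cfg.join_high - low, pair)
    # ingroup root branch up to the outgroup split
    add(cfg.out_depth - cfg.join_high, [t for g in group_tips.values() for t in g])
    return np.array(lengths), np.vstack(members)


def _mixed_branch_table(
    cfg: SimulationConfig,
    arc_sides: Sequence[int],
    pi_factor: float = 1.0,
    div_extra: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Branches for a 'mixed' tract: focal-group *samples* are split
    three ways (``arc_sides[i]`` = 0: sister to P1, 1: sister to P2,
    2: basal), so one-tip-per-group subtrees vote roughly (1/3, 1/3,
    1/3) and windows inside the tract come out unresolved."""
    samples, _, sample_group = _tip_layout(cfg)
    n_tips = 2 * len(samples) + 1
    group_tips = {g: [] for g in ("P1", "P2", "P3")}
    arc_samples = []
    for i, s in enumerate(samples):
        group_tips[sample_group[s]] += [2 * i, 2 * i + 1]
        if sample_group[s] == "P3":
            arc_samples.append(i)
    depth = dict(cfg.group_depth)
    depth["P3"] = depth["P3"] * pi_factor
    sides: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for k, si in enumerate(arc_samples):
        sides[arc_sides[k % len(arc_sides)]] += [2 * si, 2 * si + 1]
    low = cfg.mixed_join_low
    lengths: list[float] = []
    members: list[np.ndarray] = []

    def add(length, tips):
        if length <= 0 or not len(tips):
            return
        m = np.zeros(n_tips, dtype=bool)
        m[list(tips)] = True
        lengths.append(length)
        members.append(m)

    for g in ("P1", "P2", "P3"):
        for t in group_tips[g]:
            add(depth[g], [t])
    add(cfg.out_depth, [n_tips - 1])
    add(low - depth["P1"], group_tips["P1"])
    add(low - depth["P2"], group_tips["P2"])
    # the basal focal lineage joins strictly above the clade join so NJ
    # keeps it outside both donor clades
    high2 = (cfg.join_high + cfg.out_depth) / 2
    add(low - depth["P3"] + div_extra, sides[0])
    add(low - depth["P3"] + div_extra, sides[1])
    add(high2 - depth["P3"] + div_extra, sides[2])
    add(cfg.join_high - low, group_tips["P1"] + sides[0])
    add(cfg.join_high - low, group_tips["P2"] + sides[1])
    add(
        high2 - cfg.join_high,
        group_tips["P1"] + group_tips["P2"] + sides[0] + sides[1],
    )
    add(cfg.out_depth - high2, [t for g in group_tips.values() for t in g])
    return np.array(lengths), np.vstack(members)


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------


def _draw_tracts(
    cfg: SimulationConfig, length: int, rng: np.random.Generator
) -> list[tuple[int, int, str]]:
    labels = list(CLASSES)
    probs = np.array([cfg.class_props[c] for c in labels])
    out = []
    pos = 0
    while pos < length:
        ln = max(cfg.tract_min_len, int(rng.exponential(cfg.tract_mean_len)))
        end = min(length, pos + ln)
        lbl = labels[rng.choice(len(labels), p=probs)]
        out.append((pos, end, lbl))
        pos = end
    return out


def _elementary_pieces(
    tracts: list[tuple[int, int, str]],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[int, int, str]]:
    """Attach a tract index to every piece (mixed tracts keep one
    half-split genealogy for their whole span)."""
    return [(s, e, lbl, ti) for ti, (s, e, lbl) in enumerate(tracts)]


def _split_by_windows(
    pieces: list[tuple[int, int, str, int]],
    windows: list[tuple[int, int]],
) -> list[tuple[int, int, str, int, bool]]:
    """Split pieces at planted-effect window boundaries; the extra flag
    marks overlap with a planted window."""
    if not windows:
        return [(s, e, l, t, False) for s, e, l, t in pieces]
    cuts = sorted({b for w in windows for b in w})
    out = []
    for s, e, lbl, ti in pieces:
        bounds = [s] + [c for c in cuts if s < c < e] + [e]
        for a, b in zip(bounds[:-1], bounds[1:]):
            inside = any(ws < b and a < we for ws, we in windows)
            out.append((a, b, lbl, ti, inside))
    return out


def simulate_genome(
    cfg: SimulationConfig,
    effect_windows: Mapping[str, list[tuple[int, int]]] | None = None,
    pi_modifiers: Mapping[str, list[tuple[int, int, float]]] | None = None,
    ref_seqs: Mapping[str, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[gio.GenotypeMatrix, SimTruth]:
    """Simulate the genotype matrix and its genealogy-truth segments.

    ``effect_windows`` (per chromosome) mark regions where the planted
    candidate effect applies (focal diversity deflated, focal divergence
    inflated). ``ref_seqs`` supplies per-chromosome reference bases so
    REF alleles match an emitted FASTA.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    effect_windows = effect_windows or {}
    pi_modifiers = pi_modifiers or {}
    samples, _, sample_group = _tip_layout(cfg)
    n_samples = len(samples)

    branch_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}

    def branches(label: str, planted: bool, pi_mod: float, tract_key):
        pi_factor = (cfg.effect_pi_factor if planted else 1.0) * pi_mod
        div_extra = cfg.effect_div_extra if planted else 0.0
        if label == "mixed":
            key = ("mixed", tract_key, planted, round(pi_mod, 9))
            if key not in branch_cache:
                sides = mixed_assignments[tract_key]
                branch_cache[key] = _mixed_branch_table(cfg, sides, pi_factor, div_extra)
            return branch_cache[key]
        key = (label, planted, round(pi_mod, 9))
        if key not in branch_cache:
            branch_cache[key] = _branch_table(cfg, label, pi_factor, div_extra)
        return branch_cache[key]

    all_chrom: list[str] = []
    all_pos: list[np.ndarray] = []
    all_geno: list[np.ndarray] = []
    all_out: list[np.ndarray] = []
    all_ref: list[np.ndarray] = []
    all_alt: list[np.ndarray] = []
    truth_rows = []

    # three-way side assignment of focal samples per mixed tract
    n_arc = cfg.samples_per_group["P3"]
    mixed_assignments: dict[tuple[str, int], list[int]] = {}

    for chrom, length in cfg.chrom_lengths.items():
        tracts = _draw_tracts(cfg, length, rng)
        for s, e, lbl in tracts:
            truth_rows.append((chrom, s, e, lbl))
        mixed_assignments.update(
            {
                (chrom, ti): [
                    int(x) for x in rng.permutation(np.arange(n_arc) % 3)
                ]
                for ti, (_, _, lbl) in enumerate(tracts)
                if lbl == "mixed"
            }
        )
        pieces = _split_by_windows(
            _elementary_pieces(tracts, cfg, rng),
            effect_windows.get(chrom, []),
        )
        mods = pi_modifiers.get(chrom, [])
        pos_list, geno_list, out_list = [], [], []
        for a, b, lbl, tract_key, planted in pieces:
            pi_mod = 1.0
            for ms, me, f in mods:
                if ms <= a < me:
                    pi_mod = f
                    break
            lens, members = branches(lbl, planted, pi_mod, (chrom, tract_key))
            total = lens.sum() * cfg.mutation_scale
            n_mut = rng.poisson((b - a) * total)
            n_mut = min(n_mut, b - a)
            if n_mut == 0:
                continue
            pos = rng.choice(b - a, size=n_mut, replace=False) + a
            pos.sort()
            br = rng.choice(len(lens), size=n_mut, p=lens / lens.sum())
            carriers = members[br]  # (n_mut, n_tips) booleans
            hap = carriers[:, : 2 * n_samples].astype(np.int8)
            geno = hap[:, 0::2] + hap[:, 1::2]  # (n_mut, n_samples)
            outg = carriers[:, -1].astype(np.int8)
            pos_list.append(pos)
            geno_list.append(geno)
            out_list.append(outg)
        if not pos_list:
            continue
        pos = np.concatenate(pos_list)
        geno = np.vstack(geno_list)
        outg = np.concatenate(out_list)
        order = np.argsort(pos, kind="stable")
        pos, geno, outg = pos[order], geno[order], outg[order]
        if ref_seqs is not None and chrom in ref_seqs:
            refc = np.asarray(ref_seqs[chrom])[pos]
        else:
            refc = _NT[rng.integers(0, 4, size=len(pos))]
        shift = rng.integers(1, 4, size=len(pos))
        ref_idx = np.searchsorted(_NT, refc)
        altc = _NT[(ref_idx + shift) % 4]
        all_chrom.append(np.full(len(pos), chrom, dtype=object))
        all_pos.append(pos + 1)  # to 1-based
        all_geno.append(geno)
        all_out.append(outg)
        all_ref.append(refc.astype(object))
        all_alt.append(altc.astype(object))

    if all_pos:
        gm = gio.GenotypeMatrix(
            samples=samples,
            chrom=np.concatenate(all_chrom),
            pos=np.concatenate(all_pos),
            ref=np.concatenate(all_ref),
            alt=np.concatenate(all_alt),
            genotypes=np.vstack(all_geno).T.astype(np.int8),
            outgroup=np.concatenate(all_out),
            contig_lengths=dict(cfg.chrom_lengths),
        )
    else:
        gm = gio.GenotypeMatrix(
            samples=samples,
            chrom=np.array([], dtype=object),
            pos=np.array([], dtype=np.int64),
            ref=np.array([], dtype=object),
            alt=np.array([], dtype=object),
            genotypes=np.zeros((n_samples, 0), dtype=np.int8),
            outgroup=np.array([], dtype=np.int8),
            contig_lengths=dict(cfg.chrom_lengths),
        )
    truth = SimTruth(
        segments=pd.DataFrame(truth_rows, columns=["chrom", "start", "end", "label"])
    )
    return gm, truth


def group_map_for(cfg: SimulationConfig) -> gio.GroupMap:
    samples, _, sample_group = _tip_layout(cfg)
    mapping = dict(sample_group)
    mapping[cfg.outgroup_name] = "OUT"
    return gio.GroupMap(mapping)


# ---------------------------------------------------------------------------
# Annotation layer
# ---------------------------------------------------------------------------


def simulate_annotation(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> dict:
    """Gene models, candidate lists, recombination map, and reference
    sequences.

    Genes are non-overlapping with 1-3 transcripts; candidate genes are
    an exact ``candidate_fraction`` subset; a ``effect_fraction`` subset
    of candidates gets planted effect windows. The recombination map is
    piecewise constant; with ``recomb_corr`` non-zero, local diversity is
    coupled to the map via per-segment depth modifiers.
    """
    if cfg.n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)

    # reference sequences
    ref_seqs = {
        c: _NT[rng.integers(0, 4, size=ln)] for c, ln in cfg.chrom_lengths.items()
    }

    # distribute genes over chromosomes proportionally to length
    total_len = sum(cfg.chrom_lengths.values())
    counts = {
        c: int(round(cfg.n_genes * ln / total_len))
        for c, ln in cfg.chrom_lengths.items()
    }
    drift = cfg.n_genes - sum(counts.values())
    first = next(iter(counts))
    counts[first] += drift

    models: dict[str, gio.GeneModel] = {}
    gi = 0
    for chrom, ln in cfg.chrom_lengths.items():
        n = counts[chrom]
        if n == 0:
            continue
        slot = ln // n
        if slot < cfg.gene_len_range[1] + 2 * cfg.flank:
            raise ValidationError(
                f"genome too small for {cfg.n_genes} genes "
                f"(slot {slot} bp on {chrom})"
            )
        for k in range(n):
            gi += 1
            glen = int(rng.integers(cfg.gene_len_range[0], cfg.gene_len_range[1] + 1))
            lo = k * slot + cfg.flank
            hi = (k + 1) * slot - cfg.flank - glen
            start = int(rng.integers(lo, max(lo + 1, hi)))
            gene_id = f"g{gi:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            tx = [(start, start + glen)]
            for _ in range(int(rng.integers(0, 3))):
                off = int(rng.integers(0, glen // 3 + 1))
                end_off = int(rng.integers(0, glen // 3 + 1))
                if glen - off - end_off > 300:
                    tx.append((start + off, start + glen - end_off))
            n_cod = cfg.n_codons
            cds_len = 3 * n_cod
            cds_len = min(cds_len, (glen // 2) // 3 * 3)
            cds_start = start + (glen - cds_len) // 2
            n_ex = int(rng.integers(1, 4))
            cds = _split_cds(cds_start, cds_len, n_ex, rng)
            models[gene_id] = gio.GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                transcripts=sorted(tx),
                cds=cds,
            )
            # write a stop-free reading frame into the reference
            codons = rng.choice(len(_SENSE_CODONS), size=cds_len // 3)
            coding = "".join(_SENSE_CODONS[i] for i in codons)
            if strand == "-":
                coding = coding[::-1].translate(str.maketrans("ACGT", "TGCA"))
            # lay the (genomic-strand) CDS bases across the segments
            flat = list(coding)
            pos = 0
            for s, e in cds:
                ref_seqs[chrom][s:e] = np.array(flat[pos : pos + (e - s)])
                pos += e - s

    gene_ids = list(models)
    n_cand = int(len(gene_ids) * cfg.candidate_fraction)
    cand_idx = rng.choice(len(gene_ids), size=n_cand, replace=False)
    candidates = sorted(gene_ids[i] for i in cand_idx)
    n_plant = int(round(len(candidates) * cfg.effect_fraction))
    planted = sorted(
        np.array(candidates)[rng.choice(len(candidates), size=n_plant, replace=False)]
    ) if candidates else []

    # male / female sub-lists: overlapping candidate subsets
    male, female = [], []
    for g in candidates:
        u = rng.random()
        if u < 0.45:
            male.append(g)
        elif u < 0.9:
            female.append(g)
        else:
            male.append(g)
            female.append(g)

    effect_windows: dict[str, list[tuple[int, int]]] = {}
    for g in planted:
        m = models[g]
        s, e = m.span()
        effect_windows.setdefault(m.chrom, []).append(
            (max(0, s - cfg.flank), e + cfg.flank)
        )

    # recombination map
    data = {}
    pi_modifiers: dict[str, list[tuple[int, int, float]]] = {}
    mu, sigma = cfg.recomb_lognorm
    for chrom, ln in cfg.chrom_lengths.items():
        starts = np.arange(0, ln, cfg.recomb_segment_len)
        ends = np.minimum(starts + cfg.recomb_segment_len, ln)
        vals = np.exp(rng.normal(mu, sigma, size=len(starts)))
        data[chrom] = (starts, ends, vals)
        if cfg.recomb_corr != 0:
            ref = np.exp(mu)
            pi_modifiers[chrom] = [
                (int(s), int(e), float((v / ref) ** cfg.recomb_corr))
                for s, e, v in zip(starts, ends, vals)
            ]
    imap = gio.IntervalMap(data)

    genes_df = pd.DataFrame(
        [
            {
                "gene_id": g,
                "chrom": models[g].chrom,
                "start": models[g].span()[0],
                "end": models[g].span()[1],
                "candidate": g in candidates,
                "planted": g in planted,
            }
            for g in gene_ids
        ]
    )
    return {
        "models": models,
        "candidates": candidates,
        "male": sorted(male),
        "female": sorted(female),
        "planted": list(planted),
        "effect_windows": effect_windows,
        "recomb": imap,
        "ref_seqs": ref_seqs,
        "pi_modifiers": pi_modifiers,
        "genes": genes_df,
    }


def _split_cds(start: int, cds_len: int, n_ex: int, rng) -> list[tuple[int, int]]:
    """Split a CDS of cds_len coding bases into n_ex segments spread over
    ~1.5x the coding length (codon-boundary splits not required)."""
    if n_ex == 1:
        return [(start, start + cds_len)]
    sizes = np.full(n_ex, cds_len // n_ex)
    sizes[: cds_len % n_ex] += 1
    gaps = rng.integers(50, 200, size=n_ex - 1)
    segs = []
    p = start
    for i, sz in enumerate(sizes):
        segs.append((int(p), int(p + sz)))
        p += sz + (gaps[i] if i < n_ex - 1 else 0)
    return segs


# ---------------------------------------------------------------------------
# Coding layer
# ---------------------------------------------------------------------------


def _mutate(
    seq: str, n_attempts: int, omega: float, rng: np.random.Generator
) -> str:
    """Apply attempted nucleotide substitutions; acceptance makes the
    realised nonsyn/syn rate ratio equal ``omega``. Changes creating a
    stop codon are rejected."""
    if omega <= 0:
        raise ValidationError("omega must be > 0")
    p_syn = min(1.0, 1.0 / omega)
    p_non = min(1.0, omega)
    s = list(seq)
    L = len(s)
    for _ in range(n_attempts):
        i = int(rng.integers(L))
        old = s[i]
        new = "ACGT"[int(rng.integers(4))]
        if new == old:
            continue
        ci = i // 3
        codon = "".join(s[3 * ci : 3 * ci + 3])
        alt = codon[: i % 3] + new + codon[i % 3 + 1 :]
        if translate_codon(alt) == "*":
            continue
        if translate_codon(alt) == translate_codon(codon):
            accept = rng.random() < p_syn
        else:
            accept = rng.random() < p_non
        if accept:
            s[i] = new
    return "".join(s)


def simulate_coding(
    omegas: Mapping[str, float],
    cfg: SimulationConfig | None = None,
    topologies: Mapping[str, str] | None = None,
    rng: np.random.Generator | None = None,
    n_codons: int | None = None,
) -> tuple[dict[str, CodonAlignment], pd.DataFrame]:
    """Evolve per-gene codon alignments with the given focal-branch omega.

    Non-focal branches evolve at ``u_other`` with background omega; the
    focal (P3) branch evolves at ``u_focal`` with the gene's omega.
    """
    cfg = cfg or SimulationConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    if n_codons is None:
        n_codons = cfg.n_codons
    topologies = topologies or {}
    for g, w in omegas.items():
        if w <= 0:
            raise ValidationError(f"gene {g}: omega must be > 0")
    alns = {}
    rows = []
    for gene, omega in omegas.items():
        topo = topologies.get(gene, "topo2")
        L = 3 * n_codons
        root = "".join(
            _SENSE_CODONS[i] for i in rng.choice(len(_SENSE_CODONS), size=n_codons)
        )

        def nmut(u):
            return int(rng.poisson(u * L))

        ub, wb = cfg.u_other, cfg.omega_background
        out_seq = _mutate(root, nmut(2 * ub), wb, rng)
        ingroup = _mutate(root, nmut(ub), wb, rng)
        if topo == "topo1":
            anc_pair = _mutate(ingroup, nmut(ub), wb, rng)  # (P1,P2) ancestor
            p1 = _mutate(anc_pair, nmut(ub), wb, rng)
            p2 = _mutate(anc_pair, nmut(ub), wb, rng)
            p3_base = ingroup
        elif topo == "topo3":
            anc_pair = _mutate(ingroup, nmut(ub), wb, rng)  # (P2,P3) ancestor
            p2 = _mutate(anc_pair, nmut(ub), wb, rng)
            p1 = _mutate(ingroup, nmut(ub), wb, rng)
            p3_base = anc_pair
        else:
            anc_pair = _mutate(ingroup, nmut(ub), wb, rng)  # (P1,P3) ancestor
            p1 = _mutate(anc_pair, nmut(ub), wb, rng)
            p2 = _mutate(ingroup, nmut(ub), wb, rng)
            p3_base = anc_pair
        p3 = _mutate(p3_base, nmut(cfg.u_focal), omega, rng)
        alns[gene] = CodonAlignment(
            gene_id=gene, seqs={"P1": p1, "P2": p2, "P3": p3, "OUT": out_seq}
        )
        rows.append({"gene_id": gene, "omega": omega, "topology": topo})
    return alns, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------


def paperlike_dataset(
    seed: int,
    outdir: str | Path,
    scale: float = 1.0,
    cfg: SimulationConfig | None = None,
) -> dict:
    """Write a complete input bundle (VCF, BED12, bedGraph, group map,
    candidate lists, reference FASTA, codon alignments, truth tables).

    ``scale`` shrinks chromosome lengths and gene counts proportionally
    so the full pipeline stays desk-sized.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg is None:
        cfg = SimulationConfig(seed=seed)
    if scale != 1.0:
        cfg = dataclasses.replace(
            cfg,
            chrom_lengths={
                c: max(200_000, int(l * scale)) for c, l in cfg.chrom_lengths.items()
            },
            n_genes=max(30, int(cfg.n_genes * scale)),
            seed=seed,
        )
    else:
        cfg = dataclasses.replace(cfg, seed=seed)

    rng = np.random.default_rng(cfg.seed)
    ann = simulate_annotation(cfg, rng=np.random.default_rng(cfg.seed + 1))
    gm, truth = simulate_genome(
        cfg,
        effect_windows=ann["effect_windows"],
        pi_modifiers=ann["pi_modifiers"],
        ref_seqs=ann["ref_seqs"],
        rng=rng,
    )
    # deterministic per-gene omegas
    orng = np.random.default_rng(cfg.seed + 3)
    omegas = {
        g: float(np.exp(orng.normal(np.log(cfg.omega_background), 0.8)))
        for g in sorted(ann["models"])
    }
    alns, omega_truth = simulate_coding(
        omegas, cfg=cfg, rng=np.random.default_rng(cfg.seed + 4)
    )

    paths = {
        "vcf": outdir / "genome.vcf",
        "genes": outdir / "genes.bed",
        "recomb": outdir / "recomb.bedgraph",
        "groups": outdir / "groups.tsv",
        "candidates": outdir / "candidates.txt",
        "male": outdir / "male_candidates.txt",
        "female": outdir / "female_candidates.txt",
        "ref": outdir / "reference.fa",
        "cds": outdir / "cds_alignments.fa",
        "truth_segments": outdir / "truth_segments.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_omega": outdir / "truth_omega.tsv",
    }
    gio.write_vcf(gm, paths["vcf"], outgroup_sample=cfg.outgroup_name)
    gio.write_bed12(ann["models"], paths["genes"])
    gio.write_bedgraph(ann["recomb"], paths["recomb"])
    gio.write_group_map(group_map_for(cfg), paths["groups"])
    gio.write_gene_list(ann["candidates"], paths["candidates"])
    gio.write_gene_list(ann["male"], paths["male"])
    gio.write_gene_list(ann["female"], paths["female"])
    gio.write_fasta(
        {c: "".join(s.tolist()) for c, s in ann["ref_seqs"].items()}, paths["ref"]
    )
    gio.write_fasta(
        {
            f"{g}|{grp}": aln.seqs[grp]
            for g, aln in alns.items()
            for grp in ("P1", "P2", "P3", "OUT")
        },
        paths["cds"],
    )
    truth.segments.to_csv(paths["truth_segments"], sep="\t", index=False)
    ann["genes"].to_csv(paths["truth_genes"], sep="\t", index=False)
    omega_truth.to_csv(paths["truth_omega"], sep="\t", index=False)

    return {
        "config": cfg,
        "paths": {k: str(v) for k, v in paths.items()},
        "matrix": gm,
        "truth": SimTruth(
            segments=truth.segments, genes=ann["genes"], omega=omega_truth
        ),
        "annotation": ann,
        "alignments": alns,
    }


def read_cds_alignments(path: str | Path) -> dict[str, CodonAlignment]:
    """Read the ``gene|GROUP`` multi-FASTA written by the bundle."""
    seqs = gio.read_fasta(path)
    per: dict[str, dict[str, str]] = {}
    for name, seq in seqs.items():
        if "|" not in name:
            raise ValidationError(f"bad CDS alignment record name {name!r}")
        gene, grp = name.rsplit("|", 1)
        per.setdefault(gene, {})[grp] = seq
    return {g: CodonAlignment(gene_id=g, seqs=s) for g, s in per.items()}
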