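"""Branch-specific dN/dS on the focal branch and a minimal variant
consequence classifier.

The branch estimator is a counting method: substitutions are assigned to
the focal terminal branch when the focal sequence differs from a
parsimony ancestral codon supported by the other three taxa (sister,
remaining ingroup, outgroup), synonymous/nonsynonymous site counts
follow Nei-Gojobori-style fractional counting on the ancestral sequence,
and multi-hit codons average over minimal substitution pathways.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

from Bio.Seq import Seq

from mosaicscan.errors import ValidationError
from mosaicscan.genomic_io import GeneModel

GROUP_SEQS = ("P1", "P2", "P3", "OUT")
_NT = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


@lru_cache(maxsize=None)
def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


@dataclass
class CodonAlignment:
    """One gene's aligned coding sequences (per-group consensus), coding
    strand, frame 0, equal lengths divisible by 3."""

    gene_id: str
    seqs: dict[str, str]

    def __post_init__(self) -> None:
        lens = {len(s) for s in self.seqs.values()}
        if len(lens) != 1:
            raise ValidationError(f"{self.gene_id}: unequal sequence lengths")
        (n,) = lens
        if n % 3 != 0:
            raise ValidationError(f"{self.gene_id}: length {n} not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.seqs.values()))) // 3


@dataclass
class DnDsEstimate:
    gene_id: str
    dn: float
    ds: float
    omega: float | None
    topology: str
    n_codons_used: int = 0
    nd: float = 0.0
    sd: float = 0.0
    n_sites: float = 0.0
    s_sites: float = 0.0
    excluded: bool = False
    reason: str | None = None


@lru_cache(maxsize=None)
def _site_counts(codon: str) -> tuple[float, float]:
    """Nei-Gojobori fractional (nonsyn, syn) site counts for one codon.

    Changes producing a stop codon count as nonsynonymous.
    """
    aa = translate_codon(codon)
    n_sites = 0.0
    s_sites = 0.0
    for i in range(3):
        syn = 0
        for nt in _NT:
            if nt == codon[i]:
                continue
            alt = codon[:i] + nt + codon[i + 1 :]
            if translate_codon(alt) == aa:
                syn += 1
        s_sites += syn / 3
        n_sites += 1 - syn / 3
    return n_sites, s_sites


@lru_cache(maxsize=None)
def _path_counts(anc: str, der: str) -> tuple[float, float]:
    """(nonsyn, syn) substitution counts between two codons, averaged over
    minimal pathways. Pathways through stop codons are discarded unless
    every pathway hits one."""
    diff = [i for i in range(3) if anc[i] != der[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur = anc
        nd = sd = 0.0
        ok = True
        for i in order:
            nxt = cur[:i] + der[i] + cur[i + 1 :]
            if translate_codon(nxt) == translate_codon(cur):
                sd += 1
            else:
                nd += 1
            if translate_codon(nxt) == "*" and nxt != der:
                ok = False
            cur = nxt
        paths.append((ok, nd, sd))
    valid = [(nd, sd) for ok, nd, sd in paths if ok]
    if not valid:
        valid = [(nd, sd) for _, nd, sd in paths]
    nd = sum(v[0] for v in valid) / len(valid)
    sd = sum(v[1] for v in valid) / len(valid)
    return nd, sd


#: sister group of the focal taxon under each rooted topology
SISTER = {"topo1": None, "topo2": "P1", "topo3": "P2"}


def branch_dnds(
    aln: CodonAlignment,
    topology: str = "topo2",
    focal: str = "P3",
) -> DnDsEstimate:
    """dN/dS on the focal terminal branch.

    For each codon the ancestral state is the codon supported by at least
    two of the three non-focal sequences; codons with no such support, a
    frame gap, or ambiguous bases are skipped. ``omega`` is None when
    dS = 0.
    """
    if topology not in SISTER:
        raise ValidationError(f"unknown topology {topology!r}")
    missing = [g for g in GROUP_SEQS if g not in aln.seqs]
    if missing:
        raise ValidationError(f"{aln.gene_id}: missing sequences {missing}")
    others = [g for g in GROUP_SEQS if g != focal]
    nd = sd = 0.0
    n_sites = s_sites = 0.0
    used = 0
    sister = SISTER[topology]
    for ci in range(aln.n_codons):
        codons = {g: aln.seqs[g][3 * ci : 3 * ci + 3].upper() for g in GROUP_SEQS}
        if any(set(c) - set(_NT) for c in codons.values()):
            continue
        foc = codons[focal]
        if sister is not None and foc == codons[sister]:
            # parsimony puts any change below the focal/sister split
            if translate_codon(foc) == "*":
                continue
            used += 1
            n_i, s_i = _site_counts(foc)
            n_sites += n_i
            s_sites += s_i
            continue
        support = [codons[g] for g in others]
        anc = None
        for cand in set(support):
            if support.count(cand) >= 2:
                anc = cand
                break
        if anc is None or translate_codon(anc) == "*":
            continue
        used += 1
        n_i, s_i = _site_counts(anc)
        n_sites += n_i
        s_sites += s_i
        if foc != anc:
            dn_i, ds_i = _path_counts(anc, foc)
            nd += dn_i
            sd += ds_i
    dn = nd / n_sites if n_sites > 0 else 0.0
    ds = sd / s_sites if s_sites > 0 else 0.0
    omega = dn / ds if ds > 0 else None
    return DnDsEstimate(
        gene_id=aln.gene_id,
        dn=dn,
        ds=ds,
        omega=omega,
        topology=topology,
        n_codons_used=used,
        nd=nd,
        sd=sd,
        n_sites=n_sites,
        s_sites=s_sites,
    )


def dnds_exclusion(est: DnDsEstimate, max_omega: float = 10.0) -> DnDsEstimate:
    """Apply the insufficient-divergence drop rules: dS = 0, or omega > 10."""
    if est.ds == 0:
        est.excluded = True
        est.reason = "dS=0"
    elif est.omega is not None and est.omega > max_omega:
        est.excluded = True
        est.reason = f"omega>{max_omega:g}"
    return est


def weighted_dnds(
    per_topology: Mapping[str, DnDsEstimate],
    weights: Sequence[float],
) -> float | None:
    """Topology-weight average of the non-excluded omega estimates.

    Weights of excluded topologies are redistributed proportionally;
    returns None when everything is excluded or weightless.
    """
    if len(weights) != 3:
        raise ValidationError("need three topology weights")
    num = den = 0.0
    for lbl, wgt in zip(("topo1", "topo2", "topo3"), weights):
        est = per_topology.get(lbl)
        if est is None or est.excluded or est.omega is None:
            continue
        num += wgt * est.omega
        den += wgt
    if den <= 0:
        return None
    return num / den


# ---------------------------------------------------------------------------
# Variant consequence classification
# ---------------------------------------------------------------------------


def _cds_positions(model: GeneModel) -> list[int]:
    """Genomic positions of CDS bases in coding-strand order."""
    pos = [p for s, e in model.cds for p in range(s, e)]
    if model.strand == "-":
        pos.reverse()
    return pos


def classify_consequence(
    pos0: int,
    ref: str,
    alt: str,
    model: GeneModel,
    cds_seq: str,
) -> str:
    """Classify a SNP as silent / missense / nonsense / noncoding.

    ``pos0`` is the 0-based genomic position; ``cds_seq`` is the spliced
    CDS on the coding strand. Sites whose reference base disagrees with
    the CDS sequence, or falling in an incomplete codon, are 'unknown'.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValidationError("SNP alleles required")
    if not model.cds:
        return "noncoding"
    positions = _cds_positions(model)
    try:
        idx = positions.index(pos0)
    except ValueError:
        return "noncoding"
    if len(cds_seq) != len(positions):
        raise ValidationError(
            f"{model.gene_id}: CDS sequence length {len(cds_seq)} != model {len(positions)}"
        )
    ref_c, alt_c = ref.upper(), alt.upper()
    if model.strand == "-":
        ref_c = ref_c.translate(_COMP)
        alt_c = alt_c.translate(_COMP)
    ci = idx // 3
    codon = cds_seq[3 * ci : 3 * ci + 3].upper()
    if len(codon) != 3 or set(codon) - set(_NT):
        return "unknown"
    off = idx % 3
    if codon[off] != ref_c:
        return "unknown"
    alt_codon = codon[:off] + alt_c + codon[off + 1 :]
    aa_ref = translate_codon(codon)
    aa_alt = translate_codon(alt_codon)
    if aa_alt == aa_ref:
        return "silent"
    if aa_alt == "*":
        return "nonsense"
    return "missense"
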