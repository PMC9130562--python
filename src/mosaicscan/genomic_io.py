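"""Readers and writers for the genomic formats consumed by the pipeline.

Formats: VCF 4.x (biallelic SNPs with a designated haploid outgroup
column), BED12 / GFF3 gene models, bedGraph recombination maps,
two-column group maps, one-ID-per-line gene lists, and FASTA.

Coordinate conventions: VCF positions are 1-based; everything internal is
0-based half-open. BED is read as-is, GFF3 is converted on read.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

from mosaicscan.errors import ConfigurationError, ParseError, ValidationError

GROUPS = ("P1", "P2", "P3", "OUT")

#: Default display names for the four taxon groups.
DEFAULT_DISPLAY = {
    "P1": "sinica",
    "P2": "fascicularis",
    "P3": "arctoides",
    "OUT": "outgroup",
}

_DISPLAY_TO_GROUP = {v: k for k, v in DEFAULT_DISPLAY.items()}

_NT = frozenset("ACGT")


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes over ordered samples plus an outgroup allele.

    ``genotypes`` holds diploid ALT-allele counts in {0, 1, 2} with -1 for
    missing, shaped (n_samples, n_sites). ``outgroup`` holds the haploid
    outgroup allele per site: 0 = REF, 1 = ALT, -1 = missing.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray  # 1-based
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    outgroup: np.ndarray
    contig_lengths: dict[str, int] = field(default_factory=dict)
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.pos)
        for name in ("chrom", "ref", "alt", "outgroup"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"field {name!r} length mismatch")
        if self.genotypes.shape != (len(self.samples), n):
            raise ValidationError("genotype matrix shape mismatch")
        self._check_sorted()

    def _check_sorted(self) -> None:
        seen: set[str] = set()
        prev_chrom = None
        prev_pos = -1
        for c, p in zip(self.chrom, self.pos):
            if c != prev_chrom:
                if c in seen:
                    raise ValidationError(f"sites not grouped by chromosome: {c}")
                seen.add(c)
                prev_chrom, prev_pos = c, -1
            if p <= prev_pos:
                raise ValidationError(
                    f"sites not strictly sorted at {c}:{p}"
                )
            prev_pos = p

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise ValidationError(f"unknown sample {name!r}") from None

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def region_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of sites whose 0-based position lies in [start, end)."""
        p0 = self.pos - 1
        return (self.chrom == chrom) & (p0 >= start) & (p0 < end)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            genotypes=self.genotypes[:, mask],
            outgroup=self.outgroup[mask],
            contig_lengths=dict(self.contig_lengths),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.outgroup, other.outgroup)
        )

    def effective_contig_lengths(self) -> dict[str, int]:
        """Declared contig lengths, falling back to the last site position."""
        out = dict(self.contig_lengths)
        for c in self.chromosomes():
            if c not in out:
                out[c] = int(self.pos[self.chrom == c].max())
        return out


def read_vcf(
    path: str | Path,
    outgroup_sample: str | None = "outgroup",
    region: tuple[str, int, int] | None = None,
) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records with at least one called genotype are kept;
    multiallelic, indel and fully-uncalled records are dropped and counted
    in ``GenotypeMatrix.dropped``. The outgroup allele is taken from the
    designated haploid sample column (``outgroup_sample``); pass ``None``
    to read a VCF without one (all outgroup alleles set missing).

    ``region`` is a 0-based half-open ``(chrom, start, end)`` interval.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"VCF not found: {path}")
    vcf = VCF(str(path))
    all_samples = list(vcf.samples)
    if outgroup_sample is not None and outgroup_sample not in all_samples:
        raise ConfigurationError(
            f"outgroup sample {outgroup_sample!r} not in VCF columns {all_samples}"
        )
    samples = [s for s in all_samples if s != outgroup_sample]
    out_i = all_samples.index(outgroup_sample) if outgroup_sample is not None else -1
    idx = [all_samples.index(s) for s in samples]

    contig_lengths = {}
    for name, ln in zip(vcf.seqnames, vcf.seqlens or []):
        if ln:
            contig_lengths[name] = int(ln)

    chrom: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    gts: list[list[int]] = []
    outg: list[int] = []
    dropped = collections.Counter()

    nrec = 0
    try:
        for rec in vcf:
            nrec += 1
            if len(rec.ALT) != 1:
                dropped["multiallelic"] += 1
                continue
            if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
                dropped["indel"] += 1
                continue
            if rec.REF not in _NT or rec.ALT[0] not in _NT:
                dropped["non_snp"] += 1
                continue
            if region is not None:
                c, s, e = region
                if rec.CHROM != c or not (s <= rec.POS - 1 < e):
                    continue
            raw = rec.genotypes
            row: list[int] = []
            for i in idx:
                alleles = [a for a in raw[i][:-1] if a is not None]
                if any(a < 0 for a in alleles) or not alleles:
                    row.append(-1)
                elif len(alleles) == 1:  # haploid ingroup column: double it
                    row.append(2 * alleles[0])
                else:
                    row.append(alleles[0] + alleles[1])
            if all(g < 0 for g in row):
                dropped["no_call"] += 1
                continue
            if out_i >= 0:
                oa = [a for a in raw[out_i][:-1] if a is not None]
                if not oa or any(a < 0 for a in oa) or len(set(oa)) > 1:
                    outg.append(-1)
                else:
                    outg.append(oa[0])
            else:
                outg.append(-1)
            chrom.append(rec.CHROM)
            pos.append(rec.POS)
            ref.append(rec.REF)
            alt.append(rec.ALT[0])
            gts.append(row)
    except Exception as exc:  # htslib parse failure
        if isinstance(exc, ValidationError):
            raise
        raise ParseError(
            f"malformed VCF record near record {nrec + 1} in {path}: {exc}"
        ) from exc

    n = len(pos)
    gm = GenotypeMatrix(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        genotypes=(
            np.array(gts, dtype=np.int8).T if n else np.zeros((len(samples), 0), np.int8)
        ),
        outgroup=np.array(outg, dtype=np.int8),
        contig_lengths=contig_lengths,
        dropped=dict(dropped),
    )
    return gm


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
_HAP_STR = {0: "0", 1: "1", -1: "."}


def write_vcf(
    gm: GenotypeMatrix,
    path: str | Path,
    outgroup_sample: str = "outgroup",
) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF.

    The outgroup allele is emitted as a haploid genotype in a trailing
    sample column named ``outgroup_sample``.
    """
    path = Path(path)
    lengths = gm.effective_contig_lengths()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mosaicscan\n")
        for c in gm.chromosomes():
            fh.write(f"##contig=<ID={c},length={lengths[c]}>\n")
        for c, ln in lengths.items():
            if c not in gm.chromosomes():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        cols += gm.samples + [outgroup_sample]
        fh.write("\t".join(cols) + "\n")
        G = gm.genotypes
        for j in range(gm.n_sites):
            row = [
                str(gm.chrom[j]),
                str(int(gm.pos[j])),
                ".",
                str(gm.ref[j]),
                str(gm.alt[j]),
                ".",
                "PASS",
                ".",
                "GT",
            ]
            row += [_GT_STR[int(G[i, j])] for i in range(gm.n_samples)]
            row.append(_HAP_STR[int(gm.outgroup[j])])
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# GroupMap
# ---------------------------------------------------------------------------


class GroupMap:
    """Mapping of sample IDs to the four taxon groups P1/P2/P3/OUT."""

    def __init__(
        self,
        mapping: Mapping[str, str],
        display: Mapping[str, str] | None = None,
    ) -> None:
        self.mapping: dict[str, str] = {}
        for sample, group in mapping.items():
            group = _DISPLAY_TO_GROUP.get(group, group)
            if group not in GROUPS:
                raise ValidationError(f"unknown group label {group!r} for {sample!r}")
            self.mapping[sample] = group
        self.display = dict(display or DEFAULT_DISPLAY)

    def __len__(self) -> int:
        return len(self.mapping)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GroupMap) and self.mapping == other.mapping

    def group_of(self, sample: str) -> str:
        try:
            return self.mapping[sample]
        except KeyError:
            raise ValidationError(f"sample {sample!r} has no group") from None

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.mapping.items() if g == group]

    def require_nonempty(self, groups: Iterable[str] = ("P1", "P2", "P3")) -> None:
        for g in groups:
            if not self.samples_in(g):
                raise ValidationError(f"group {g} has no samples")


def read_group_map(path: str | Path) -> GroupMap:
    """Read a two-column (sample, group) whitespace/tab-separated file.

    Group labels may be canonical (P1/P2/P3/OUT) or display names
    (sinica/fascicularis/arctoides/outgroup). Duplicate samples are an
    error regardless of the group they claim.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"group map not found: {path}")
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
        sample, group = parts
        if sample in mapping:
            raise ValidationError(f"{path}:{lineno}: duplicate sample {sample!r}")
        mapping[sample] = group
    return GroupMap(mapping)


def write_group_map(groups: GroupMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, group in groups.mapping.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# IntervalMap (recombination rates)
# ---------------------------------------------------------------------------


@dataclass
class IntervalMap:
    """Per-chromosome sorted, non-overlapping intervals with a value each.

    Stored as ``chrom -> (starts, ends, values)`` ndarrays, 0-based
    half-open, values in cM/Mb.
    """

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for c, (s, e, v) in self.data.items():
            if not (len(s) == len(e) == len(v)):
                raise ValidationError(f"interval arrays length mismatch on {c}")
            if np.any(e <= s):
                raise ValidationError(f"empty/inverted interval on {c}")
            if np.any(s[1:] < e[:-1]):
                raise ValidationError(f"overlapping intervals on {c}")
            if np.any(v < 0):
                raise ValidationError(f"negative rate on {c}")


def read_bedgraph(path: str | Path) -> IntervalMap:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"bedGraph not found: {path}")
    per: dict[str, list[tuple[int, int, float]]] = collections.defaultdict(list)
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns")
        try:
            per[parts[0]].append((int(parts[1]), int(parts[2]), float(parts[3])))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    data = {}
    for c, rows in per.items():
        rows.sort()
        s, e, v = (np.array(x) for x in zip(*rows))
        data[c] = (s.astype(np.int64), e.astype(np.int64), v.astype(float))
    return IntervalMap(data)


def write_bedgraph(imap: IntervalMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in sorted(imap.data):
            s, e, v = imap.data[c]
            for i in range(len(s)):
                fh.write(f"{c}\t{int(s[i])}\t{int(e[i])}\t{v[i]:.6g}\n")


def mean_rate_in_interval(
    imap: IntervalMap, chrom: str, start: int, end: int
) -> float | None:
    """Length-weighted mean rate over [start, end); None when no overlap."""
    if end <= start:
        raise ValidationError(f"inverted interval {chrom}:{start}-{end}")
    if chrom not in imap.data:
        return None
    s, e, v = imap.data[chrom]
    lo = np.minimum(e, end) - np.maximum(s, start)
    w = np.clip(lo, 0, None)
    tot = w.sum()
    if tot == 0:
        return None
    return float((w * v).sum() / tot)


# ---------------------------------------------------------------------------
# Gene models (BED12 / GFF3)
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A gene: transcript spans plus the CDS segments of one transcript.

    ``transcripts`` are 0-based half-open (start, end) spans, all on
    ``chrom``. ``cds`` lists the coding segments in genomic order; their
    total length is divisible by 3 for coding genes. Frame starts at 0 at
    the 5' end of the coding strand.
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id}: no transcripts")
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        for s, e in self.transcripts + self.cds:
            if e <= s:
                raise ValidationError(f"gene {self.gene_id}: empty interval")
        if self.cds and self.cds_length() % 3 != 0:
            raise ValidationError(
                f"gene {self.gene_id}: CDS length {self.cds_length()} not divisible by 3"
            )

    def span(self) -> tuple[int, int]:
        return (
            min(s for s, _ in self.transcripts),
            max(e for _, e in self.transcripts),
        )

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


def read_bed12(path: str | Path) -> dict[str, GeneModel]:
    """Read BED12 gene models; rows sharing a name are transcripts of one gene.

    The CDS is taken from the row with the largest thick (coding) extent.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"BED12 not found: {path}")
    genes: dict[str, dict] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise ParseError(f"{path}:{lineno}: expected 12 BED columns, got {len(f)}")
        chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
        strand = f[5]
        thick_s, thick_e = int(f[6]), int(f[7])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offs = [int(x) for x in f[11].rstrip(",").split(",")]
        blocks = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
        cds = []
        if thick_e > thick_s:
            for bs, be in blocks:
                s2, e2 = max(bs, thick_s), min(be, thick_e)
                if e2 > s2:
                    cds.append((s2, e2))
        rec = genes.setdefault(
            name, {"chrom": chrom, "strand": strand, "tx": [], "cds": [], "cds_len": -1}
        )
        if rec["chrom"] != chrom:
            raise ValidationError(f"gene {name}: transcripts on multiple chromosomes")
        rec["tx"].append((start, end))
        clen = sum(e - s for s, e in cds)
        if clen > rec["cds_len"]:
            rec["cds"], rec["cds_len"] = cds, clen
    return {
        name: GeneModel(
            gene_id=name,
            chrom=rec["chrom"],
            strand=rec["strand"],
            transcripts=sorted(rec["tx"]),
            cds=rec["cds"],
        )
        for name, rec in genes.items()
    }


def write_bed12(models: Mapping[str, GeneModel], path: str | Path) -> None:
    """Write gene models as BED12, one row per transcript.

    The CDS (thick/blocks) is attached to the transcript containing it;
    other transcripts get a single full-span block with no thick region.
    """
    with open(path, "w") as fh:
        for model in models.values():
            cds_span = (
                (model.cds[0][0], model.cds[-1][1]) if model.cds else None
            )
            for ti, (ts, te) in enumerate(model.transcripts):
                use_cds = (
                    model.cds
                    and cds_span is not None
                    and ts <= cds_span[0]
                    and te >= cds_span[1]
                    and ti == _first_containing(model.transcripts, cds_span)
                )
                if use_cds:
                    blocks = _blocks_for(model, ts, te)
                    thick_s, thick_e = cds_span
                else:
                    blocks = [(ts, te)]
                    thick_s = thick_e = ts
                sizes = ",".join(str(e - s) for s, e in blocks) + ","
                offs = ",".join(str(s - ts) for s, _ in blocks) + ","
                fh.write(
                    "\t".join(
                        [
                            model.chrom,
                            str(ts),
                            str(te),
                            model.gene_id,
                            "0",
                            model.strand,
                            str(thick_s),
                            str(thick_e),
                            "0",
                            str(len(blocks)),
                            sizes,
                            offs,
                        ]
                    )
                    + "\n"
                )


def _first_containing(transcripts: Sequence[tuple[int, int]], span: tuple[int, int]) -> int:
    for i, (s, e) in enumerate(transcripts):
        if s <= span[0] and e >= span[1]:
            return i
    return -1


def _blocks_for(model: GeneModel, ts: int, te: int) -> list[tuple[int, int]]:
    """Exon blocks for the CDS-bearing transcript: CDS segments with the
    first/last block extended to cover the UTRs out to the span ends."""
    blocks = list(model.cds)
    if not blocks:
        return [(ts, te)]
    blocks[0] = (min(blocks[0][0], ts), blocks[0][1])
    blocks[-1] = (blocks[-1][0], max(blocks[-1][1], te))
    merged = [blocks[0]]
    for s, e in blocks[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    return merged


def read_gff3(path: str | Path) -> dict[str, GeneModel]:
    """Read gene models from GFF3 (gene -> mRNA -> CDS/exon)."""
    import gffutils

    path = Path(path)
    if not path.exists():
        raise ValidationError(f"GFF3 not found: {path}")
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        gid = gene.attributes.get("ID", [gene.id])[0]
        transcripts = []
        best_cds: list[tuple[int, int]] = []
        for mrna in db.children(gene, featuretype=("mRNA", "transcript")):
            transcripts.append((mrna.start - 1, mrna.end))
            cds = sorted(
                (c.start - 1, c.end) for c in db.children(mrna, featuretype="CDS")
            )
            if sum(e - s for s, e in cds) > sum(e - s for s, e in best_cds):
                best_cds = cds
        if not transcripts:
            transcripts = [(gene.start - 1, gene.end)]
        models[gid] = GeneModel(
            gene_id=gid,
            chrom=gene.seqid,
            strand=gene.strand if gene.strand in "+-" else "+",
            transcripts=sorted(transcripts),
            cds=best_cds,
        )
    return models


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Dispatch on extension: .bed -> BED12, .gff/.gff3 -> GFF3."""
    p = Path(path)
    if p.suffix in (".gff", ".gff3"):
        return read_gff3(p)
    return read_bed12(p)


# ---------------------------------------------------------------------------
# Gene lists and FASTA
# ---------------------------------------------------------------------------


def read_gene_list(path: str | Path) -> list[str]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"gene list not found: {path}")
    out = []
    seen = set()
    for line in path.read_text().splitlines():
        g = line.strip()
        if g and not g.startswith("#") and g not in seen:
            out.append(g)
            seen.add(g)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise ValidationError(f"FASTA not found: {path}")
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"duplicate FASTA record {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Heterozygous-site intersections
# ---------------------------------------------------------------------------


@dataclass
class HetIntersections:
    """Per-sample heterozygous-site totals and subset intersection counts.

    ``exclusive`` counts sites by the exact set of samples heterozygous
    there (UpSet-style); :meth:`intersection` gives the plain k-way
    intersection size for any subset.
    """

    samples: list[str]
    totals: dict[str, int]
    exclusive: dict[frozenset, int]
    _het: np.ndarray = field(repr=False, default=None)

    def intersection(self, subset: Iterable[str]) -> int:
        names = list(subset)
        if not names:
            raise ValidationError("empty subset")
        idx = [self.samples.index(s) for s in names]
        return int(np.all(self._het[idx], axis=0).sum())


def het_intersections(gm: GenotypeMatrix, samples: Sequence[str] | None = None) -> HetIntersections:
    """Heterozygous-site set sizes per sample and per exact sample subset."""
    names = list(samples) if samples is not None else list(gm.samples)
    if not names:
        raise ValidationError("need at least one sample")
    idx = [gm.sample_index(s) for s in names]
    het = gm.genotypes[idx] == 1
    totals = {s: int(het[i].sum()) for i, s in enumerate(names)}
    excl: collections.Counter = collections.Counter()
    if gm.n_sites:
        # encode each site's het pattern as a bitmask
        weights = 1 << np.arange(len(names), dtype=np.int64)
        codes = (het.astype(np.int64).T @ weights)
        uniq, counts = np.unique(codes, return_counts=True)
        for code, cnt in zip(uniq, counts):
            if code == 0:
                continue
            members = frozenset(names[i] for i in range(len(names)) if code >> i & 1)
            excl[members] = int(cnt)
    return HetIntersections(samples=names, totals=totals, exclusive=dict(excl), _het=het)
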