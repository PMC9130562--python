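# mosaicscan

Analysis pipeline for dissecting a genome that is a mosaic of ancestries
from two donor lineages, and for finding candidate genes with extreme
population-genetic signatures while controlling for recombination rate.

Given a multi-sample VCF of biallelic SNPs (with a haploid outgroup
column), gene annotations, a recombination map, a sample-to-group map and
a candidate gene list, the pipeline computes:

1. **Windowed statistics** — nucleotide diversity (π), absolute
   divergence (D_XY), Hudson-type F_ST, Patterson's D and the signed
   dynamic-donor introgression statistic f_dM (positive = excess sharing
   of the focal group P3 with P2, negative = with P1), in overlapping
   windows with per-size minimum-site thresholds.
2. **Topology weighting** — neighbor-joining trees in 50-SNP windows from
   pseudo-haplotypes, exact enumeration of one-tip-per-group subtree
   topologies, majority labelling at a 2/3 threshold, run-length-collapsed
   segments, and genome-wide topology shares with 95% block-bootstrap CIs.
3. **Per-topology divergence** — D_XY between the focal group and the
   topology-specific sister lineage in 100%-purity segments.
4. **Branch dN/dS** — a parsimony + Nei–Gojobori-style counting estimator
   of ω on the focal terminal branch per rooted topology, averaged with
   the local topology weights; estimates with dS = 0 or ω > 10 are
   excluded.
5. **Outlier scan** — per-gene windows (transcript union ± 5 kb), OLS
   regression of each statistic on the gene's mean recombination rate,
   Cook's distance outlier calls (> 3 × mean, direction-aware), a 5%
   upper-quantile rule for ω, chi-square candidate enrichment, and
   permutation tests of candidate-vs-background and male-vs-female mean
   differences.
6. **Synthetic genomes** — a generator that plants genealogy-class tracts
   (topo1/topo2/topo3/mixed) in configurable proportions with full truth
   tables, gene models, recombination maps, candidate lists with planted
   effects, and codon alignments with controlled focal-branch ω, for
   end-to-end recovery testing.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence at 1e-10, topology-weight subsampling agreement, bounds and
symmetry, mosaic recovery on 20 replicate genomes, divergence ordering,
ω recovery, inference calibration, byte-level determinism).

## CLI

```sh
# generate a fully synthetic input bundle with truth tables
mosaicscan simulate --preset paperlike --seed 1 --scale 0.1 --out bundle/

# windowed statistics
mosaicscan winstats --vcf bundle/genome.vcf --groups bundle/groups.tsv \
    --size 50000 --step-frac 0.2 --out windows.tsv

# window trees + topology weights + collapsed segments
mosaicscan topoweights --vcf bundle/genome.vcf --groups bundle/groups.tsv \
    --snps 50 --threshold 0.667 --out-prefix topo

# branch dN/dS, variant consequences, outliers, permutation tests
mosaicscan dnds --alignments bundle/cds_alignments.fa --out dnds.tsv
mosaicscan consequences --vcf bundle/genome.vcf --genes bundle/genes.bed \
    --reference bundle/reference.fa --out consequences.tsv
mosaicscan outliers --genescan out/genescan.tsv --k 3 --dnds-q 0.05 --out calls.tsv
mosaicscan permtest --genescan out/genescan.tsv --n 100 --seed 1 --out perms.tsv

# the full pipeline from one YAML config
mosaicscan run -c config.yaml -o out/
mosaicscan report --outdir out/
```

A minimal `config.yaml` needs only the input paths; every tunable
(window size 50 kb, 20% step, min-sites ladder, 50 SNPs per tree, 2/3
majority threshold, 100% purity, cooksd multiplier 3, 5% ω quantile, 100
permutations, 10,000 bootstrap replicates over 1 Mbp blocks) defaults to
the canonical parameterization:

```yaml
vcf: bundle/genome.vcf
genes: bundle/genes.bed
recomb: bundle/recomb.bedgraph
groups: bundle/groups.tsv
candidates: bundle/candidates.txt
cds_alignments: bundle/cds_alignments.fa
seed: 1
```

Exit codes: 0 success, 2 validation/configuration error, 1 runtime error.

## Layout

```
src/mosaicscan/
  genomic_io.py      VCF / BED12 / GFF3 / bedGraph / FASTA / group-map IO,
                     het-site intersections, interval means
  windows_stats.py   windows, π, D_XY, F_ST, D, f_dM, min-site thresholds
  topology.py        pseudo-haplotypes, NJ trees, exact topology weights,
                     segmentation, block bootstrap, per-topology D_XY
  coding_evol.py     branch dN/dS, weighting, exclusions, consequences
  outlier_scan.py    OLS + Cook's distance, quantile rule, chi-square,
                     permutation tests
  synthetic_data.py  tract/genealogy genome simulator, annotation and
                     codon-alignment generators, paperlike bundles
  pipeline.py        stage orchestration, config, manifest
  cli.py             command-line interface
```
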