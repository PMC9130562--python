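"""End-to-end orchestration: windows -> topology -> dN/dS -> gene scan ->
outliers -> permutations, from a single YAML config.

Every tunable defaults to the canonical analysis parameterization
(50 kb windows at 20% step, 50-SNP trees, 2/3 majority threshold, 100%
purity for per-topology divergence, cooksd multiplier 3, 5% dN/dS
quantile, 100 permutations, 10,000 bootstrap replicates over 1 Mbp
blocks). Outputs are pure functions of (inputs, config, seed): rerunning
with an identical config byte-reproduces every table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import mosaicscan
from mosaicscan.errors import ValidationError
from mosaicscan import coding_evol as ce
from mosaicscan import genomic_io as gio
from mosaicscan import outlier_scan as osc
from mosaicscan import topology as topo
from mosaicscan import windows_stats as ws
from mosaicscan.synthetic_data import read_cds_alignments

log = logging.getLogger(__name__)

STAGES = (
    "load",
    "winstats",
    "topoweights",
    "dnds",
    "genescan",
    "outliers",
    "permtest",
)

GENE_STATS = ("pi", "fst_P3_P1", "fst_P3_P2", "dxy_P3_P1", "dxy_P3_P2", "fdm")


@dataclass
class PipelineConfig:
    # inputs
    vcf: str = ""
    genes: str = ""
    recomb: str = ""
    groups: str = ""
    candidates: str = ""
    male_candidates: str | None = None
    female_candidates: str | None = None
    cds_alignments: str | None = None
    reference: str | None = None
    outgroup_sample: str = "outgroup"
    # windows
    window_size: int = 50_000
    step_fraction: float = 0.2
    min_sites: int | None = None  # None -> ladder lookup by window size
    flank: int = 5_000
    # topology
    snps_per_tree: int = 50
    majority_threshold: float = 2 / 3
    purity: float = 1.0
    block_size: int = 1_000_000
    bootstrap_reps: int = 10_000
    # outliers / inference
    cooksd_k: float = 3.0
    dnds_q: float = 0.05
    n_perm: int = 100
    chisq_correction: bool = False
    tails: dict = field(default_factory=lambda: dict(osc.DEFAULT_TAILS))
    directions: dict = field(default_factory=lambda: dict(osc.DEFAULT_DIRECTIONS))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages in dependency order, writing one table per stage
    plus a run manifest. Returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "version": mosaicscan.__version__,
        "stages": {},
    }
    state: dict = {}
    for stage in STAGES:
        t0 = time.monotonic()
        try:
            rows = _STAGE_FUNCS[stage](cfg, outdir, state)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, outdir)
            raise ValidationError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s done in %.1fs (%d rows)", stage, time.monotonic() - t0, rows)
        manifest["stages"][stage] = {"status": "complete", "rows": rows}
    _write_manifest(manifest, outdir)
    cfg.to_yaml(outdir / "config.used.yaml")
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_load(cfg: PipelineConfig, outdir: Path, state: dict) -> int:
    for name in ("vcf", "genes", "recomb", "groups", "candidates"):
        p = getattr(cfg, name)
        if not p or not Path(p).exists():
            raise ValidationError(f"missing input {name!r}: {p or '(unset)'}")
    state["gm"] = gio.read_vcf(cfg.vcf, outgroup_sample=cfg.outgroup_sample)
    state["groups"] = gio.read_group_map(cfg.groups)
    state["groups"].require_nonempty(("P1", "P2", "P3"))
    state["models"] = gio.read_gene_models(cfg.genes)
    state["recomb"] = gio.read_bedgraph(cfg.recomb)
    state["candidates"] = set(gio.read_gene_list(cfg.candidates))
    for attr in ("male_candidates", "female_candidates"):
        p = getattr(cfg, attr)
        state[attr] = gio.read_gene_list(p) if p else None
    state["alignments"] = (
        read_cds_alignments(cfg.cds_alignments) if cfg.cds_alignments else {}
    )
    return state["gm"].n_sites


def _stage_winstats(cfg: PipelineConfig, outdir: Path, state: dict) -> int:
    gm, groups = state["gm"], state["groups"]
    windows = ws.make_sliding_windows(
        gm.effective_contig_lengths(), cfg.window_size, cfg.step_fraction
    )
    min_sites = cfg.min_sites
    ladder = None if min_sites is not None else ws.DEFAULT_MIN_SITES
    df = ws.windows_table(gm, groups, windows, min_sites=min_sites, ladder=ladder)
    _tsv(df, outdir / "windows.tsv")
    state["windows"] = df
    return len(df)


def _stage_topoweights(cfg: PipelineConfig, outdir: Path, state: dict) -> int:
    gm, groups = state["gm"], state["groups"]
    trees = topo.window_trees(
        gm, groups, snps_per_window=cfg.snps_per_tree, seed=cfg.seed
    )
    weights = [
        topo.topology_weights(t, threshold=cfg.majority_threshold) for t in trees
    ]
    with open(outdir / "trees.nwk", "w") as fh:
        for t in trees:
            fh.write(f"{t.newick}\n")
    wdf = pd.DataFrame(
        {
            "chrom": [t.chrom for t in trees],
            "start": [t.start for t in trees],
            "end": [t.end for t in trees],
            "w1": [w.w1 for w in weights],
            "w2": [w.w2 for w in weights],
            "w3": [w.w3 for w in weights],
            "majority": [w.majority for w in weights],
        }
    )
    _tsv(wdf, outdir / "topology_weights.tsv")
    segs = topo.weights_to_segments(trees, weights, threshold=cfg.majority_threshold)
    with open(outdir / "topology_segments.bed", "w") as fh:
        for s in segs:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.label}\t{s.support:.6g}\n")
    props = topo.genome_proportions_bootstrap(
        list(zip(wdf.chrom, wdf.start, wdf.end, wdf.majority)),
        block=cfg.block_size,
        reps=cfg.bootstrap_reps,
        seed=cfg.seed,
    )
    pdf = pd.DataFrame(
        [
            {"label": l, "percent": v["estimate"], "ci_lo": v["lo"], "ci_hi": v["hi"]}
            for l, v in props.items()
        ]
    )
    _tsv(pdf, outdir / "topology_proportions.tsv")
    bytopo = topo.dxy_by_topology(gm, groups, trees, weights, purity=cfg.purity)
    rows = [
        {"chrom": seg.chrom, "start": seg.start, "end": seg.end,
         "label": lbl, "dxy": val}
        for lbl, pairs in bytopo.items()
        for seg, val in pairs
    ]
    _tsv(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "dxy"]),
        outdir / "dxy_by_topology.tsv",
    )
    state["trees"] = trees
    state["weights"] = weights
    state["weights_df"] = wdf
    state["proportions"] = props
    return len(trees)


def gene_topology_weights(
    model: gio.GeneModel,
    weights_df: pd.DataFrame,
    flank: int = 5_000,
) -> tuple[float, float, float]:
    """Mean topology weights of tree windows overlapping the gene window;
    equal weights when nothing overlaps."""
    w = ws.gene_window(model, flank=flank)
    sel = weights_df[
        (weights_df.chrom == w.chrom)
        & (weights_df.end > w.start)
        & (weights_df.start < w.end)
    ]
    if len(sel) == 0:
        return (1 / 3, 1 / 3, 1 / 3)
    return (float(sel.w1.mean()), float(sel.w2.mean()), float(sel.w3.mean()))


def _stage_dnds(cfg: PipelineConfig, outdir: Path, state: dict) -> int:
    alns = state["alignments"]
    rows = []
    omegas: dict[str, float] = {}
    wdf = state["weights_df"]
    for gene_id in sorted(alns):
        aln = alns[gene_id]
        model = state["models"].get(gene_id)
        gw = (
            gene_topology_weights(model, wdf, flank=cfg.flank)
            if model is not None
            else (1 / 3, 1 / 3, 1 / 3)
        )
        per = {}
        for lbl in ("topo1", "topo2", "topo3"):
            per[lbl] = ce.dnds_exclusion(ce.branch_dnds(aln, topology=lbl))
        wbar = ce.weighted_dnds(per, gw)
        if wbar is not None:
            omegas[gene_id] = wbar
        rows.append(
            {
                "gene_id": gene_id,
                **{
                    f"{k}_{lbl}": getattr(per[lbl], k)
                    for lbl in per
                    for k in ("dn", "ds")
                },
                "w1": gw[0],
                "w2": gw[1],
                "w3": gw[2],
                "omega_bar": math.nan if wbar is None else wbar,
                "excluded": all(p.excluded for p in per.values()),
                "reason": ";".join(
                    sorted({p.reason for p in per.values() if p.reason})
                ),
            }
        )
    df = pd.DataFrame(rows)
    _tsv(df, outdir / "dnds.tsv")
    state["omega"] = omegas
    return len(df)


def _stage_genescan(cfg: PipelineConfig, outdir: Path, state: dict) -> int:
    gm, groups = state["gm"], state["groups"]
    if not Path(cfg.recomb).exists():
        raise ValidationError(f"missing input recomb: {cfg.recomb}")
    sd = ws.SiteData(gm, groups)
    lengths = gm.effective_contig_lengths()
    rows = []
    for gene_id in sorted(state["models"]):
        model = state["models"][gene_id]
        w = ws.gene_window(model, flank=cfg.flank, chrom_length=lengths.get(model.chrom))
        st = ws.window_stats(gm, groups, w, sd=sd)
        rate = gio.mean_rate_in_interval(state["recomb"], w.chrom, w.start, w.end)
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "n_sites": st.window.n_usable_sites,
                "recomb_rate": math.nan if rate is None else rate,
                **{
                    k: (math.nan if getattr(st, k) is None else getattr(st, k))
                    for k in GENE_STATS
                },
                "omega": state.get("omega", {}).get(gene_id, math.nan),
                "candidate": gene_id in state["candidates"],
            }
        )
    df = pd.DataFrame(rows)
    _tsv(df, outdir / "genescan.tsv")
    state["genescan"] = df
    return len(df)


def _stage_outliers(cfg: PipelineConfig, outdir: Path, state: dict) -> int:
    df = state["genescan"]
    calls: list[osc.OutlierCall] = []
    regress_rows = []
    for stat in GENE_STATS:
        try:
            fit = osc.fit_rate_regression(
                df.gene_id, df[stat], df.recomb_rate, statistic=stat
            )
        except ValidationError as exc:
            log.warning("skipping regression for %s: %s", stat, exc)
            continue
        regress_rows.append(
            {
                "statistic": stat,
                "n": fit.n,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r2": fit.r2,
                "slope_p": fit.slope_p,
                "mean_cooksd": float(fit.cooksd.mean()),
            }
        )
        calls.extend(
            osc.call_cooksd_outliers(
                fit, direction=cfg.directions.get(stat), k=cfg.cooksd_k
            )
        )
    try:
        calls.extend(
            osc.call_quantile_outliers(df.gene_id, df.omega, q=cfg.dnds_q)
        )
    except ValidationError as exc:
        log.warning("skipping dN/dS quantile rule: %s", exc)

    odf = pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "statistic": c.statistic,
                "rule": c.rule,
                "is_outlier": c.is_outlier,
                "direction": c.direction,
                "value": c.value,
                "fitted": math.nan if c.fitted is None else c.fitted,
                "cooksd": math.nan if c.cooksd is None else c.cooksd,
            }
            for c in calls
        ]
    )
    _tsv(odf, outdir / "outliers.tsv")
    _tsv(pd.DataFrame(regress_rows), outdir / "regressions.tsv")

    # enrichment of outliers within the candidate set
    out_genes = set(odf[odf.is_outlier].gene_id) if len(odf) else set()
    cand = df.candidate.to_numpy()
    outflag = df.gene_id.isin(out_genes).to_numpy()
    enrich_rows = []
    try:
        stat, p, table = osc.enrichment_chisq(
            outflag, cand, correction=cfg.chisq_correction
        )
        enrich_rows.append(
            {
                "set": "any_statistic",
                "chi2": stat,
                "p": p,
                "candidate_outliers": int(table[0, 0]),
                "candidate_total": int(table[0].sum()),
                "background_outliers": int(table[1, 0]),
                "background_total": int(table[1].sum()),
            }
        )
    except ValidationError as exc:
        log.warning("enrichment test skipped: %s", exc)
    _tsv(pd.DataFrame(enrich_rows), outdir / "enrichment.tsv")
    state["outliers"] = odf
    return len(odf)


def _stage_permtest(cfg: PipelineConfig, outdir: Path, state: dict) -> int:
    df = state["genescan"]
    rows = []
    stats = list(GENE_STATS) + ["omega"]
    rng = np.random.default_rng(cfg.seed)
    for stat in stats:
        tail = cfg.tails.get(stat, "two-sided")
        sub = df[np.isfinite(df[stat])]
        try:
            res = osc.permutation_mean_diff(
                sub[stat],
                sub.candidate,
                n_perm=cfg.n_perm,
                tail=tail,
                seed=int(rng.integers(2**31)),
            )
        except ValidationError as exc:
            log.warning("permutation for %s skipped: %s", stat, exc)
            continue
        rows.append(
            {
                "contrast": "candidate_vs_background",
                "statistic": stat,
                "tail": tail,
                "observed_diff": res.observed,
                "p": res.p_value,
                "p_add_one": res.p_value_add_one,
                "n_candidate": res.n_candidate,
                "n_background": res.n_background,
            }
        )
    male, female = state.get("male_candidates"), state.get("female_candidates")
    if male and female:
        for stat in stats:
            values = {
                g: v
                for g, v in zip(df.gene_id, df[stat])
                if np.isfinite(v)
            }
            try:
                res = osc.male_female_contrast(
                    values, male, female, n_perm=cfg.n_perm,
                    seed=int(rng.integers(2**31)),
                )
            except ValidationError as exc:
                log.warning("male/female contrast for %s skipped: %s", stat, exc)
                continue
            rows.append(
                {
                    "contrast": "male_vs_female",
                    "statistic": stat,
                    "tail": "two-sided",
                    "observed_diff": res.observed,
                    "p": res.p_value,
                    "p_add_one": res.p_value_add_one,
                    "n_candidate": res.n_candidate,
                    "n_background": res.n_background,
                }
            )
    pdf = pd.DataFrame(rows)
    _tsv(pdf, outdir / "permutations.tsv")
    state["permutations"] = pdf
    return len(pdf)


_STAGE_FUNCS = {
    "load": _stage_load,
    "winstats": _stage_winstats,
    "topoweights": _stage_topoweights,
    "dnds": _stage_dnds,
    "genescan": _stage_genescan,
    "outliers": _stage_outliers,
    "permtest": _stage_permtest,
}


# ---------------------------------------------------------------------------
# Consequence classification (standalone helper used by the CLI)
# ---------------------------------------------------------------------------


def extract_cds_sequence(ref_seq: str, model: gio.GeneModel) -> str:
    """Spliced coding-strand CDS from a chromosome reference string."""
    parts = [ref_seq[s:e] for s, e in model.cds]
    seq = "".join(parts)
    if model.strand == "-":
        seq = seq[::-1].translate(str.maketrans("ACGTacgt", "TGCAtgca"))
    return seq


def consequence_table(
    gm: gio.GenotypeMatrix,
    models: dict[str, gio.GeneModel],
    ref_seqs: dict[str, str],
) -> pd.DataFrame:
    """Classify every SNP that falls inside an annotated CDS."""
    rows = []
    for gene_id in sorted(models):
        model = models[gene_id]
        if not model.cds or model.chrom not in ref_seqs:
            continue
        cds_seq = extract_cds_sequence(ref_seqs[model.chrom], model)
        lo, hi = model.cds[0][0], model.cds[-1][1]
        mask = gm.region_mask(model.chrom, lo, hi)
        for j in np.nonzero(mask)[0]:
            cls = ce.classify_consequence(
                int(gm.pos[j] - 1), str(gm.ref[j]), str(gm.alt[j]), model, cds_seq
            )
            if cls == "noncoding":
                continue
            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": model.chrom,
                    "pos": int(gm.pos[j]),
                    "ref": str(gm.ref[j]),
                    "alt": str(gm.alt[j]),
                    "consequence": cls,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "pos", "ref", "alt", "consequence"]
    )
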