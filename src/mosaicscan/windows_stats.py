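"""Sliding and gene-anchored windows and the per-window statistics.

Statistics: nucleotide diversity (pi), absolute divergence (D_XY), a
Hudson-type ratio-of-averages F_ST, Patterson's D, and the signed,
dynamic-donor introgression fraction f_dM (positive = excess P2/P3
sharing, negative = excess P1/P3 sharing). Sites are polarized on the
haploid outgroup allele, so the outgroup derived frequency is 0 by
construction; sites with a missing outgroup allele are skipped for the
polarized statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mosaicscan.errors import ConfigurationError, ValidationError
from mosaicscan.genomic_io import GenotypeMatrix, GroupMap

#: window size (bp) -> minimum usable sites
DEFAULT_MIN_SITES = {
    5_000: 10,
    25_000: 50,
    50_000: 100,
    100_000: 200,
    500_000: 1_000,
    1_000_000: 2_000,
}

STAT_COLUMNS = (
    "pi",
    "dxy_P3_P1",
    "dxy_P3_P2",
    "fst_P3_P1",
    "fst_P3_P2",
    "D",
    "fdm",
)


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    end: int
    n_usable_sites: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"window end <= start: {self}")


@dataclass
class SitePatternSums:
    """Accumulated ABBA/BABA pattern terms over the polarized sites of a
    window, plus the two dynamic-donor denominators of f_dM."""

    abba: float = 0.0
    baba: float = 0.0
    denom_pos: float = 0.0
    denom_neg: float = 0.0
    n_sites: int = 0


@dataclass
class WindowStat:
    window: Window
    pi: float | None = None
    dxy_P3_P1: float | None = None
    dxy_P3_P2: float | None = None
    fst_P3_P1: float | None = None
    fst_P3_P2: float | None = None
    D: float | None = None
    fdm: float | None = None


# ---------------------------------------------------------------------------
# Window construction
# ---------------------------------------------------------------------------


def make_sliding_windows(
    chrom_lengths: Mapping[str, int],
    size: int,
    step_fraction: float = 0.2,
) -> list[Window]:
    """Overlapping windows of ``size`` bp with step = round(size * frac).

    Only windows fully contained in a chromosome are emitted.
    """
    if size <= 0:
        raise ValidationError("window size must be positive")
    if not 0 < step_fraction <= 1:
        raise ValidationError("step_fraction must be in (0, 1]")
    step = max(1, round(size * step_fraction))
    out = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start + size <= length:
            out.append(Window(chrom, start, start + size))
            start += step
    return out


def gene_window(
    model, flank: int = 5_000, chrom_length: int | None = None
) -> Window:
    """The smallest span containing all of a gene's transcripts, extended
    by ``flank`` bp each side and clipped at 0 / chromosome end."""
    s, e = model.span()
    s = max(0, s - flank)
    e = e + flank
    if chrom_length is not None:
        e = min(e, chrom_length)
    return Window(model.chrom, s, e)


def apply_min_sites(
    stat: WindowStat,
    window_size: int | None = None,
    threshold: int | None = None,
    ladder: Mapping[int, int] = DEFAULT_MIN_SITES,
) -> WindowStat:
    """Blank all statistics when the window has too few usable sites."""
    if threshold is None:
        if window_size is None:
            window_size = stat.window.end - stat.window.start
        if window_size not in ladder:
            raise ConfigurationError(
                f"no min-sites threshold configured for window size {window_size}"
            )
        threshold = ladder[window_size]
    if stat.window.n_usable_sites < threshold:
        return replace(
            stat, **{name: None for name in STAT_COLUMNS}
        )
    return stat


# ---------------------------------------------------------------------------
# Per-site arrays
# ---------------------------------------------------------------------------


class SiteData:
    """Per-site allele counts and derived frequencies for the three P
    groups, precomputed once per genotype matrix."""

    def __init__(self, gm: GenotypeMatrix, groups: GroupMap) -> None:
        groups.require_nonempty(("P1", "P2", "P3"))
        self.gm = gm
        self.groups = groups
        self.ac = {}
        self.an = {}
        for g in ("P1", "P2", "P3"):
            idx = [gm.sample_index(s) for s in groups.samples_in(g) if s in gm.samples]
            if not idx:
                raise ValidationError(f"group {g} has no samples in the matrix")
            sub = gm.genotypes[idx]
            called = sub >= 0
            self.an[g] = 2 * called.sum(axis=0)
            self.ac[g] = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.palt = {
                g: np.where(self.an[g] > 0, self.ac[g] / np.maximum(self.an[g], 1), np.nan)
                for g in ("P1", "P2", "P3")
            }
        self.out = gm.outgroup
        # derived allele frequency: flip where the outgroup carries ALT
        self.pder = {
            g: np.where(self.out == 1, 1.0 - self.palt[g], self.palt[g])
            for g in ("P1", "P2", "P3")
        }
        self.pattern_usable = (
            (self.out >= 0)
            & (self.an["P1"] > 0)
            & (self.an["P2"] > 0)
            & (self.an["P3"] > 0)
        )
        # contiguous index range per chromosome (matrix is sorted)
        self._ranges: dict[str, tuple[int, int]] = {}
        start = 0
        for i in range(1, gm.n_sites + 1):
            if i == gm.n_sites or gm.chrom[i] != gm.chrom[start]:
                self._ranges[gm.chrom[start]] = (start, i)
                start = i

    def window_slice(self, w: Window) -> np.ndarray:
        rng = self._ranges.get(w.chrom)
        if rng is None:
            return np.zeros(0, dtype=np.intp)
        a, b = rng
        pos = self.gm.pos[a:b]
        lo = np.searchsorted(pos, w.start + 1, side="left")
        hi = np.searchsorted(pos, w.end, side="right")
        return np.arange(a + lo, a + hi, dtype=np.intp)


def _sites_in(gm: GenotypeMatrix, w: Window) -> np.ndarray:
    return np.nonzero(gm.region_mask(w.chrom, w.start, w.end))[0]


def _group_counts(gm: GenotypeMatrix, groups: GroupMap, group: str, sites: np.ndarray):
    idx = [gm.sample_index(s) for s in groups.samples_in(group) if s in gm.samples]
    if not idx:
        raise ValidationError(f"group {group} has no samples in the matrix")
    sub = gm.genotypes[np.ix_(idx, sites)]
    called = sub >= 0
    an = 2 * called.sum(axis=0)
    ac = np.where(called, sub, 0).sum(axis=0)
    return ac, an


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def nucleotide_diversity(
    gm: GenotypeMatrix,
    groups: GroupMap,
    w: Window,
    group: str = "P3",
    sites: np.ndarray | None = None,
) -> float | None:
    """Unbiased per-site heterozygosity averaged over usable sites:
    mean of 2p(1-p) * n/(n-1) over sites with >= 2 called alleles."""
    if sites is None:
        sites = _sites_in(gm, w)
    ac, an = _group_counts(gm, groups, group, sites)
    use = an >= 2
    if not use.any():
        return None
    p = ac[use] / an[use]
    n = an[use]
    return float(np.sum(2 * p * (1 - p) * n / (n - 1)) / use.sum())


def dxy(
    gm: GenotypeMatrix,
    groups: GroupMap,
    w: Window,
    group_a: str = "P3",
    group_b: str = "P1",
    sites: np.ndarray | None = None,
) -> float | None:
    """Mean pairwise between-group difference per usable site."""
    if sites is None:
        sites = _sites_in(gm, w)
    ac_a, an_a = _group_counts(gm, groups, group_a, sites)
    ac_b, an_b = _group_counts(gm, groups, group_b, sites)
    use = (an_a >= 1) & (an_b >= 1)
    if not use.any():
        return None
    pa = ac_a[use] / an_a[use]
    pb = ac_b[use] / an_b[use]
    return float(np.sum(pa * (1 - pb) + pb * (1 - pa)) / use.sum())


def fst(
    gm: GenotypeMatrix,
    groups: GroupMap,
    w: Window,
    group_a: str = "P3",
    group_b: str = "P1",
    sites: np.ndarray | None = None,
) -> float | None:
    """Hudson-type ratio of averages: 1 - mean(Hw)/mean(Hb) over usable
    variable sites, with n/(n-1)-corrected within-group heterozygosity."""
    if sites is None:
        sites = _sites_in(gm, w)
    ac_a, an_a = _group_counts(gm, groups, group_a, sites)
    ac_b, an_b = _group_counts(gm, groups, group_b, sites)
    use = (an_a >= 2) & (an_b >= 2)
    if not use.any():
        return None
    pa, na = ac_a[use] / an_a[use], an_a[use]
    pb, nb = ac_b[use] / an_b[use], an_b[use]
    hw = (2 * pa * (1 - pa) * na / (na - 1) + 2 * pb * (1 - pb) * nb / (nb - 1)) / 2
    hb = pa * (1 - pb) + pb * (1 - pa)
    var = (hw > 0) | (hb > 0)
    if not var.any() or hb[var].sum() == 0:
        return None
    return float(1 - hw[var].sum() / hb[var].sum())


def site_pattern_sums(
    sd_or_gm, groups: GroupMap | None = None, w: Window | None = None
) -> SitePatternSums:
    """Accumulate ABBA/BABA and f_dM denominator terms over the polarized,
    fully represented sites of a window.

    Accepts either a precomputed :class:`SiteData` or a
    (GenotypeMatrix, GroupMap) pair.
    """
    if isinstance(sd_or_gm, SiteData):
        sd = sd_or_gm
    else:
        sd = SiteData(sd_or_gm, groups)
    if w is None:
        raise ValidationError("window required")
    sites = sd.window_slice(w)
    use = sites[sd.pattern_usable[sites]]
    s = SitePatternSums()
    if len(use) == 0:
        return s
    p1 = sd.pder["P1"][use]
    p2 = sd.pder["P2"][use]
    p3 = sd.pder["P3"][use]
    abba = (1 - p1) * p2 * p3
    baba = p1 * (1 - p2) * p3
    pd_ = np.maximum(p2, p3)
    pg = np.maximum(p1, p3)
    s.abba = float(abba.sum())
    s.baba = float(baba.sum())
    # donor = max(p2,p3) substituted in the P2 and P3 slots
    s.denom_pos = float(((1 - p1) * pd_ * pd_ - p1 * (1 - pd_) * pd_).sum())
    # donor = max(p1,p3) substituted in the P1 and P3 slots (sign flipped)
    s.denom_neg = float((pg * (1 - p2) * pg - (1 - pg) * p2 * pg).sum())
    s.n_sites = int(len(use))
    return s


def patterson_D(s: SitePatternSums) -> float | None:
    tot = s.abba + s.baba
    if tot <= 0:
        return None
    return (s.abba - s.baba) / tot


def fdm(s: SitePatternSums) -> float | None:
    """Signed dynamic-donor admixture fraction in [-1, 1].

    The denominator substitutes the higher of (p2, p3) as donor when the
    ABBA-BABA numerator is non-negative, and the higher of (p1, p3) when
    it is negative. The ratio is clamped into [-1, 1]; summed dynamic
    denominators do not bound the numerator in all corner cases.
    """
    num = s.abba - s.baba
    denom = s.denom_pos if num >= 0 else s.denom_neg
    if denom <= 0:
        return None
    return float(min(1.0, max(-1.0, num / denom)))


# ---------------------------------------------------------------------------
# Window tables
# ---------------------------------------------------------------------------


def window_stats(
    gm: GenotypeMatrix,
    groups: GroupMap,
    w: Window,
    sd: SiteData | None = None,
) -> WindowStat:
    """All seven per-window statistics plus the usable-site count.

    ``n_usable_sites`` counts polarized sites with at least one called
    allele in every P group (the sites feeding D and f_dM).
    """
    if sd is None:
        sd = SiteData(gm, groups)
    s = site_pattern_sums(sd, w=w)
    win = Window(w.chrom, w.start, w.end, n_usable_sites=s.n_sites)
    sites = sd.window_slice(w)
    return WindowStat(
        window=win,
        pi=nucleotide_diversity(gm, groups, w, "P3", sites=sites),
        dxy_P3_P1=dxy(gm, groups, w, "P3", "P1", sites=sites),
        dxy_P3_P2=dxy(gm, groups, w, "P3", "P2", sites=sites),
        fst_P3_P1=fst(gm, groups, w, "P3", "P1", sites=sites),
        fst_P3_P2=fst(gm, groups, w, "P3", "P2", sites=sites),
        D=patterson_D(s),
        fdm=fdm(s),
    )


def windows_table(
    gm: GenotypeMatrix,
    groups: GroupMap,
    windows: Sequence[Window],
    min_sites: int | None = None,
    ladder: Mapping[int, int] | None = None,
) -> pd.DataFrame:
    """Statistics table for many windows; missing values become NaN."""
    sd = SiteData(gm, groups)
    rows = []
    for w in windows:
        st = window_stats(gm, groups, w, sd=sd)
        if min_sites is not None or ladder is not None:
            st = apply_min_sites(
                st,
                threshold=min_sites,
                ladder=ladder or DEFAULT_MIN_SITES,
            )
        rows.append(
            {
                "chrom": st.window.chrom,
                "start": st.window.start,
                "end": st.window.end,
                "n_sites": st.window.n_usable_sites,
                **{
                    name: (math.nan if getattr(st, name) is None else getattr(st, name))
                    for name in STAT_COLUMNS
                },
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites", *STAT_COLUMNS]
    )


def write_windows_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
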