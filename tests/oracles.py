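"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written as plain loops over haplotypes/sites/pairs,
deliberately sharing no code with the package implementations.
"""

from __future__ import annotations

import itertools

import numpy as np


def haplotypes_of(gm, sample):
    """All consistent haplotype pairs are ambiguous; for oracle purposes
    genotype counts are enough, so return the allele count vector."""
    return gm.genotypes[gm.samples.index(sample)]


def group_freqs_site(gm, groups, group, j):
    """(alt frequency, called allele count) for one site, by naive loop."""
    ac = an = 0
    for s in groups.samples_in(group):
        if s not in gm.samples:
            continue
        g = gm.genotypes[gm.samples.index(s), j]
        if g >= 0:
            ac += int(g)
            an += 2
    return (ac / an if an else np.nan), an


def naive_pi(gm, groups, group, lo, hi, chrom):
    """Mean over usable sites of unbiased heterozygosity, via explicit
    allele-pair counting."""
    tot = 0.0
    n_use = 0
    for j in range(gm.n_sites):
        if gm.chrom[j] != chrom or not (lo < gm.pos[j] <= hi):
            continue
        alleles = []
        for s in groups.samples_in(group):
            g = gm.genotypes[gm.samples.index(s), j]
            if g >= 0:
                alleles += [1] * int(g) + [0] * (2 - int(g))
        n = len(alleles)
        if n < 2:
            continue
        n_use += 1
        diffs = sum(a != b for a, b in itertools.combinations(alleles, 2))
        tot += diffs / (n * (n - 1) / 2)
    return tot / n_use if n_use else None


def naive_dxy(gm, groups, ga, gb, lo, hi, chrom):
    """Mean between-group allele-pair difference per usable site."""
    tot = 0.0
    n_use = 0
    for j in range(gm.n_sites):
        if gm.chrom[j] != chrom or not (lo < gm.pos[j] <= hi):
            continue
        aa, bb = [], []
        for s in groups.samples_in(ga):
            g = gm.genotypes[gm.samples.index(s), j]
            if g >= 0:
                aa += [1] * int(g) + [0] * (2 - int(g))
        for s in groups.samples_in(gb):
            g = gm.genotypes[gm.samples.index(s), j]
            if g >= 0:
                bb += [1] * int(g) + [0] * (2 - int(g))
        if not aa or not bb:
            continue
        n_use += 1
        tot += sum(a != b for a in aa for b in bb) / (len(aa) * len(bb))
    return tot / n_use if n_use else None


def naive_fst(gm, groups, ga, gb, lo, hi, chrom):
    """Hudson ratio-of-averages with n/(n-1)-corrected Hw, direct form."""
    hw_sum = hb_sum = 0.0
    any_site = False
    for j in range(gm.n_sites):
        if gm.chrom[j] != chrom or not (lo < gm.pos[j] <= hi):
            continue
        pa, na = group_freqs_site(gm, groups, ga, j)
        pb, nb = group_freqs_site(gm, groups, gb, j)
        if na < 2 or nb < 2:
            continue
        hw = (2 * pa * (1 - pa) * na / (na - 1) + 2 * pb * (1 - pb) * nb / (nb - 1)) / 2
        hb = pa * (1 - pb) + pb * (1 - pa)
        if hw == 0 and hb == 0:
            continue
        any_site = True
        hw_sum += hw
        hb_sum += hb
    if not any_site or hb_sum == 0:
        return None
    return 1 - hw_sum / hb_sum


def naive_patterns(gm, groups, lo, hi, chrom):
    """Per-site loop over ABBA/BABA terms and dynamic-donor denominators."""
    abba = baba = dpos = dneg = 0.0
    n = 0
    for j in range(gm.n_sites):
        if gm.chrom[j] != chrom or not (lo < gm.pos[j] <= hi):
            continue
        if gm.outgroup[j] < 0:
            continue
        ps = {}
        ok = True
        for grp in ("P1", "P2", "P3"):
            p, an = group_freqs_site(gm, groups, grp, j)
            if an < 1:
                ok = False
                break
            ps[grp] = p if gm.outgroup[j] == 0 else 1 - p
        if not ok:
            continue
        n += 1
        p1, p2, p3 = ps["P1"], ps["P2"], ps["P3"]
        abba += (1 - p1) * p2 * p3
        baba += p1 * (1 - p2) * p3
        d = max(p2, p3)
        dpos += (1 - p1) * d * d - p1 * (1 - d) * d
        g = max(p1, p3)
        dneg += g * (1 - p2) * g - (1 - g) * p2 * g
    return abba, baba, dpos, dneg, n


def naive_D(abba, baba):
    if abba + baba == 0:
        return None
    return (abba - baba) / (abba + baba)


def naive_fdm(abba, baba, dpos, dneg):
    num = abba - baba
    den = dpos if num >= 0 else dneg
    if den <= 0:
        return None
    return max(-1.0, min(1.0, num / den))


def loo_cooks_distance(x, y):
    """Cook's distance by literal leave-one-out refitting:
    D_i = sum_j (yhat_j - yhat_j(i))^2 / (p * s^2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)

    def ols(xs, ys):
        sxx = ((xs - xs.mean()) ** 2).sum()
        b = ((xs - xs.mean()) * (ys - ys.mean())).sum() / sxx
        a = ys.mean() - b * xs.mean()
        return a, b

    a, b = ols(x, y)
    yhat = a + b * x
    s2 = ((y - yhat) ** 2).sum() / (n - 2)
    out = np.zeros(n)
    for i in range(n):
        keep = np.arange(n) != i
        ai, bi = ols(x[keep], y[keep])
        yhat_i = ai + bi * x
        out[i] = ((yhat - yhat_i) ** 2).sum() / (2 * s2)
    return out


def chisq_closed_form(table):
    """Pearson chi-square via literal sum((O-E)^2/E)."""
    table = np.asarray(table, float)
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    expected = rowsum * colsum / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def rle_labels(labels):
    """Run-length encoding of a label sequence."""
    out = []
    for l in labels:
        if out and out[-1][0] == l:
            out[-1][1] += 1
        else:
            out.append([l, 1])
    return [(l, c) for l, c in out]


def random_genotype_matrix(rng, n_samples=10, n_sites=20, miss=0.05, chrom="chr1"):
    """A random biallelic matrix with haploid outgroup column."""
    from mosaicscan.genomic_io import GenotypeMatrix

    g = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    g[rng.random((n_samples, n_sites)) < miss] = -1
    out = rng.integers(0, 2, size=n_sites).astype(np.int8)
    out[rng.random(n_sites) < miss] = -1
    pos = np.sort(rng.choice(np.arange(1, 100_000), size=n_sites, replace=False))
    nts = np.array(list("ACGT"))
    ref = nts[rng.integers(0, 4, n_sites)]
    alt = nts[(np.searchsorted(nts, ref) + rng.integers(1, 4, n_sites)) % 4]
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n_samples)],
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=pos.astype(np.int64),
        ref=ref.astype(object),
        alt=alt.astype(object),
        genotypes=g,
        outgroup=out,
    )
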