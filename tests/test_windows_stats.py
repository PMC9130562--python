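import numpy as np
import pytest

from mosaicscan import windows_stats as ws
from mosaicscan.errors import ConfigurationError, ValidationError
from mosaicscan.genomic_io import GenotypeMatrix, GroupMap

import oracles


def matrix_from_columns(genotypes, outgroup, pos=None, samples=None):
    """Build a matrix from a (n_samples, n_sites) list of lists."""
    g = np.array(genotypes, dtype=np.int8)
    n_samples, n_sites = g.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 10
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        samples=samples,
        chrom=np.full(n_sites, "chr1", dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "G", dtype=object),
        genotypes=g,
        outgroup=np.asarray(outgroup, dtype=np.int8),
    )


WIN = ws.Window("chr1", 0, 100_000)


# ---------------------------------------------------------------------------
# Window construction
# ---------------------------------------------------------------------------


class TestSlidingWindows:
    def test_example_enumeration(self):
        wins = ws.make_sliding_windows({"chr1": 100_000}, 50_000, 0.2)
        assert [w.start for w in wins] == [0, 10_000, 20_000, 30_000, 40_000, 50_000]
        assert all(w.end - w.start == 50_000 for w in wins)

    def test_chromosome_shorter_than_window(self):
        assert ws.make_sliding_windows({"chr1": 40_000}, 50_000) == []

    def test_step_fraction_one_tiles(self):
        wins = ws.make_sliding_windows({"chr1": 150_000}, 50_000, 1.0)
        assert [(w.start, w.end) for w in wins] == [
            (0, 50_000),
            (50_000, 100_000),
            (100_000, 150_000),
        ]

    def test_empty_map(self):
        assert ws.make_sliding_windows({}, 50_000) == []

    def test_bad_args(self):
        with pytest.raises(ValidationError):
            ws.make_sliding_windows({"c": 100}, 0)
        with pytest.raises(ValidationError):
            ws.make_sliding_windows({"c": 100}, 10, 0.0)


class TestGeneWindow:
    class Model:
        def __init__(self, transcripts, chrom="chr1"):
            self.transcripts = transcripts
            self.chrom = chrom

        def span(self):
            return (
                min(s for s, _ in self.transcripts),
                max(e for _, e in self.transcripts),
            )

    def test_union_plus_flank(self):
        m = self.Model([(10_000, 15_000), (12_000, 20_000)])
        w = ws.gene_window(m, flank=5_000)
        assert (w.start, w.end) == (5_000, 25_000)

    def test_boundary_clip(self):
        m = self.Model([(2_000, 3_000)])
        w = ws.gene_window(m, flank=5_000)
        assert (w.start, w.end) == (0, 8_000)

    def test_zero_flank_identity(self):
        m = self.Model([(2_000, 3_000)])
        w = ws.gene_window(m, flank=0)
        assert (w.start, w.end) == (2_000, 3_000)


class TestMinSites:
    def stat(self, n):
        return ws.WindowStat(window=ws.Window("chr1", 0, 50_000, n), pi=0.1, D=0.5)

    def test_50kb_below_threshold_blanked(self):
        out = ws.apply_min_sites(self.stat(99), window_size=50_000)
        assert out.pi is None and out.D is None

    def test_50kb_at_threshold_kept(self):
        out = ws.apply_min_sites(self.stat(100), window_size=50_000)
        assert out.pi == 0.1

    def test_5kb_ladder_entry(self):
        st = ws.WindowStat(window=ws.Window("chr1", 0, 5_000, 10), pi=0.2)
        assert ws.apply_min_sites(st, window_size=5_000).pi == 0.2

    def test_ladder_values(self):
        assert ws.DEFAULT_MIN_SITES == {
            5_000: 10,
            25_000: 50,
            50_000: 100,
            100_000: 200,
            500_000: 1_000,
            1_000_000: 2_000,
        }

    def test_unknown_size_without_threshold(self):
        with pytest.raises(ConfigurationError):
            ws.apply_min_sites(self.stat(5), window_size=12_345)


# ---------------------------------------------------------------------------
# pi / dxy / fst
# ---------------------------------------------------------------------------


class TestPi:
    def test_monomorphic_window_zero(self, ten_sample_groups):
        gm = matrix_from_columns(np.full((10, 5), 2), [0] * 5)
        assert ws.nucleotide_diversity(gm, ten_sample_groups, WIN) == 0.0

    def test_single_het_site(self):
        # one diploid sample: het at 1 of 10 usable sites -> 0.1
        groups = GroupMap({"s0": "P3"})
        g = [[0] * 10]
        g[0][3] = 1
        gm = matrix_from_columns(g, [0] * 10)
        assert ws.nucleotide_diversity(gm, groups, WIN, "P3") == pytest.approx(0.1)

    def test_matches_all_pairs_oracle(self, rng, ten_sample_groups):
        for _ in range(10):
            gm = oracles.random_genotype_matrix(rng, 10, 20)
            got = ws.nucleotide_diversity(gm, ten_sample_groups, WIN, "P3")
            want = oracles.naive_pi(gm, ten_sample_groups, "P3", 0, 100_000, "chr1")
            assert got == pytest.approx(want, abs=1e-12)


class TestDxy:
    def test_identical_fixed_sequences(self, ten_sample_groups):
        gm = matrix_from_columns(np.full((10, 6), 2), [0] * 6)
        assert ws.dxy(gm, ten_sample_groups, WIN, "P3", "P1") == 0.0

    def test_alternate_fixation_2_of_10(self, ten_sample_groups):
        g = np.zeros((10, 10), dtype=int)
        g[6:9, 0] = 2  # P3 fixed ALT at sites 0, 1
        g[6:9, 1] = 2
        gm = matrix_from_columns(g, [0] * 10)
        assert ws.dxy(gm, ten_sample_groups, WIN, "P3", "P1") == pytest.approx(0.2)

    def test_matches_pair_oracle(self, rng, ten_sample_groups):
        for _ in range(10):
            gm = oracles.random_genotype_matrix(rng, 10, 20)
            for other in ("P1", "P2"):
                got = ws.dxy(gm, ten_sample_groups, WIN, "P3", other)
                want = oracles.naive_dxy(
                    gm, ten_sample_groups, "P3", other, 0, 100_000, "chr1"
                )
                assert got == pytest.approx(want, abs=1e-12)


class TestFst:
    def test_equal_frequencies_near_zero(self, ten_sample_groups):
        # all samples het everywhere: sample frequencies equal (0.5);
        # the n/(n-1) correction leaves a small negative residue bounded
        # by 1/(n_min-1)
        gm = matrix_from_columns(np.full((10, 8), 1), [0] * 8)
        got = ws.fst(gm, ten_sample_groups, WIN, "P3", "P1")
        assert got == pytest.approx(0.0, abs=1 / 3)
        assert got < 0  # exact zero is unattainable with corrected Hw

    def test_alternate_fixation_gives_one(self, ten_sample_groups):
        g = np.zeros((10, 4), dtype=int)
        g[6:9] = 2
        gm = matrix_from_columns(g, [0] * 4)
        assert ws.fst(gm, ten_sample_groups, WIN, "P3", "P1") == pytest.approx(1.0)

    def test_closed_form_10_haplotypes(self):
        # two groups of 10 haplotypes (5 diploids), p = 0.2 vs 0.8
        groups = GroupMap({f"a{i}": "P3" for i in range(5)} | {f"b{i}": "P1" for i in range(5)})
        ga = [[1, ], [1], [0], [0], [0]]  # 2/10 alt
        gb = [[2], [2], [2], [1], [1]]  # 8/10 alt
        gm = matrix_from_columns(
            np.array(ga + gb), [0], samples=[f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        )
        hw = (2 * 0.2 * 0.8 * 10 / 9 + 2 * 0.8 * 0.2 * 10 / 9) / 2
        hb = 0.2 * 0.2 + 0.8 * 0.8
        assert ws.fst(gm, groups, WIN, "P3", "P1") == pytest.approx(1 - hw / hb)

    def test_matches_oracle(self, rng, ten_sample_groups):
        for _ in range(10):
            gm = oracles.random_genotype_matrix(rng, 10, 20)
            got = ws.fst(gm, ten_sample_groups, WIN, "P3", "P1")
            want = oracles.naive_fst(
                gm, ten_sample_groups, "P3", "P1", 0, 100_000, "chr1"
            )
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=1e-12)


# ---------------------------------------------------------------------------
# Site patterns, D, f_dM
# ---------------------------------------------------------------------------


def patterns_for(p1, p2, p3, out=0):
    """One site with the requested derived frequencies using 2 diploids
    per P group (frequencies in quarters)."""

    def geno(p):
        # two diploids carrying 4 alleles total
        alt = round(p * 4)
        return [min(2, alt), max(0, alt - 2)]

    groups = GroupMap(
        {"a0": "P1", "a1": "P1", "b0": "P2", "b1": "P2", "c0": "P3", "c1": "P3"}
    )
    col = geno(p1) + geno(p2) + geno(p3)
    gm = matrix_from_columns(
        np.array([[v] for v in col]),
        [out],
        samples=["a0", "a1", "b0", "b1", "c0", "c1"],
    )
    return gm, groups


class TestSitePatterns:
    def test_no_derived_alleles_contribute_zero(self):
        gm, groups = patterns_for(0, 0, 0)
        s = ws.site_pattern_sums(gm, groups, WIN)
        assert s.abba == s.baba == 0.0
        assert s.n_sites == 1

    def test_direct_formula_evaluation(self):
        gm, groups = patterns_for(0, 0.5, 0.5)
        s = ws.site_pattern_sums(gm, groups, WIN)
        assert s.abba == pytest.approx(0.25)
        assert s.baba == pytest.approx(0.0)

    def test_missing_outgroup_skipped(self):
        gm, groups = patterns_for(0, 0.5, 0.5, out=-1)
        s = ws.site_pattern_sums(gm, groups, WIN)
        assert s.n_sites == 0

    def test_polarization_flips_on_alt_outgroup(self):
        # outgroup carries ALT -> derived = REF
        gm, groups = patterns_for(1, 0.5, 0.5, out=1)
        s = ws.site_pattern_sums(gm, groups, WIN)
        # derived freqs: p1 = 0, p2 = 0.5, p3 = 0.5
        assert s.abba == pytest.approx(0.25)


class TestPattersonD:
    def test_symmetric_sums_zero(self):
        assert ws.patterson_D(ws.SitePatternSums(abba=3, baba=3)) == 0.0

    def test_bound(self):
        assert ws.patterson_D(ws.SitePatternSums(abba=5, baba=0)) == 1.0

    def test_zero_denominator_missing(self):
        assert ws.patterson_D(ws.SitePatternSums()) is None

    def test_matches_per_site_loop(self, rng, ten_sample_groups):
        for _ in range(10):
            gm = oracles.random_genotype_matrix(rng, 10, 20)
            s = ws.site_pattern_sums(gm, ten_sample_groups, WIN)
            abba, baba, dpos, dneg, n = oracles.naive_patterns(
                gm, ten_sample_groups, 0, 100_000, "chr1"
            )
            assert s.n_sites == n
            assert s.abba == pytest.approx(abba, abs=1e-12)
            assert s.baba == pytest.approx(baba, abs=1e-12)
            got = ws.patterson_D(s)
            want = oracles.naive_D(abba, baba)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=1e-12)


class TestFdm:
    def test_full_sharing_gives_one(self):
        gm, groups = patterns_for(0, 1, 1)
        s = ws.site_pattern_sums(gm, groups, WIN)
        assert ws.fdm(s) == pytest.approx(1.0)

    def test_p1_equals_p2_everywhere_gives_zero(self, rng):
        groups = GroupMap(
            {"a0": "P1", "a1": "P1", "b0": "P2", "b1": "P2", "c0": "P3", "c1": "P3"}
        )
        cols = []
        for _ in range(12):
            ga = [int(rng.integers(0, 3)), int(rng.integers(0, 3))]
            gc = [int(rng.integers(0, 3)), int(rng.integers(0, 3))]
            cols.append(ga + ga + gc)
        gm = matrix_from_columns(
            np.array(cols).T,
            [0] * 12,
            samples=["a0", "a1", "b0", "b1", "c0", "c1"],
        )
        s = ws.site_pattern_sums(gm, groups, WIN)
        val = ws.fdm(s)
        assert val is None or val == pytest.approx(0.0, abs=1e-12)

    def test_swapping_p1_p2_flips_sign(self, rng):
        for _ in range(10):
            gm = oracles.random_genotype_matrix(rng, 10, 20, miss=0)
            groups = GroupMap(
                {f"s{i}": g for i, g in enumerate("P1 P1 P2 P2 P2 P2 P3 P3 P3 OUT".split())}
            )
            swapped = GroupMap(
                {f"s{i}": g for i, g in enumerate("P2 P2 P1 P1 P1 P1 P3 P3 P3 OUT".split())}
            )
            a = ws.fdm(ws.site_pattern_sums(gm, groups, WIN))
            b = ws.fdm(ws.site_pattern_sums(gm, swapped, WIN))
            if a is None or b is None:
                assert a is None and b is None
            else:
                assert a == pytest.approx(-b, abs=1e-12)

    def test_matches_oracle(self, rng, ten_sample_groups):
        for _ in range(20):
            gm = oracles.random_genotype_matrix(rng, 10, 20)
            s = ws.site_pattern_sums(gm, ten_sample_groups, WIN)
            abba, baba, dpos, dneg, _ = oracles.naive_patterns(
                gm, ten_sample_groups, 0, 100_000, "chr1"
            )
            got = ws.fdm(s)
            want = oracles.naive_fdm(abba, baba, dpos, dneg)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=1e-12)


# ---------------------------------------------------------------------------
# Invariants
# ---------------------------------------------------------------------------


class TestInvariants:
    def test_bounds_on_random_windows(self, rng, ten_sample_groups):
        for _ in range(100):
            gm = oracles.random_genotype_matrix(rng, 10, 15)
            st = ws.window_stats(gm, ten_sample_groups, WIN)
            if st.D is not None:
                assert -1 <= st.D <= 1
            if st.fdm is not None:
                assert -1 <= st.fdm <= 1
            if st.pi is not None:
                assert st.pi >= 0
            for name in ("dxy_P3_P1", "dxy_P3_P2"):
                v = getattr(st, name)
                if v is not None:
                    assert v >= 0
            for name in ("fst_P3_P1", "fst_P3_P2"):
                v = getattr(st, name)
                if v is not None:
                    assert v <= 1

    def test_d_and_fdm_share_sign(self, rng, ten_sample_groups):
        for _ in range(50):
            gm = oracles.random_genotype_matrix(rng, 10, 15)
            s = ws.site_pattern_sums(gm, ten_sample_groups, WIN)
            d = ws.patterson_D(s)
            f = ws.fdm(s)
            if d is None or f is None:
                continue
            assert d * f >= 0 or abs(d) < 1e-12 or abs(f) < 1e-12

    def test_windows_table_shape_and_na(self, rng, ten_sample_groups):
        gm = oracles.random_genotype_matrix(rng, 10, 40)
        wins = ws.make_sliding_windows({"chr1": 100_000}, 50_000, 1.0)
        df = ws.windows_table(gm, ten_sample_groups, wins, min_sites=1_000)
        assert list(df.columns) == [
            "chrom", "start", "end", "n_sites", *ws.STAT_COLUMNS,
        ]
        # min_sites 1000 can never be met with 40 SNPs -> all NaN
        assert df[list(ws.STAT_COLUMNS)].isna().all().all()
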