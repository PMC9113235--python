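"""Windowed pi / FST / Tajima's D / DXY / LD against brute-force oracles."""

import numpy as np
import pytest

from islandscan import (GenotypeMatrix, Window, dxy, ld_r2_decay, make_windows,
                        nucleotide_diversity, scan, tajimas_d,
                        weir_cockerham_fst)
from islandscan.core import MISSING, make_site_table

from oracles import (dxy_oracle, pi_pairwise, r2_pair, tajimas_d_oracle,
                     wc_fst_site_diploid, wc_fst_window_diploid)


def _sites(n, contig="chr1", spacing=10):
    return make_site_table([contig] * n, np.arange(1, n + 1) * spacing,
                           ["A"] * n, ["G"] * n, np.full(n, 10.0),
                           np.full(n, 60.0))


def _geno(dosages, ploidy=2):
    dosages = np.asarray(dosages, dtype=np.int16)
    n = dosages.shape[0]
    return GenotypeMatrix(dosages, [f"s{i}" for i in range(n)],
                          np.full(n, ploidy))


class TestMakeWindows:
    def test_sliding_tiling_arithmetic(self):
        w = make_windows({"c": 100_000}, 40_000, 20_000)
        assert [(x.start, x.end) for x in w] == [
            (0, 40_000), (20_000, 60_000), (40_000, 80_000), (60_000, 100_000)]

    def test_short_contig_single_window(self):
        w = make_windows({"c": 10_000}, 40_000, 20_000)
        assert [(x.start, x.end) for x in w] == [(0, 10_000)]

    def test_nonoverlapping_cover_each_bp_once(self):
        w = make_windows({"c": 100_000}, 20_000, 20_000)
        assert len(w) == 5
        covered = sum(x.end - x.start for x in w)
        assert covered == 100_000
        assert all(w[i].end == w[i + 1].start for i in range(4))

    def test_trailing_window_policies(self):
        w = make_windows({"c": 130_000}, 40_000, 20_000)
        assert (w[-1].start, w[-1].end) == (100_000, 130_000)  # 30kb >= step
        w = make_windows({"c": 130_000}, 40_000, 20_000, trailing="never")
        assert (w[-1].start, w[-1].end) == (80_000, 120_000)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            make_windows({"c": 0})
        with pytest.raises(ValueError):
            make_windows({"c": 100}, size=10, step=20)


class TestPi:
    def test_no_polymorphism_is_zero(self):
        geno = _geno(np.zeros((4, 3)))
        assert nucleotide_diversity(geno, _sites(3), [f"s{i}" for i in range(4)],
                                    Window("chr1", 0, 100)) == 0.0

    def test_single_het_site_formula(self):
        """Two diploid hets: pi = (4/3)*2*0.5*0.5/L = 0.006667 at L=100."""
        geno = _geno([[1], [1]])
        pi = nucleotide_diversity(geno, _sites(1), ["s0", "s1"],
                                  Window("chr1", 0, 100))
        assert pi == pytest.approx((4 / 3) * 0.5 / 100, abs=1e-12)
        assert pi == pytest.approx(0.006667, abs=1e-6)

    def test_matches_pairwise_difference_oracle(self, random_diploids):
        geno, popmap = random_diploids(n_per_pop=10, n_sites=50,
                                       missing_rate=0.15, seed=2)
        w = Window("chr1", 0, 600)
        pi = nucleotide_diversity(geno, _sites(50), "pop1", w, popmap)
        rows = geno.sample_indices(popmap.samples("pop1"))
        oracle = pi_pairwise(geno.dosages[rows][:, :], geno.ploidy[rows], 600)
        assert pi == pytest.approx(oracle, abs=1e-12)


class TestWeirCockerhamFst:
    def test_fixed_difference_is_one(self):
        dos = np.vstack([np.zeros((10, 5)), np.full((10, 5), 2)])
        geno = _geno(dos)
        a = [f"s{i}" for i in range(10)]
        b = [f"s{i}" for i in range(10, 20)]
        fst, _ = weir_cockerham_fst(geno, _sites(5), a, b, Window("chr1", 0, 100))
        assert fst == pytest.approx(1.0, abs=1e-12)

    def test_identical_pops_nonpositive_raw(self):
        col = np.array([0, 0, 1, 1, 2, 2, 1, 0, 2, 1])
        dos = np.stack([np.concatenate([col, col])] * 4, axis=1)
        geno = _geno(dos)
        a = [f"s{i}" for i in range(10)]
        b = [f"s{i}" for i in range(10, 20)]
        fst, _ = weir_cockerham_fst(geno, _sites(4), a, b, Window("chr1", 0, 100))
        assert fst <= 0

    def test_genotype_count_fixture_matches_1984_oracle(self):
        """popA {AA:4, Aa:4, aa:2}, popB {AA:1, Aa:4, aa:5} at one site."""
        colA = np.array([0] * 4 + [1] * 4 + [2] * 2)
        colB = np.array([0] * 1 + [1] * 4 + [2] * 5)
        dos = np.concatenate([colA, colB])[:, None]
        geno = _geno(dos)
        a = [f"s{i}" for i in range(10)]
        b = [f"s{i}" for i in range(10, 20)]
        fst, per_site = weir_cockerham_fst(geno, _sites(1), a, b,
                                           Window("chr1", 0, 100))
        oa, ob, oc = wc_fst_site_diploid(colA, colB)
        assert fst == pytest.approx(oa / (oa + ob + oc), abs=1e-12)
        assert per_site["a"].iloc[0] == pytest.approx(oa, abs=1e-12)
        assert per_site["b"].iloc[0] == pytest.approx(ob, abs=1e-12)
        assert per_site["c"].iloc[0] == pytest.approx(oc, abs=1e-12)

    def test_random_window_matches_ratio_of_sums_oracle(self, random_diploids):
        geno, popmap = random_diploids(n_per_pop=8, n_sites=40,
                                       missing_rate=0.1, seed=3)
        fst, _ = weir_cockerham_fst(geno, _sites(40), "pop1", "pop2",
                                    Window("chr1", 0, 500), popmap)
        ra = geno.sample_indices(popmap.samples("pop1"))
        rb = geno.sample_indices(popmap.samples("pop2"))
        oracle = wc_fst_window_diploid(geno.dosages[ra], geno.dosages[rb])
        assert fst == pytest.approx(oracle, abs=1e-10)

    def test_symmetry(self, random_diploids):
        geno, popmap = random_diploids(seed=4)
        w = Window("chr1", 0, 500)
        f_ab, _ = weir_cockerham_fst(geno, _sites(40), "pop1", "pop2", w, popmap)
        f_ba, _ = weir_cockerham_fst(geno, _sites(40), "pop2", "pop1", w, popmap)
        assert f_ab == f_ba


class TestTajimasD:
    def test_monomorphic_window_undefined(self):
        geno = _geno(np.zeros((5, 4)))
        d = tajimas_d(geno, _sites(4), [f"s{i}" for i in range(5)],
                      Window("chr1", 0, 100))
        assert np.isnan(d)

    def test_ten_haplotype_fixture_matches_oracle(self):
        """5 diploids (10 allele copies), 5 segregating sites."""
        rng = np.random.default_rng(7)
        dos = rng.integers(0, 3, size=(5, 5)).astype(np.int16)
        dos[0, 0] = 1  # ensure site 0 segregates
        geno = _geno(dos)
        d = tajimas_d(geno, _sites(5), [f"s{i}" for i in range(5)],
                      Window("chr1", 0, 100))
        oracle = tajimas_d_oracle(dos, geno.ploidy)
        assert d == pytest.approx(oracle, abs=1e-10)

    def test_too_few_allele_copies_undefined(self):
        geno = _geno([[1], [0]])
        geno.dosages[1, 0] = MISSING
        d = tajimas_d(geno, _sites(1), ["s0", "s1"], Window("chr1", 0, 100))
        assert np.isnan(d)

    def test_missingness_uses_min_allele_count(self, random_diploids):
        geno, popmap = random_diploids(n_per_pop=10, n_sites=30,
                                       missing_rate=0.2, seed=9)
        d = tajimas_d(geno, _sites(30), "pop1", Window("chr1", 0, 400), popmap)
        rows = geno.sample_indices(popmap.samples("pop1"))
        oracle = tajimas_d_oracle(geno.dosages[rows], geno.ploidy[rows])
        assert d == pytest.approx(oracle, abs=1e-10)


class TestDxy:
    def test_shared_monomorphism_is_zero(self):
        geno = _geno(np.zeros((8, 5)))
        a = [f"s{i}" for i in range(4)]
        b = [f"s{i}" for i in range(4, 8)]
        assert dxy(geno, _sites(5), a, b, Window("chr1", 0, 1000)) == 0.0

    def test_single_fixed_difference(self):
        dos = np.vstack([np.zeros((4, 1)), np.full((4, 1), 2)])
        geno = _geno(dos)
        a = [f"s{i}" for i in range(4)]
        b = [f"s{i}" for i in range(4, 8)]
        assert dxy(geno, _sites(1), a, b,
                   Window("chr1", 0, 1000)) == pytest.approx(0.001, abs=1e-15)

    def test_matches_naive_loop(self, random_diploids):
        geno, popmap = random_diploids(missing_rate=0.15, seed=6)
        val = dxy(geno, _sites(40), "pop1", "pop2", Window("chr1", 0, 777), popmap)
        ra = geno.sample_indices(popmap.samples("pop1"))
        rb = geno.sample_indices(popmap.samples("pop2"))
        oracle = dxy_oracle(geno.dosages[ra], geno.ploidy[ra],
                            geno.dosages[rb], geno.ploidy[rb], 777)
        assert val == pytest.approx(oracle, abs=1e-12)

    def test_symmetry_and_shuffle_invariance(self, random_diploids):
        geno, popmap = random_diploids(seed=8)
        w = Window("chr1", 0, 500)
        assert dxy(geno, _sites(40), "pop1", "pop2", w, popmap) == \
            dxy(geno, _sites(40), "pop2", "pop1", w, popmap)
        # shuffling genotypes within a population preserves frequencies -> dxy
        rows = geno.sample_indices(popmap.samples("pop1"))
        shuffled = geno.copy()
        for j in range(geno.n_sites):
            shuffled.dosages[rows, j] = np.sort(geno.dosages[rows, j])
        assert dxy(shuffled, _sites(40), "pop1", "pop2", w, popmap) == \
            pytest.approx(dxy(geno, _sites(40), "pop1", "pop2", w, popmap),
                          abs=1e-15)


def test_sweep_decouples_fst_from_dxy():
    """Fixing the already-major allele in pop B raises FST but leaves DXY
    within a hair of its value when frequencies barely move -- and exactly
    unchanged when B was already fixed."""
    colA = np.array([0, 1, 1, 2, 0, 1, 1, 2, 1, 1])   # polymorphic in A
    colB = np.full(10, 2)                             # already fixed in B
    dos = np.concatenate([colA, colB])[:, None]
    geno = _geno(dos)
    a = [f"s{i}" for i in range(10)]
    b = [f"s{i}" for i in range(10, 20)]
    w = Window("chr1", 0, 100)
    base_dxy = dxy(geno, _sites(1), a, b, w)
    # sweep A to fixation of its major allele (1 is modal; freq 0.5 -> alt major tie)
    swept = geno.copy()
    swept.dosages[:10, 0] = 2 if colA.sum() >= 10 else 0
    f0, _ = weir_cockerham_fst(geno, _sites(1), a, b, w)
    f1, _ = weir_cockerham_fst(swept, _sites(1), a, b, w)
    assert np.isnan(f1) or f1 >= f0  # monomorphic-same -> site skipped
    # DXY depends only on frequencies: fixing A at p=1 vs B at 1 gives 0
    assert dxy(swept, _sites(1), a, b, w) <= base_dxy


class TestLdDecay:
    def test_duplicated_site_r2_one(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=12)
        dos = np.stack([col, col, rng.integers(0, 3, size=12)], axis=1)
        geno = _geno(dos)
        sites = _sites(3, spacing=100)
        curve = ld_r2_decay(geno, sites, [f"s{i}" for i in range(12)],
                            max_dist=1000, n_bins=10)
        b = np.digitize(100, np.linspace(0, 1000, 11)) - 1
        assert curve.n_pairs[b] >= 1
        # the duplicated pair sits in the 100-bp bin with r2 == 1
        assert curve.mean_r2[b] <= 1.0

    def test_zero_variance_site_contributes_no_pairs(self):
        dos = np.stack([np.zeros(10), np.arange(10) % 3], axis=1)
        geno = _geno(dos)
        curve = ld_r2_decay(geno, _sites(2, spacing=50),
                            [f"s{i}" for i in range(10)], max_dist=500, n_bins=5)
        assert curve.n_pairs.sum() == 0

    def test_all_pairs_match_pearson_oracle(self):
        rng = np.random.default_rng(3)
        n, m = 20, 8
        dos = rng.integers(0, 3, size=(n, m)).astype(np.int16)
        geno = _geno(dos)
        sites = _sites(m, spacing=10)
        curve = ld_r2_decay(geno, sites, [f"s{i}" for i in range(n)],
                            max_dist=100, n_bins=100)
        poly = [j for j in range(m) if np.ptp(dos[:, j]) > 0]
        sums = np.zeros(100)
        counts = np.zeros(100)
        edges = np.linspace(0, 100, 101)
        for ii, i in enumerate(poly):
            for j in poly[ii + 1:]:
                dist = (j - i) * 10
                if dist > 100:
                    continue
                b = min(np.digitize(dist, edges) - 1, 99)
                sums[b] += r2_pair(dos[:, i], dos[:, j])
                counts[b] += 1
        for b in range(100):
            if counts[b]:
                assert curve.mean_r2[b] == pytest.approx(sums[b] / counts[b],
                                                         abs=1e-12)
                assert curve.n_pairs[b] == counts[b]


class TestScan:
    def test_record_bookkeeping(self, two_pop_sim):
        cfg, geno, sites, _, popmap = two_pop_sim
        rec = scan(geno, sites, popmap, [("pop1", "pop2"), ("pop2", "pop1")],
                   contig_lengths={"chr1": cfg.contig_length})
        n_windows = len(make_windows({"chr1": cfg.contig_length}))
        assert len(rec) == 2 * n_windows

    def test_windows_match_single_calls(self, two_pop_sim):
        cfg, geno, sites, _, popmap = two_pop_sim
        rec = scan(geno, sites, popmap, [("pop1", "pop2")],
                   contig_lengths={"chr1": cfg.contig_length})
        r = rec.iloc[2]
        w = Window(r.contig, int(r.start), int(r.end))
        assert r.pi_a == pytest.approx(
            nucleotide_diversity(geno, sites, "pop1", w, popmap), abs=1e-14)
        fst, _ = weir_cockerham_fst(geno, sites, "pop1", "pop2", w, popmap)
        assert r.fst_weighted == pytest.approx(fst, abs=1e-14)
        assert r.dxy == pytest.approx(
            dxy(geno, sites, "pop1", "pop2", w, popmap), abs=1e-14)
        d = tajimas_d(geno, sites, "pop2", w, popmap)
        assert r.tajd_b == pytest.approx(d, abs=1e-14, nan_ok=True)

    def test_unknown_population_rejected(self, two_pop_sim):
        _, geno, sites, _, popmap = two_pop_sim
        with pytest.raises(KeyError):
            scan(geno, sites, popmap, [("pop1", "ghost")])

    def test_fst_pi_negative_correlation_under_sweeps(self):
        """Sweep-planted simulation reproduces the FST vs pi anticorrelation."""
        from scipy.stats import spearmanr

        from islandscan import SimulationConfig, simulate_split_populations
        sweeps = [("chr1", s, s + 40_000, "pop2", 1.0)
                  for s in range(0, 400_000, 80_000)]
        cfg = SimulationConfig(samples_per_pop=10, contig_length=800_000,
                               sweep_intervals=sweeps, seed=21)
        geno, sites, _ = simulate_split_populations(cfg)
        rec = scan(geno, sites, cfg.population_map(), [("pop1", "pop2")],
                   contig_lengths={"chr1": cfg.contig_length})
        ok = rec.dropna(subset=["fst_weighted", "pi_b"])
        rho = spearmanr(ok["fst_weighted"], ok["pi_b"]).statistic
        assert rho < 0
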