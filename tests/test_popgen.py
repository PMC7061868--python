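"""Window construction and the core statistics against independent oracles."""

import numpy as np
import pytest

import popsweep as ps
from popsweep.popgen import WindowSpec
from popsweep.variants import MISSING

from conftest import brute_force_pi, make_gm, random_gm, tajimas_d_reference


class TestMakeWindows:
    def test_enumeration(self):
        w = ps.make_windows({"chr1": 250_000})
        assert len(w) == 16
        assert list(w["start"][:3]) == [1, 10_001, 20_001]
        assert w["start"].iloc[-1] == 150_001
        assert (w["end"] - w["start"] + 1 == 100_000).all()

    @pytest.mark.parametrize("length,n", [(99_999, 0), (100_000, 1)])
    def test_boundaries(self, length, n):
        w = ps.make_windows({"chr1": length})
        assert len(w) == n
        if n:
            assert (w["start"].iloc[0], w["end"].iloc[0]) == (1, 100_000)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            WindowSpec(10_000, 20_000)


class TestWindowPi:
    def test_monomorphic_window_is_zero(self):
        gm = make_gm(np.zeros((4, 5), dtype=np.int8))
        assert ps.window_pi(gm, ("chr1", 1, 1000), "H") == 0.0

    def test_single_segregating_site_closed_form(self):
        # 4 allele copies, p = 0.5 -> (4/3) * 2 * 0.25 / 1000
        gm = make_gm([[1], [1]], populations={"s0": "H", "s1": "H"})
        pi = ps.window_pi(gm, ("chr1", 1, 1000), "H")
        assert pi == pytest.approx((4 / 3) * 0.5 / 1000, abs=1e-15)

    def test_matches_brute_force_pairwise_oracle(self, rng):
        for _ in range(20):
            gm = random_gm(rng, n_samples=5, n_sites=20, missing_rate=0.2)
            rows = gm.sample_indices("H")
            window = ("chr1", 1, 100_000)
            expected = brute_force_pi(gm.calls[rows], 100_000)
            assert ps.window_pi(gm, window, "H") == pytest.approx(
                expected, abs=1e-12)

    def test_fewer_than_two_samples_undefined(self):
        gm = make_gm([[1], [1]], populations={"s0": "H", "s1": "S"})
        assert np.isnan(ps.window_pi(gm, ("chr1", 1, 1000), "H"))


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        gm = make_gm(np.zeros((3, 4), dtype=np.int8),
                     populations=dict.fromkeys([f"s{i}" for i in range(3)], "H"))
        assert np.isnan(ps.window_tajimas_d(gm, ("chr1", 1, 1000), "H"))

    def test_single_singleton_matches_reference_formula(self):
        # n = 4 copies, one singleton site: pi_sum = (4/3)*2*(1/4)*(3/4) = 0.5
        gm = make_gm([[1, 0], [0, 0]],
                     populations={"s0": "H", "s1": "H"})
        expected = tajimas_d_reference(0.5, 1, 4)
        got = ps.window_tajimas_d(gm, ("chr1", 1, 1000), "H")
        assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_reference_on_constructed_sfs(self):
        # 10 copies (5 diploids); construct sites at chosen allele counts
        for counts in ([1, 1, 1, 1], [5, 5, 5], [1, 2, 5, 8, 9]):
            sites = []
            for c in counts:
                copies = [1] * c + [0] * (10 - c)
                sites.append([copies[2 * i] + copies[2 * i + 1]
                              for i in range(5)])
            calls = np.array(sites, dtype=np.int8).T
            gm = make_gm(calls,
                         populations=dict.fromkeys(
                             [f"s{i}" for i in range(5)], "H"))
            pi_sum = brute_force_pi(calls, 1)
            expected = tajimas_d_reference(pi_sum, len(counts), 10)
            got = ps.window_tajimas_d(gm, ("chr1", 1, 100_000), "H")
            assert got == pytest.approx(expected, rel=1e-10)

    def test_sign_follows_frequency_spectrum(self):
        # excess singletons -> D < 0; intermediate-frequency excess -> D > 0
        def gm_from_counts(counts):
            sites = []
            for c in counts:
                copies = [1] * c + [0] * (12 - c)
                sites.append([copies[2 * i] + copies[2 * i + 1]
                              for i in range(6)])
            return make_gm(np.array(sites, dtype=np.int8).T,
                           populations=dict.fromkeys(
                               [f"s{i}" for i in range(6)], "H"))
        w = ("chr1", 1, 100_000)
        assert ps.window_tajimas_d(gm_from_counts([1] * 12), w, "H") < 0
        assert ps.window_tajimas_d(gm_from_counts([6] * 12), w, "H") > 0

    def test_neutral_coalescent_mean_near_zero(self):
        # independent oracle: msprime neutral simulations should average D ~ 0
        import msprime

        vals = []
        for seed in range(1, 41):
            ts = msprime.sim_ancestry(samples=10, sequence_length=50_000,
                                      recombination_rate=1e-8,
                                      population_size=10_000,
                                      random_seed=seed)
            mts = msprime.sim_mutations(ts, rate=2e-8, random_seed=seed)
            if mts.num_sites < 3:
                continue
            geno = mts.genotype_matrix()  # sites x haploid samples
            geno = np.minimum(geno, 1)
            calls = (geno[:, ::2] + geno[:, 1::2]).T.astype(np.int8)
            pos = np.unique(np.array(
                [int(s.position) + 1 for s in mts.sites()]))
            if pos.size != calls.shape[1]:
                continue
            gm = make_gm(calls, pos=pos,
                         populations=dict.fromkeys(
                             [f"s{i}" for i in range(10)], "H"))
            vals.append(ps.window_tajimas_d(gm, ("chr1", 1, 50_000), "H"))
        assert len(vals) >= 25
        assert abs(np.mean(vals)) < 0.45


class TestFst:
    def test_fixed_difference_is_one(self):
        gm = make_gm([[2, 2], [2, 2], [0, 0], [0, 0]])
        assert ps.window_fst(gm, ("chr1", 1, 1000), "H", "S") == pytest.approx(1.0)

    def test_identical_panels_near_zero(self, rng):
        # both populations drawn as identical copies of one frequency panel
        freqs = rng.uniform(0.1, 0.9, 400)
        calls = rng.binomial(2, freqs, size=(12, 400)).astype(np.int8)
        gm = make_gm(calls)
        fst = ps.genome_fst(gm, "H", "S")
        assert abs(fst) < 0.02

    def test_single_site_closed_form(self):
        # pop1: dosages (2,1) -> p1=3/4, n1=4; pop2: (1,0,0) -> p2=1/6, n2=6
        # Hudson: num = (7/12)^2 - (3/16)/3 - (5/36)/5 = 1/4; den = 2/3
        gm = make_gm([[2], [1], [1], [0], [0]],
                     populations={"s0": "H", "s1": "H",
                                  "s2": "S", "s3": "S", "s4": "S"})
        assert ps.window_fst(gm, ("chr1", 1, 100), "H", "S") == pytest.approx(
            0.375, abs=1e-12)

    def test_weir_cockerham_agrees_on_balanced_clean_data(self, rng):
        freq_a = rng.uniform(0.1, 0.9, 2000)
        freq_b = np.clip(freq_a + rng.normal(0, 0.25, 2000), 0.01, 0.99)
        calls = np.vstack([
            rng.binomial(2, freq_a, size=(10, 2000)),
            rng.binomial(2, freq_b, size=(10, 2000)),
        ]).astype(np.int8)
        gm = make_gm(calls)
        hudson = ps.genome_fst(gm, "H", "S", "hudson")
        wc = ps.genome_fst(gm, "H", "S", "weir-cockerham")
        assert hudson == pytest.approx(wc, abs=0.03)

    def test_no_usable_sites_undefined(self):
        gm = make_gm([[0], [0], [0], [0]])
        assert np.isnan(ps.window_fst(gm, ("chr1", 1, 100), "H", "S"))

    def test_unknown_estimator(self):
        gm = make_gm([[1], [0], [1], [0]])
        with pytest.raises(ValueError):
            ps.genome_fst(gm, "H", "S", "nei")


class TestDiversityRatio:
    def test_simple_ratio(self):
        r, flag = ps.diversity_ratio(0.4, 0.1)
        assert r == pytest.approx(4.0) and not flag

    def test_zero_denominator_capped_and_flagged(self):
        r, flag = ps.diversity_ratio(0.4, 0.0)
        assert r == 100.0 and flag

    def test_zero_over_zero_undefined(self):
        r, _ = ps.diversity_ratio(0.0, 0.0)
        assert np.isnan(r)


class TestWindowStatsTable:
    def test_invariant_under_sample_reordering(self, rng):
        gm = random_gm(rng, n_samples=8, n_sites=60, missing_rate=0.1)
        w = ps.make_windows({"chr1": 100_000}, WindowSpec(100_000, 100_000))
        base = ps.compute_window_stats(gm, w)
        order = rng.permutation(gm.n_samples)
        gm2 = type(gm)(samples=[gm.samples[i] for i in order],
                       populations=dict(gm.populations),
                       chrom=gm.chrom, pos=gm.pos, ref=gm.ref, alt=gm.alt,
                       calls=gm.calls[order])
        again = ps.compute_window_stats(gm2, w)
        for col in ("pi_a", "pi_b", "tajd_a", "tajd_b", "fst"):
            np.testing.assert_allclose(base[col], again[col], rtol=1e-12)

    def test_pi_per_kb_scaling(self, rng):
        gm = random_gm(rng, n_samples=8, n_sites=40, missing_rate=0)
        w = ps.make_windows({"chr1": 100_000}, WindowSpec(100_000, 100_000))
        stats = ps.compute_window_stats(gm, w)
        pi_site = ps.window_pi(gm, ("chr1", 1, 100_000), "H")
        assert stats["pi_a"].iloc[0] == pytest.approx(pi_site)
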