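"""Sweep-region calling: cut-offs, selection rules, merging, annotation,
enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

import popsweep as ps
from popsweep.sweep import (call_candidate_windows, merge_regions,
                            permutation_cutoff, top_fraction_windows,
                            write_regions_bed)

from conftest import make_gm


def stats_frame(values, col="fst", pop_a="H", pop_b="S", **extra):
    n = len(values)
    df = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n) * 10_000 + 1,
        "end": np.arange(n) * 10_000 + 100_000,
        "n_sites": extra.pop("n_sites", 50),
        col: values,
    })
    for k, v in extra.items():
        df[k] = v
    df.attrs["pop_a"] = pop_a
    df.attrs["pop_b"] = pop_b
    return df


class TestTopFraction:
    def test_rank_arithmetic_no_ties(self):
        mask = top_fraction_windows(np.arange(200, dtype=float), 0.05)
        assert mask.sum() == 10
        assert mask[-10:].all()

    def test_all_equal_selects_all(self):
        assert top_fraction_windows(np.ones(30), 0.05).all()

    def test_ceiling_rule_small_n(self):
        assert top_fraction_windows(np.arange(10, dtype=float), 0.05).sum() == 1

    def test_nan_excluded(self):
        v = np.array([np.nan, 1.0, 2.0, np.nan])
        mask = top_fraction_windows(v, 0.5)
        assert not mask[0] and not mask[3] and mask[2]

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            top_fraction_windows(np.ones(5), 1.5)


class TestPermutationCutoff:
    def _null_gm(self, seed, n_sites=400):
        rng = np.random.default_rng(seed)
        freqs = rng.uniform(0.1, 0.9, n_sites)
        calls = rng.binomial(2, freqs, size=(10, n_sites)).astype(np.int8)
        pos = np.sort(rng.choice(400_000, n_sites, replace=False)) + 1
        return make_gm(calls, pos=pos)

    def test_deterministic_given_seed(self):
        gm = self._null_gm(1)
        w = ps.make_windows({"chr1": 400_000})
        a = permutation_cutoff(gm, w, "S", "H", n_perm=20, seed=7)
        b = permutation_cutoff(gm, w, "S", "H", n_perm=20, seed=7)
        assert a == b

    def test_n_perm_guard(self):
        gm = self._null_gm(2)
        w = ps.make_windows({"chr1": 400_000})
        with pytest.raises(ValueError):
            permutation_cutoff(gm, w, "S", "H", n_perm=1)

    def test_single_population_errors(self):
        gm = self._null_gm(3)
        for s in gm.samples:
            gm.populations[s] = "H"
        w = ps.make_windows({"chr1": 400_000})
        with pytest.raises(ValueError):
            permutation_cutoff(gm, w, "S", "H", n_perm=10)


class TestCallCandidates:
    def test_conjunction_required(self):
        df = stats_frame([0.9, 0.1, 0.9], ratio_b_over_a=[5.0, 5.0, 0.5],
                         ratio_a_over_b=[0.2, 0.2, 2.0])
        out = call_candidate_windows(df, 2.0, ("threshold", 0.5))
        # H candidates need ratio(S/H) >= 2 AND fst >= 0.5: only window 0
        assert list(out["H"]["start"]) == [1]
        # high ratio but low FST not called
        assert 10_001 not in list(out["H"]["start"])

    def test_no_window_passes(self):
        df = stats_frame([0.1, 0.1], ratio_b_over_a=[0.5, 0.5],
                         ratio_a_over_b=[0.5, 0.5])
        out = call_candidate_windows(df, 2.0, ("threshold", 0.5))
        assert len(out["H"]) == 0 and len(out["S"]) == 0

    def test_min_snps_masks_windows(self):
        df = stats_frame([0.9, 0.9], ratio_b_over_a=[5.0, 5.0],
                         ratio_a_over_b=[5.0, 5.0], n_sites=5)
        out = call_candidate_windows(df, 2.0, ("threshold", 0.5), min_snps=10)
        assert len(out["H"]) == 0


class TestMergeRegions:
    def test_overlapping_windows_merge(self):
        w = pd.DataFrame({"chrom": ["chr1", "chr1"],
                          "start": [1, 10_001], "end": [100_000, 110_000]})
        out = merge_regions(w, 10_000)
        assert len(out) == 1
        assert (out["start"].iloc[0], out["end"].iloc[0]) == (1, 110_000)

    def test_reported_length_mb(self):
        w = pd.DataFrame({"chrom": ["chr1"], "start": [16_330_001],
                          "end": [42_530_000]})
        out = merge_regions(w, 10_000)
        assert out["length_mb"].iloc[0] == 26.20

    def test_distant_windows_stay_separate(self):
        w = pd.DataFrame({"chrom": ["chr1", "chr1"],
                          "start": [1, 5_000_001], "end": [100_000, 5_100_000]})
        out = merge_regions(w, 10_000)
        assert len(out) == 2

    def test_idempotent_and_conserves_union(self):
        rng = np.random.default_rng(5)
        starts = np.sort(rng.choice(2_000_000, 40, replace=False))
        w = pd.DataFrame({"chrom": "chr1", "start": starts,
                          "end": starts + 99_999})
        merged = merge_regions(w, 0)
        again = merge_regions(merged[["chrom", "start", "end"]], 0)
        pd.testing.assert_frame_equal(merged[["chrom", "start", "end"]],
                                      again[["chrom", "start", "end"]])
        # at gap 0 the merged regions cover exactly the union of the windows
        covered = set()
        for r in w.itertuples():
            covered.update(range(r.start, r.end + 1))
        assert (merged["end"] - merged["start"] + 1).sum() == len(covered)

    def test_empty_input(self):
        assert len(merge_regions(pd.DataFrame(columns=["chrom", "start", "end"]))) == 0

    def test_bed_export_is_zero_based_half_open(self, tmp_path):
        w = pd.DataFrame({"chrom": ["chr1"], "start": [1], "end": [100]})
        out = merge_regions(w, 0, population="H")
        write_regions_bed(out, tmp_path / "r.bed")
        assert (tmp_path / "r.bed").read_text() == "chr1\t0\t100\tH\n"


TOY_GFF = """##gff-version 3
chr1\tsim\tgene\t100\t200\t.\t+\t.\tID=g1
chr1\tsim\tgene\t300\t400\t.\t+\t.\tID=g2
chr1\tsim\tgene\t500\t600\t.\t+\t.\tID=g3
chr1\tsim\tgene\t700\t800\t.\t+\t.\tID=g4
chr2\tsim\tgene\t100\t200\t.\t+\t.\tID=g5
"""


class TestAnnotateRegions:
    def test_interval_overlap_oracle(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [150],
                                "end": [550]})
        out = ps.annotate_regions(regions, TOY_GFF)
        assert out["gene_ids"].iloc[0] == "g1,g2,g3"
        assert out["n_genes"].iloc[0] == 3

    def test_one_bp_boundary_overlap_included(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [200],
                                "end": [250]})
        out = ps.annotate_regions(regions, TOY_GFF)
        assert out["gene_ids"].iloc[0] == "g1"

    def test_unmatched_chromosome_warns_and_counts(self):
        regions = pd.DataFrame({"chrom": ["chrX"], "start": [1], "end": [100]})
        out = ps.annotate_regions(regions, TOY_GFF)
        assert out["n_genes"].iloc[0] == 0
        assert out.attrs["n_unmatched_regions"] == 1


class TestEnrichment:
    def test_exact_combinatorics_smallest_case(self):
        background = {f"g{i}" for i in range(20)}
        pathway = {f"g{i}" for i in range(5)}
        res = ps.enrich_hypergeometric(pathway, background, {"p1": pathway})
        assert res["p"].iloc[0] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_pathway_equals_background_p_one(self):
        background = {f"g{i}" for i in range(10)}
        res = ps.enrich_hypergeometric({"g0", "g1"}, background,
                                       {"all": set(background)})
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_empty_region_set(self):
        res = ps.enrich_hypergeometric(set(), {"g0"}, {"p": {"g0"}})
        assert res.empty

    def test_region_not_subset_errors(self):
        with pytest.raises(ValueError):
            ps.enrich_hypergeometric({"gX"}, {"g0"}, {"p": {"g0"}})

    def test_matches_exact_combinatorial_oracle(self, rng):
        # every instance with N <= 30 against direct enumeration
        for _ in range(20):
            big_n = int(rng.integers(8, 31))
            background = {f"g{i}" for i in range(big_n)}
            n = int(rng.integers(1, big_n))
            region = set(rng.choice(sorted(background), n, replace=False))
            big_k = int(rng.integers(1, big_n + 1))
            pathway = set(rng.choice(sorted(background), big_k, replace=False))
            k = len(pathway & region)
            if k == 0:
                continue
            res = ps.enrich_hypergeometric(region, background,
                                           {"p": pathway}, correction="none")
            expected = sum(
                math.comb(big_k, i) * math.comb(big_n - big_k, n - i)
                for i in range(k, min(big_k, n) + 1)) / math.comb(big_n, n)
            assert res["p"].iloc[0] == pytest.approx(expected, rel=1e-10)

    def test_bh_correction_flags(self):
        background = {f"g{i}" for i in range(30)}
        pmap = {"enriched": {f"g{i}" for i in range(5)},
                "flat": {f"g{i}" for i in range(5, 30)}}
        region = {f"g{i}" for i in range(5)}
        res = ps.enrich_hypergeometric(region, background, pmap)
        enr = res.set_index("pathway")
        assert bool(enr.loc["enriched", "significant"])
        assert res["p_adj"].between(0, 1).all()
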