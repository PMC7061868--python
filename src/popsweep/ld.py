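"""Linkage-disequilibrium decay within chromosomes.

r-squared is the squared Pearson correlation of unphased genotype dosages
(0/1/2) across the samples of one population, computed for every
within-chromosome site pair up to a maximum distance (default 1000 kb) with
pairwise deletion of missing calls.  This composite, genotype-based r2 is
deterministic and phase-free; it differs from haplotype-frequency r2, which
would require phased data or an EM step.

Pairs are binned by physical distance into an :class:`LDCurve`; the
genome-wide curve pools bins over chromosomes, i.e. averages weighted by pair
count.  Decay curves of two populations are compared with a label-permutation
test on the difference of the curves' areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .variants import GenotypeMatrix

__all__ = ["LDCurve", "pairwise_r2", "ld_decay_curve", "ld_decay",
           "compare_ld_decay", "thin_site_index"]

_BLOCK = 1024


@dataclass
class LDCurve:
    """Distance-binned mean r2 for one population.

    ``bins`` has columns ``bin_lo_kb, bin_hi_kb, mean_r2, n_pairs`` (ordered,
    nonoverlapping; empty bins carry NaN mean and zero pairs).
    """

    population: str
    bins: pd.DataFrame
    max_distance_kb: float = 1000.0

    def occupied(self) -> pd.DataFrame:
        return self.bins[self.bins["n_pairs"] > 0].reset_index(drop=True)

    def area(self, bin_mask: np.ndarray | None = None) -> float:
        """Area under the binned curve (sum of mean r2 x bin width, kb) over
        occupied bins, optionally restricted to ``bin_mask``."""
        b = self.bins if bin_mask is None else self.bins[bin_mask]
        b = b[b["n_pairs"] > 0]
        return float(((b["bin_hi_kb"] - b["bin_lo_kb"]) * b["mean_r2"]).sum())

    def write_tsv(self, path: str | Path) -> None:
        self.bins.to_csv(path, sep="\t", index=False)


def thin_site_index(gm: GenotypeMatrix, max_sites_per_chrom: int) -> np.ndarray:
    """Deterministic, evenly spaced site subsample per chromosome."""
    keep: list[np.ndarray] = []
    for c in pd.unique(gm.chrom):
        idx = np.flatnonzero(gm.chrom == c)
        if idx.size > max_sites_per_chrom:
            sel = np.linspace(0, idx.size - 1, max_sites_per_chrom).round()
            idx = idx[np.unique(sel.astype(np.intp))]
        keep.append(idx)
    return np.concatenate(keep) if keep else np.array([], dtype=np.intp)


# ---------------------------------------------------------------------------
# pair engine
# ---------------------------------------------------------------------------

def _block_r2(x_i, m_i, x_j, m_j) -> np.ndarray:
    """Squared correlation for all column pairs of two blocks with pairwise
    deletion; NaN where undefined (monomorphic subsample or <2 shared calls)."""
    n = m_i.T @ m_j
    sx = x_i.T @ m_j
    sy = m_i.T @ x_j
    sxy = x_i.T @ x_j
    sxx = (x_i ** 2).T @ m_j
    syy = m_i.T @ (x_j ** 2)
    cov = n * sxy - sx * sy
    varx = n * sxx - sx ** 2
    vary = n * syy - sy ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = cov ** 2 / (varx * vary)
    r2[(varx <= 0) | (vary <= 0) | (n < 2)] = np.nan
    return r2


def _iter_pair_blocks(gm: GenotypeMatrix, rows: np.ndarray, max_bp: int):
    """Yield (distance_bp, r2) flat arrays for all within-chromosome site
    pairs at distance in (0, max_bp], blockwise."""
    calls = gm.calls[rows].astype(np.float64)
    mask = (calls >= 0).astype(np.float64)
    calls = np.where(mask > 0, calls, 0.0)
    for c in pd.unique(gm.chrom):
        sel = np.flatnonzero(gm.chrom == c)
        pos = gm.pos[sel]
        x = calls[:, sel]
        m = mask[:, sel]
        nb = sel.size
        for i0 in range(0, nb, _BLOCK):
            i1 = min(i0 + _BLOCK, nb)
            j0 = i0
            while j0 < nb and pos[j0] - pos[i1 - 1] <= max_bp:
                j1 = min(j0 + _BLOCK, nb)
                r2 = _block_r2(x[:, i0:i1], m[:, i0:i1], x[:, j0:j1], m[:, j0:j1])
                dist = pos[j0:j1][None, :] - pos[i0:i1][:, None]
                valid = (dist > 0) & (dist <= max_bp) & np.isfinite(r2)
                if valid.any():
                    yield dist[valid].astype(np.int64), r2[valid]
                j0 = j1


def pairwise_r2(gm: GenotypeMatrix, population: str,
                max_distance_kb: float = 1000.0,
                max_sites_per_chrom: int | None = None) -> pd.DataFrame:
    """All within-chromosome (distance_bp, r2) pairs for one population.

    Pairs where either site is monomorphic within the population's samples
    are skipped.  ``max_sites_per_chrom`` applies deterministic thinning
    first (for large cohorts; the binned accumulator :func:`ld_decay` avoids
    materialising pairs altogether).
    """
    rows = gm.sample_indices(population)
    if rows.size < 2:
        raise ValueError(f"population {population!r} needs >= 2 samples")
    if max_sites_per_chrom is not None:
        gm = gm.take_sites(thin_site_index(gm, max_sites_per_chrom))
    max_bp = int(round(max_distance_kb * 1000))
    dists, r2s = [], []
    for d, r in _iter_pair_blocks(gm, rows, max_bp):
        dists.append(d)
        r2s.append(r)
    if not dists:
        return pd.DataFrame(columns=["distance_bp", "r2"])
    return pd.DataFrame({"distance_bp": np.concatenate(dists),
                         "r2": np.concatenate(r2s)})


# ---------------------------------------------------------------------------
# binned curves
# ---------------------------------------------------------------------------

def _empty_bins(bin_width_kb: float, max_distance_kb: float) -> pd.DataFrame:
    n_bins = int(np.ceil(max_distance_kb / bin_width_kb))
    lo = np.arange(n_bins) * bin_width_kb
    return pd.DataFrame({"bin_lo_kb": lo, "bin_hi_kb": lo + bin_width_kb,
                         "mean_r2": np.nan, "n_pairs": 0})


def ld_decay_curve(pairs: pd.DataFrame, bin_width_kb: float = 10.0,
                   max_distance_kb: float = 1000.0,
                   population: str = "") -> LDCurve:
    """Bin raw (distance_bp, r2) pairs into an :class:`LDCurve`."""
    if bin_width_kb <= 0:
        raise ValueError("bin_width_kb must be > 0")
    bins = _empty_bins(bin_width_kb, max_distance_kb)
    if len(pairs):
        d = pairs["distance_bp"].to_numpy()
        bin_bp = int(round(bin_width_kb * 1000))
        keep = d <= max_distance_kb * 1000
        # (lo, hi] bins so boundary distances match the streaming accumulator
        idx = np.minimum((d[keep] - 1) // bin_bp, len(bins) - 1).astype(np.intp)
        r2 = pairs["r2"].to_numpy()[keep]
        sums = np.bincount(idx, weights=r2, minlength=len(bins))
        counts = np.bincount(idx, minlength=len(bins))
        with np.errstate(invalid="ignore", divide="ignore"):
            bins["mean_r2"] = np.where(counts > 0, sums / np.maximum(counts, 1),
                                       np.nan)
        bins["n_pairs"] = counts
    return LDCurve(population=population, bins=bins,
                   max_distance_kb=max_distance_kb)


def _binned_for_rows(gm: GenotypeMatrix, rows: np.ndarray, max_bp: int,
                     bin_bp: int, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for d, r in _iter_pair_blocks(gm, rows, max_bp):
        idx = np.minimum((d - 1) // bin_bp, n_bins - 1)
        sums += np.bincount(idx, weights=r, minlength=n_bins)
        counts += np.bincount(idx, minlength=n_bins)
    return sums, counts


def ld_decay(gm: GenotypeMatrix, population: str,
             bin_width_kb: float = 10.0, max_distance_kb: float = 1000.0,
             max_sites_per_chrom: int | None = None) -> LDCurve:
    """Binned decay curve computed without materialising the pair list;
    bins are pooled over chromosomes (pair-count weighting)."""
    rows = gm.sample_indices(population)
    if rows.size < 2:
        raise ValueError(f"population {population!r} needs >= 2 samples")
    if max_sites_per_chrom is not None:
        gm = gm.take_sites(thin_site_index(gm, max_sites_per_chrom))
    bins = _empty_bins(bin_width_kb, max_distance_kb)
    max_bp = int(round(max_distance_kb * 1000))
    bin_bp = int(round(bin_width_kb * 1000))
    sums, counts = _binned_for_rows(gm, rows, max_bp, bin_bp, len(bins))
    with np.errstate(invalid="ignore", divide="ignore"):
        bins["mean_r2"] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    bins["n_pairs"] = counts
    return LDCurve(population=population, bins=bins,
                   max_distance_kb=max_distance_kb)


# ---------------------------------------------------------------------------
# decay comparison
# ---------------------------------------------------------------------------

def compare_ld_decay(gm: GenotypeMatrix, pop_a: str, pop_b: str,
                     bin_width_kb: float = 10.0, max_distance_kb: float = 1000.0,
                     n_perm: int = 200, seed: int = 0,
                     max_sites_per_chrom: int | None = None) -> dict:
    """Label-permutation test for a difference in LD decay between two
    populations.

    The statistic is the difference of areas under the two binned decay
    curves, restricted to bins occupied in both.  Sample labels are permuted
    across the pooled samples ``n_perm`` times; the two-sided p-value is
    (1 + #{|T_perm| >= |T_obs|}) / (n_perm + 1).  The population with the
    smaller area decays faster.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    rows_a = gm.sample_indices(pop_a)
    rows_b = gm.sample_indices(pop_b)
    if rows_a.size < 2 or rows_b.size < 2:
        raise ValueError("both populations need >= 2 samples")
    if set(rows_a) == set(rows_b):
        raise ValueError("populations share the same samples; comparison undefined")
    if max_sites_per_chrom is not None:
        gm = gm.take_sites(thin_site_index(gm, max_sites_per_chrom))

    max_bp = int(round(max_distance_kb * 1000))
    bin_bp = int(round(bin_width_kb * 1000))
    n_bins = int(np.ceil(max_distance_kb / bin_width_kb))
    width = bin_width_kb

    def stat(rows1, rows2) -> float:
        s1, c1 = _binned_for_rows(gm, rows1, max_bp, bin_bp, n_bins)
        s2, c2 = _binned_for_rows(gm, rows2, max_bp, bin_bp, n_bins)
        both = (c1 > 0) & (c2 > 0)
        if not both.any():
            return np.nan
        return float(((s1[both] / c1[both]) - (s2[both] / c2[both])).sum() * width)

    t_obs = stat(rows_a, rows_b)
    pool = np.concatenate([rows_a, rows_b])
    k = rows_a.size
    rng = np.random.default_rng(seed)
    exceed = 0
    n_valid = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        t = stat(perm[:k], perm[k:])
        if np.isfinite(t):
            n_valid += 1
            if abs(t) >= abs(t_obs):
                exceed += 1
    p = (1 + exceed) / (n_valid + 1) if n_valid else float("nan")
    faster = pop_a if t_obs < 0 else pop_b
    return {"statistic": t_obs, "p_value": p, "faster_decay": faster,
            "n_perm": n_perm, "n_valid_perm": n_valid}
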