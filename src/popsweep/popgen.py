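"""Sliding-window population-genetic statistics.

Implements the scan layer of the divergence analysis: nucleotide diversity
(pi), Tajima's D, FST (Hudson ratio-of-sums by default, Weir-Cockerham
selectable) and the between-population diversity ratio, all over sliding
windows (default 100 kb windows advancing in 10 kb steps).

Everything is computed from per-site allele counts with missing data handled
per site: a site contributes to a population only where at least two allele
copies are callable.  Window aggregation uses prefix sums over the site
arrays, which keeps full-genome scans and label permutations cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import GenotypeMatrix

__all__ = [
    "WindowSpec",
    "make_windows",
    "site_allele_counts",
    "window_pi",
    "window_tajimas_d",
    "window_fst",
    "genome_fst",
    "diversity_ratio",
    "compute_window_stats",
    "tajima_constants",
    "tajimas_d",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: ``size_bp`` windows every ``step_bp``."""

    size_bp: int = 100_000
    step_bp: int = 10_000

    def __post_init__(self) -> None:
        if self.size_bp <= 0 or self.step_bp <= 0:
            raise ValueError("window size and step must be positive")
        if self.step_bp > self.size_bp:
            raise ValueError("step_bp must be <= size_bp")


def make_windows(chrom_lengths: dict[str, int],
                 spec: WindowSpec = WindowSpec()) -> pd.DataFrame:
    """Enumerate fully contained windows per chromosome.

    Windows start at 1, advance by ``step_bp``, and are emitted only when the
    full ``size_bp`` span fits inside the chromosome.  Returns a DataFrame
    with columns ``chrom, start, end`` (1-based inclusive).
    """
    rows: list[tuple[str, int, int]] = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        start = 1
        while start + spec.size_bp - 1 <= length:
            rows.append((chrom, start, start + spec.size_bp - 1))
            start += spec.step_bp
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# per-site building blocks
# ---------------------------------------------------------------------------

def site_allele_counts(gm: GenotypeMatrix, rows: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """(alt-allele count, non-missing allele-copy count) per site for the
    sample rows given (diploids contribute two copies)."""
    calls = gm.calls[rows]
    ok = calls >= 0
    alt = np.where(ok, calls, 0).sum(axis=0).astype(np.int64)
    n = 2 * ok.sum(axis=0).astype(np.int64)
    return alt, n


def _pi_site_terms(alt: np.ndarray, n: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site mean-pairwise-difference contribution and segregating mask.

    The unbiased per-site heterozygosity (n/(n-1)) * 2p(1-p) equals the mean
    pairwise difference among the n sampled allele copies at the site.
    Sites with fewer than two callable copies contribute zero.
    """
    usable = n >= 2
    nf = np.where(usable, n, 2).astype(float)
    p = np.where(usable, alt / np.maximum(n, 1), 0.0)
    contrib = np.where(usable, nf / (nf - 1.0) * 2.0 * p * (1.0 - p), 0.0)
    seg = usable & (alt > 0) & (alt < n)
    return contrib, seg


def _hudson_site_terms(alt1, n1, alt2, n2) -> tuple[np.ndarray, np.ndarray]:
    """Per-site numerator/denominator of Hudson's FST (Bhatia et al. form)."""
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = alt1 / np.maximum(n1, 1)
        p2 = alt2 / np.maximum(n2, 1)
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
               - p2 * (1 - p2) / np.maximum(n2 - 1, 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    return np.where(usable, num, 0.0), np.where(usable, den, 0.0)


def _wc_site_terms(gm: GenotypeMatrix, rows1: np.ndarray, rows2: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site a and a+b+c variance components of the Weir-Cockerham
    two-population estimator (diploid, with observed heterozygosity)."""
    comps = []
    for rows in (rows1, rows2):
        calls = gm.calls[rows]
        ok = calls >= 0
        n_ind = ok.sum(axis=0).astype(float)          # individuals called
        alt = np.where(ok, calls, 0).sum(axis=0)
        het = (calls == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_ind > 0, alt / np.maximum(2 * n_ind, 1), 0.0)
            h = np.where(n_ind > 0, het / np.maximum(n_ind, 1), 0.0)
        comps.append((n_ind, p, h))
    (na, pa, ha), (nb, pb, hb) = comps
    r = 2.0
    usable = (na >= 1) & (nb >= 1) & (na + nb >= 3)
    nbar = (na + nb) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (na ** 2 + nb ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (na * pa + nb * pb) / (r * nbar)
        s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (na * ha + nb * hb) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r
                                 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1.0) / r
                                     - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
        c = hbar / 2.0
    usable &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & (nc > 0)
    a = np.where(usable, a, 0.0)
    abc = np.where(usable, a + np.where(usable, b, 0) + np.where(usable, c, 0), 0.0)
    return a, abc


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """Standard a1, a2, b1, b2, c1, c2, e1, e2 for n allele copies (n >= 3)."""
    if n < 3:
        raise ValueError("Tajima's D needs at least 3 allele copies")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(pi_sum: float, s: int, n: int) -> float:
    """Tajima's D from the summed pairwise diversity, segregating-site count
    and allele-copy count; NaN when undefined (S = 0 or n < 3)."""
    if s <= 0 or n < 3:
        return float("nan")
    k = tajima_constants(n)
    var = k["e1"] * s + k["e2"] * s * (s - 1.0)
    if var <= 0:
        return float("nan")
    return (pi_sum - s / k["a1"]) / np.sqrt(var)


def _tajd_vector(pi_sum: np.ndarray, s: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorised Tajima's D over windows with per-window n."""
    n = np.asarray(n)
    out = np.full(pi_sum.shape, np.nan)
    nmax = int(n.max()) if n.size and n.max() >= 3 else 0
    if nmax < 3:
        return out
    i = np.arange(1, nmax)
    h1 = np.concatenate([[0.0], np.cumsum(1.0 / i)])       # h1[k] = sum_{i<=k} 1/i
    h2 = np.concatenate([[0.0], np.cumsum(1.0 / i ** 2)])
    ok = (s > 0) & (n >= 3)
    nn = np.where(ok, n, 3).astype(np.int64)
    a1 = h1[nn - 1]
    a2 = h2[nn - 1]
    b1 = (nn + 1.0) / (3.0 * (nn - 1.0))
    b2 = 2.0 * (nn ** 2 + nn + 3.0) / (9.0 * nn * (nn - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (nn + 2.0) / (a1 * nn) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * s + e2 * s * (s - 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (pi_sum - s / a1) / np.sqrt(var)
    out[ok & (var > 0)] = d[ok & (var > 0)]
    return out


# ---------------------------------------------------------------------------
# window aggregation
# ---------------------------------------------------------------------------

def _window_sums(gm: GenotypeMatrix, windows: pd.DataFrame,
                 values: np.ndarray) -> np.ndarray:
    """Sum per-site ``values`` (m arrays x n_sites) over each window."""
    values = np.atleast_2d(values)
    out = np.zeros((values.shape[0], len(windows)))
    for chrom, grp in windows.groupby("chrom", sort=False):
        sel = gm.chrom == chrom
        pos = gm.pos[sel]
        cum = np.concatenate(
            [np.zeros((values.shape[0], 1)), np.cumsum(values[:, sel], axis=1)],
            axis=1)
        i0 = np.searchsorted(pos, grp["start"].to_numpy(), side="left")
        i1 = np.searchsorted(pos, grp["end"].to_numpy(), side="right")
        out[:, grp.index.to_numpy()] = cum[:, i1] - cum[:, i0]
    return out


def diversity_ratio(pi_num: np.ndarray | float, pi_den: np.ndarray | float,
                    cap: float = 100.0) -> tuple[np.ndarray, np.ndarray]:
    """Ratio pi_num / pi_den with degenerate handling.

    A zero denominator with a positive numerator is capped at ``cap`` and
    flagged; 0/0 is NaN.  Returns (ratio, capped-flag) arrays.
    """
    num = np.asarray(pi_num, dtype=float)
    den = np.asarray(pi_den, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = num / den
    capped = (den == 0) & (num > 0)
    ratio = np.where(capped, cap, ratio)
    ratio = np.where((den == 0) & (num == 0), np.nan, ratio)
    ratio = np.where(np.isnan(num) | np.isnan(den), np.nan, ratio)
    return ratio, capped


def compute_window_stats(gm: GenotypeMatrix, windows: pd.DataFrame,
                         pop_a: str = "H", pop_b: str = "S",
                         estimator: str = "hudson",
                         ratio_cap: float = 100.0) -> pd.DataFrame:
    """Full window-statistics table for two populations.

    Columns: ``chrom, start, end, n_sites, n_snps_a, n_snps_b, pi_a, pi_b,
    tajd_a, tajd_b, fst, ratio_a_over_b, ratio_b_over_a``.  ``pi`` is per
    site; multiply by 1000 for a per-kb rendering.  ``n_snps_*`` counts sites
    segregating within the population; ``n_sites`` counts all matrix sites in
    the window.  Undefined statistics are NaN.
    """
    windows = windows.reset_index(drop=True)
    rows_a = gm.sample_indices(pop_a)
    rows_b = gm.sample_indices(pop_b)
    if rows_a.size < 2 or rows_b.size < 2:
        raise ValueError("both populations need at least two samples")

    alt_a, n_a = site_allele_counts(gm, rows_a)
    alt_b, n_b = site_allele_counts(gm, rows_b)
    pi_a_terms, seg_a = _pi_site_terms(alt_a, n_a)
    pi_b_terms, seg_b = _pi_site_terms(alt_b, n_b)

    if estimator == "hudson":
        fst_num, fst_den = _hudson_site_terms(alt_a, n_a, alt_b, n_b)
    elif estimator == "weir-cockerham":
        fst_num, fst_den = _wc_site_terms(gm, rows_a, rows_b)
    else:
        raise ValueError(f"unknown FST estimator: {estimator}")

    stacked = np.vstack([
        pi_a_terms, seg_a, n_a * seg_a,
        pi_b_terms, seg_b, n_b * seg_b,
        fst_num, fst_den,
        np.ones(gm.n_sites),
    ])
    sums = _window_sums(gm, windows, stacked)
    (w_pi_a, s_a, nsum_a, w_pi_b, s_b, nsum_b,
     w_fnum, w_fden, n_sites) = sums

    size = (windows["end"] - windows["start"] + 1).to_numpy().astype(float)
    pi_a = w_pi_a / size
    pi_b = w_pi_b / size
    # a single n per window for the D constants: mean callable copies over
    # segregating sites (exact when data are complete)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar_a = np.where(s_a > 0, np.round(nsum_a / np.maximum(s_a, 1)), 0)
        nbar_b = np.where(s_b > 0, np.round(nsum_b / np.maximum(s_b, 1)), 0)
    tajd_a = _tajd_vector(w_pi_a, s_a, nbar_a)
    tajd_b = _tajd_vector(w_pi_b, s_b, nbar_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(w_fden > 0, w_fnum / np.maximum(w_fden, 1e-300), np.nan)
    r_ab, _ = diversity_ratio(pi_a, pi_b, ratio_cap)
    r_ba, _ = diversity_ratio(pi_b, pi_a, ratio_cap)

    out = windows.copy()
    out["n_sites"] = n_sites.astype(np.int64)
    out["n_snps_a"] = s_a.astype(np.int64)
    out["n_snps_b"] = s_b.astype(np.int64)
    out["pi_a"] = pi_a
    out["pi_b"] = pi_b
    out["tajd_a"] = tajd_a
    out["tajd_b"] = tajd_b
    out["fst"] = fst
    out["ratio_a_over_b"] = r_ab
    out["ratio_b_over_a"] = r_ba
    out.attrs["pop_a"] = pop_a
    out.attrs["pop_b"] = pop_b
    out.attrs["estimator"] = estimator
    return out


# ---------------------------------------------------------------------------
# single-window / genome-wide conveniences
# ---------------------------------------------------------------------------

def _window_gm(gm: GenotypeMatrix, window: tuple[str, int, int]) -> GenotypeMatrix:
    chrom, start, end = window
    return gm.take_sites(gm.site_mask(chrom, start, end))


def window_pi(gm: GenotypeMatrix, window: tuple[str, int, int],
              population: str) -> float:
    """Nucleotide diversity per site over one window [start, end]."""
    chrom, start, end = window
    sub = _window_gm(gm, window)
    rows = sub.sample_indices(population)
    if rows.size < 2:
        return float("nan")
    alt, n = site_allele_counts(sub, rows)
    terms, _ = _pi_site_terms(alt, n)
    return float(terms.sum() / (end - start + 1))


def window_tajimas_d(gm: GenotypeMatrix, window: tuple[str, int, int],
                     population: str) -> float:
    """Tajima's D over one window; NaN when no segregating sites."""
    sub = _window_gm(gm, window)
    rows = sub.sample_indices(population)
    if rows.size == 0:
        return float("nan")
    alt, n = site_allele_counts(sub, rows)
    terms, seg = _pi_site_terms(alt, n)
    s = int(seg.sum())
    if s == 0:
        return float("nan")
    nbar = int(np.round(n[seg].mean()))
    return tajimas_d(float(terms[seg].sum()), s, nbar)


def window_fst(gm: GenotypeMatrix, window: tuple[str, int, int],
               pop_a: str, pop_b: str, estimator: str = "hudson") -> float:
    """Multi-site FST (ratio of sums) over one window; NaN if unusable."""
    sub = _window_gm(gm, window)
    return genome_fst(sub, pop_a, pop_b, estimator)


def genome_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str,
               estimator: str = "hudson") -> float:
    """Pooled (ratio-of-sums over all sites) FST between two populations."""
    rows_a = gm.sample_indices(pop_a)
    rows_b = gm.sample_indices(pop_b)
    if rows_a.size < 1 or rows_b.size < 1:
        raise ValueError("both populations must be present")
    if estimator == "hudson":
        alt_a, n_a = site_allele_counts(gm, rows_a)
        alt_b, n_b = site_allele_counts(gm, rows_b)
        num, den = _hudson_site_terms(alt_a, n_a, alt_b, n_b)
    elif estimator == "weir-cockerham":
        num, den = _wc_site_terms(gm, rows_a, rows_b)
    else:
        raise ValueError(f"unknown FST estimator: {estimator}")
    total = den.sum()
    if total <= 0:
        return float("nan")
    return float(num.sum() / total)
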