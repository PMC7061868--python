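"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from popsweep.variants import MISSING, GenotypeMatrix


def make_gm(calls, pos=None, chrom="chr1", populations=None, ref=None, alt=None,
            samples=None) -> GenotypeMatrix:
    """Quick GenotypeMatrix from a (samples x sites) array of dosages."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    samples = samples or [f"s{i}" for i in range(n_samples)]
    if populations is None:
        populations = {s: "H" if i < n_samples // 2 else "S"
                       for i, s in enumerate(samples)}
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 10
    if isinstance(chrom, str):
        chrom = np.full(n_sites, chrom, dtype=object)
    return GenotypeMatrix(
        samples=samples,
        populations=dict(populations),
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(ref if ref is not None else ["A"] * n_sites, dtype=object),
        alt=np.array(alt if alt is not None else ["G"] * n_sites, dtype=object),
        calls=calls,
    )


def random_gm(rng: np.random.Generator, n_samples=6, n_sites=20,
              missing_rate=0.1, n_chroms=1) -> GenotypeMatrix:
    calls = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    calls[rng.random(calls.shape) < missing_rate] = MISSING
    per = n_sites // n_chroms
    chrom = np.concatenate([
        np.full(per if c < n_chroms - 1 else n_sites - per * (n_chroms - 1),
                f"chr{c + 1}", dtype=object)
        for c in range(n_chroms)])
    pos = np.concatenate([
        np.sort(rng.choice(100_000, size=(chrom == c).sum(), replace=False)) + 1
        for c in [f"chr{k + 1}" for k in range(n_chroms)]])
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, n_sites)
    alt_i = (ref_i + rng.integers(1, 4, n_sites)) % 4
    return make_gm(calls, pos=pos, chrom=chrom, ref=bases[ref_i], alt=bases[alt_i])


def brute_force_pi(calls: np.ndarray, window_bp: int) -> float:
    """Mean pairwise difference per site by explicit enumeration of all
    non-missing allele-copy pairs at every site (the textbook definition)."""
    total = 0.0
    for site in np.asarray(calls).T:
        copies: list[int] = []
        for g in site:
            if g >= 0:
                copies.extend([1] * int(g) + [0] * (2 - int(g)))
        n = len(copies)
        if n < 2:
            continue
        diffs = sum(abs(copies[i] - copies[j])
                    for i in range(n) for j in range(i + 1, n))
        total += diffs / (n * (n - 1) / 2)
    return total / window_bp


def tajimas_d_reference(pi_sum: float, s: int, n: int) -> float:
    """Direct textbook evaluation of the D constants, independent of the
    package implementation."""
    from fractions import Fraction
    a1 = float(sum(Fraction(1, i) for i in range(1, n)))
    a2 = float(sum(Fraction(1, i * i) for i in range(1, n)))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_sum - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
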