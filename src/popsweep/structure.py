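"""Cohort structure: K2P distances, neighbour-joining tree with bootstrap
support, genotype PCA and the admixture-membership rule.

The SNP matrix is bridged to the distance model by writing one pseudo-
sequence per sample over the SNP columns (heterozygotes resolved by a seeded
random allele by default, or encoded as IUPAC ambiguity codes which are then
excluded from pairwise comparisons, like missing data).  Distances use the
Kimura two-parameter correction; tree building is standard neighbour-joining
(delegated to scikit-bio) with support values from resampling SNP columns.
PCA follows the Patterson convention: dosages centred per site and scaled by
sqrt(p(1-p)), monomorphic sites dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .variants import GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "PCAResult",
    "genotypes_to_sequences",
    "k2p_distance",
    "k2p_distance_matrix",
    "nj_tree",
    "genotype_pca",
    "assign_membership",
    "read_q_matrix",
]

# base encoding: purines {A:0, G:1}, pyrimidines {C:2, T:3}; anything else -1
_CODE = {b"A": 0, b"G": 1, b"C": 2, b"T": 3}
_IUPAC = {("A", "C"): "M", ("A", "G"): "R", ("A", "T"): "W",
          ("C", "G"): "S", ("C", "T"): "Y", ("G", "T"): "K"}


@dataclass
class DistanceMatrix:
    """Symmetric matrix of K2P distances (substitutions/site); NaN entries
    flag saturated pairs where the K2P logarithm is undefined."""

    labels: list[str]
    matrix: np.ndarray

    def undefined_pairs(self) -> list[tuple[str, str]]:
        bad = np.argwhere(np.isnan(np.triu(self.matrix, 1)))
        return [(self.labels[i], self.labels[j]) for i, j in bad if i < j]

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.matrix):
                vals = " ".join(f"{v:.6f}" for v in row)
                fh.write(f"{lab:<10s} {vals}\n")


@dataclass
class PCAResult:
    """Sample scores for the leading components and the fraction of total
    genetic variance each explains (non-increasing, summing to <= 1)."""

    scores: pd.DataFrame
    variance_fraction: np.ndarray

    def write_tsv(self, path: str | Path) -> None:
        out = self.scores.copy()
        out.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# pseudo-sequences
# ---------------------------------------------------------------------------

def genotypes_to_sequences(gm: GenotypeMatrix, het_policy: str = "random",
                           seed: int = 0) -> np.ndarray:
    """Per-sample base strings over the SNP columns as an (n_samples,
    n_sites) byte array.

    hom-ref -> ref base, hom-alt -> alt base, missing -> ``-`` (excluded
    pairwise).  Heterozygotes: ``het_policy="random"`` draws one allele with
    the given seed (deterministic); ``"iupac"`` writes the ambiguity code,
    which the distance computation skips like a gap.
    """
    ref = np.array([str(b).upper() for b in gm.ref], dtype="U1")
    alt = np.array([str(b).upper() for b in gm.alt], dtype="U1")
    out = np.empty((gm.n_samples, gm.n_sites), dtype="U1")
    out[:] = "-"
    out[gm.calls == 0] = np.broadcast_to(ref, gm.calls.shape)[gm.calls == 0]
    out[gm.calls == 2] = np.broadcast_to(alt, gm.calls.shape)[gm.calls == 2]
    het = gm.calls == 1
    if het.any():
        if het_policy == "random":
            rng = np.random.default_rng(seed)
            pick_alt = rng.random(gm.calls.shape) < 0.5
            chosen = np.where(pick_alt, np.broadcast_to(alt, gm.calls.shape),
                              np.broadcast_to(ref, gm.calls.shape))
            out[het] = chosen[het]
        elif het_policy == "iupac":
            codes = np.array([_IUPAC.get(tuple(sorted((r, a))), "N")
                              for r, a in zip(ref, alt)], dtype="U1")
            out[het] = np.broadcast_to(codes, gm.calls.shape)[het]
        else:
            raise ValueError(f"unknown het_policy: {het_policy}")
    return out.astype("S1")


def _encode(sequences: np.ndarray) -> np.ndarray:
    """Map an (n, L) byte array to integer codes; non-ACGT -> -1."""
    seq = np.asarray(sequences)
    if seq.dtype.kind == "U":
        seq = seq.astype("S1")
    if seq.dtype != np.dtype("S1"):
        raise ValueError("sequences must be an (n, L) array of single bytes")
    codes = np.full(seq.shape, -1, dtype=np.int8)
    for b, c in _CODE.items():
        codes[seq == b] = c
    return codes


def sequences_from_strings(seqs: list[str]) -> np.ndarray:
    """Convenience: list of equal-length strings -> (n, L) byte array."""
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("sequences must have equal length")
    return np.array([list(s.upper()) for s in seqs], dtype="U1").astype("S1")


# ---------------------------------------------------------------------------
# K2P distances
# ---------------------------------------------------------------------------

def k2p_from_proportions(p: float, q: float) -> float:
    """K2P distance from transition (p) and transversion (q) proportions:
    d = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)]; NaN when saturated."""
    arg1 = 1.0 - 2.0 * p - q
    arg2 = 1.0 - 2.0 * q
    if arg1 <= 0 or arg2 <= 0:
        return float("nan")
    return float(-0.5 * np.log(arg1 * np.sqrt(arg2)))


def _pair_category_counts(codes: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """For every taxon pair: (#transitions, #transversions, #compared
    columns) over columns where both codes are ACGT, plus the pair index."""
    n = codes.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ts = np.zeros(len(pairs), dtype=np.int64)
    tv = np.zeros(len(pairs), dtype=np.int64)
    nn = np.zeros(len(pairs), dtype=np.int64)
    for k, (i, j) in enumerate(pairs):
        a, b = codes[i], codes[j]
        ok = (a >= 0) & (b >= 0)
        diff = ok & (a != b)
        same_class = (a >> 1) == (b >> 1)
        ts[k] = int((diff & same_class).sum())
        tv[k] = int((diff & ~same_class).sum())
        nn[k] = int(ok.sum())
    return ts, tv, nn, pairs


def k2p_distance(seq_a: str | np.ndarray, seq_b: str | np.ndarray) -> float:
    """K2P distance between two sequences (pairwise deletion of non-ACGT)."""
    if isinstance(seq_a, str):
        codes = _encode(sequences_from_strings([seq_a, seq_b]))
    else:
        codes = _encode(np.stack([np.asarray(seq_a), np.asarray(seq_b)]))
    ts, tv, nn, _ = _pair_category_counts(codes)
    if nn[0] == 0:
        return float("nan")
    return k2p_from_proportions(ts[0] / nn[0], tv[0] / nn[0])


def _k2p_matrix_from_codes(codes: np.ndarray,
                           labels: list[str]) -> DistanceMatrix:
    n = codes.shape[0]
    mat = np.zeros((n, n))
    ts, tv, nn, pairs = _pair_category_counts(codes)
    for (i, j), t, v, m in zip(pairs, ts, tv, nn):
        d = k2p_from_proportions(t / m, v / m) if m > 0 else float("nan")
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels=list(labels), matrix=mat)


def k2p_distance_matrix(sequences: np.ndarray | list[str],
                        labels: list[str] | None = None) -> DistanceMatrix:
    """All-pairs K2P distances; saturated pairs are NaN (flagged, not raised)."""
    if isinstance(sequences, list):
        sequences = sequences_from_strings(sequences)
    codes = _encode(sequences)
    labels = labels if labels is not None else [f"t{i}" for i in range(codes.shape[0])]
    return _k2p_matrix_from_codes(codes, labels)


# ---------------------------------------------------------------------------
# neighbour-joining with bootstrap
# ---------------------------------------------------------------------------

def _skbio_nj(labels: list[str], matrix: np.ndarray):
    import skbio
    from skbio.tree import nj
    return nj(skbio.DistanceMatrix(matrix, ids=labels))


def _splits(tree, all_tips: frozenset, anchor: str) -> set[frozenset]:
    """Canonical bipartitions (side not containing the anchor taxon) induced
    by the internal edges of an unrooted tree."""
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = all_tips - side
        if 1 < len(side) < len(all_tips) - 1:
            out.add(side)
    return out


def nj_tree(dm: DistanceMatrix, sequences: np.ndarray | None = None,
            bootstrap_n: int = 0, seed: int = 0):
    """Unrooted neighbour-joining tree (Saitou-Nei agglomeration via
    scikit-bio) with optional bootstrap support.

    Bootstrapping resamples SNP columns of ``sequences`` with replacement
    ``bootstrap_n`` times, rebuilds the K2P/NJ tree, and labels each internal
    node with the percentage of replicates containing its bipartition.
    Undefined (saturated) distance entries are an error naming the pairs.
    Returns a ``skbio.TreeNode``; serialise with ``str(tree)`` (Newick).
    """
    if len(dm.labels) < 3:
        raise ValueError("need at least 3 taxa")
    bad = dm.undefined_pairs()
    if bad:
        raise ValueError(f"undefined (saturated) distances for pairs: {bad}")
    tree = _skbio_nj(dm.labels, dm.matrix)

    if bootstrap_n > 0:
        if sequences is None:
            raise ValueError("bootstrap requires the sequence matrix")
        if isinstance(sequences, list):
            sequences = sequences_from_strings(sequences)
        codes = _encode(sequences)
        length = codes.shape[1]
        rng = np.random.default_rng(seed)
        all_tips = frozenset(dm.labels)
        anchor = dm.labels[0]
        counts: dict[frozenset, int] = {s: 0 for s in _splits(tree, all_tips, anchor)}
        for _ in range(bootstrap_n):
            cols = rng.integers(0, length, size=length)
            bdm = _k2p_matrix_from_codes(codes[:, cols], dm.labels)
            if bdm.undefined_pairs():
                continue
            btree = _skbio_nj(bdm.labels, bdm.matrix)
            for s in _splits(btree, all_tips, anchor):
                if s in counts:
                    counts[s] += 1
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = all_tips - side
            if side in counts:
                node.name = f"{100.0 * counts[side] / bootstrap_n:.0f}"
    return tree


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def genotype_pca(gm: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """Genotype PCA with Patterson standardisation.

    Monomorphic sites are dropped; dosages are centred by 2p and scaled by
    sqrt(p(1-p)) with p the sample alt-allele frequency; missing calls are
    mean-imputed (zero after centring).  Scores come from the eigenvectors of
    the sample-by-sample covariance, scaled by the singular values.
    """
    if gm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    calls = gm.calls.astype(float)
    ok = calls >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, calls, 0.0).sum(0) / np.maximum(2.0 * ok.sum(0), 1.0)
    poly = (p > 0) & (p < 1) & (ok.sum(0) > 0)
    if not poly.any():
        raise ValueError("all sites are monomorphic")
    x = (calls[:, poly] - 2.0 * p[poly]) / np.sqrt(p[poly] * (1.0 - p[poly]))
    x[~ok[:, poly]] = 0.0
    g = x @ x.T
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    k = min(n_components, gm.n_samples)
    scores = eigvec[:, :k] * np.sqrt(eigval[:k])
    total = eigval.sum()
    frac = eigval[:k] / total if total > 0 else np.zeros(k)
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(scores=pd.DataFrame(scores, index=gm.samples, columns=cols),
                     variance_fraction=frac)


# ---------------------------------------------------------------------------
# admixture membership
# ---------------------------------------------------------------------------

def read_q_matrix(path: str | Path) -> pd.DataFrame:
    """Sample x cluster admixture proportions from a TSV (first column =
    sample id, remaining columns = cluster proportions)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def assign_membership(q_matrix: pd.DataFrame, threshold: float = 0.7,
                      tol: float = 0.01) -> pd.Series:
    """Assign each sample to its argmax cluster iff the max proportion is
    strictly above ``threshold``, else label it ``"mixed"``.

    Rows must sum to 1 within ``tol`` (the study's rule used > 0.7)."""
    sums = q_matrix.sum(axis=1)
    bad = q_matrix.index[(sums - 1.0).abs() > tol]
    if len(bad):
        raise ValueError(f"Q rows do not sum to 1 (+-{tol}): {list(bad)}")
    best = q_matrix.idxmax(axis=1)
    maxp = q_matrix.max(axis=1)
    out = best.where(maxp > threshold, other="mixed")
    out.name = "cluster"
    return out
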