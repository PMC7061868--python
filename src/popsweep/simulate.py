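"""Synthetic two-population cohorts with known ground truth.

The generator emulates the statistical structure the divergence analysis
assumes: two diverged populations (default 8 "H" hard-seeded and 12 "S"
soft-seeded samples plus 6 unassigned varieties) genotyped at ~1 SNP/kb over
8 chromosomes, with between-population differentiation set directly through
the Balding-Nichols model at F = 0.26 and one or more injected sweeps
(locally reduced diversity in one population, including a large region on
chromosome 1).

Model per site: ancestral frequency p ~ Uniform(0.05, 0.95); each
population's frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F), whose expected
squared standardised divergence equals F (so the Hudson estimator recovers
the parameter); genotypes ~ Binomial(2, pop frequency); unassigned samples
draw from the ancestral frequency.  Inside a sweep interval the affected
population's frequency is fixed (rounded to 0/1) with probability
1 - 1/reduction, which divides expected heterozygosity by exactly the
configured reduction factor.  Sites are unlinked by default; an optional
latent-copying autocorrelation adds LD that decays exponentially with
distance for the LD-decay machinery.

Also provides a K2P sequence simulator (fixtures for distance/tree work) and
base-level recovery scoring of called sweep regions against the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .variants import MISSING, UNASSIGNED, GenotypeMatrix

__all__ = [
    "SweepInterval",
    "CohortConfig",
    "CohortTruth",
    "simulate_cohort",
    "recovery_benchmark_config",
    "simulate_genes_gff3",
    "simulate_pathway_map",
    "simulate_alignment",
    "evaluate_recovery",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SweepInterval:
    """A region where the affected population's diversity is reduced
    ``reduction``-fold (frequencies pushed to fixation)."""

    chrom: str
    start: int
    end: int
    reduction: float = 10.0
    population: str = "H"


def _default_chrom_lengths() -> dict[str, int]:
    # chromosome 1 longest, mirroring the assembly's karyotype of 8
    return {"chr1": 46_000_000, **{f"chr{i}": 40_000_000 for i in range(2, 9)}}


def _default_sweeps() -> list[SweepInterval]:
    return [
        SweepInterval("chr1", 16_330_001, 42_530_000, reduction=10.0,
                      population="H"),
        SweepInterval("chr3", 20_000_001, 22_000_000, reduction=10.0,
                      population="S"),
    ]


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort (defaults emulate the
    26-variety resequencing panel)."""

    chrom_lengths: dict[str, int] = field(default_factory=_default_chrom_lengths)
    snp_density_per_kb: float = 1.0
    n_hard: int = 8
    n_soft: int = 12
    n_other: int = 6
    fst: float = 0.26
    sweeps: list[SweepInterval] = field(default_factory=_default_sweeps)
    missing_rate: float = 0.02
    ld_decay_bp: float = 0.0      # 0 = unlinked sites
    seed: int = 0
    hard_label: str = "H"
    soft_label: str = "S"

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must be in [0, 1)")
        if self.snp_density_per_kb <= 0:
            raise ValueError("snp_density_per_kb must be > 0")
        for sw in self.sweeps:
            if sw.chrom not in self.chrom_lengths:
                raise ValueError(f"sweep chromosome {sw.chrom} not simulated")
            if not (1 <= sw.start <= sw.end <= self.chrom_lengths[sw.chrom]):
                raise ValueError(f"sweep {sw} outside chromosome bounds")
            if sw.reduction < 1.0:
                raise ValueError("sweep reduction must be >= 1")


def recovery_benchmark_config(seed: int = 0) -> CohortConfig:
    """The sweep-recovery benchmark condition: one 40 Mb chromosome carrying
    a single 2 Mb sweep (10-fold reduction in H) on the F = 0.26 background."""
    return CohortConfig(
        chrom_lengths={"chr1": 40_000_000},
        sweeps=[SweepInterval("chr1", 20_000_001, 22_000_000,
                              reduction=10.0, population="H")],
        seed=seed,
    )


@dataclass
class CohortTruth:
    """Simulator ground truth: per-site population frequencies, the sweep
    intervals and the differentiation parameter."""

    fst: float
    sweeps: list[SweepInterval]
    chrom: np.ndarray
    pos: np.ndarray
    freq_ancestral: np.ndarray
    freq_hard: np.ndarray
    freq_soft: np.ndarray
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        """Summary JSON (intervals + parameters; per-site frequencies stay
        in memory — they are regenerable from the seed)."""
        payload = {
            "fst": self.fst,
            "seed": self.seed,
            "n_sites": int(self.pos.size),
            "sweeps": [asdict(s) for s in self.sweeps],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float
                     ) -> np.ndarray:
    if f == 0.0:
        return p.copy()
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    return rng.beta(a, b)


def _genotypes(rng: np.random.Generator, freq: np.ndarray, n_samples: int,
               pos: np.ndarray, ld_decay_bp: float) -> np.ndarray:
    """Binomial(2, freq) genotypes; with ld_decay_bp > 0, each allele copy
    reuses the previous site's latent uniform with probability
    exp(-distance/ld_decay_bp), preserving marginal frequencies while adding
    distance-decaying LD."""
    if ld_decay_bp <= 0:
        return rng.binomial(2, freq[None, :], size=(n_samples, freq.size)
                            ).astype(np.int8)
    n_sites = freq.size
    u = np.empty((n_samples, 2, n_sites))
    u[:, :, 0] = rng.random((n_samples, 2))
    keep_p = np.exp(-np.diff(pos) / ld_decay_bp)
    fresh = rng.random((n_samples, 2, n_sites - 1))
    keep = rng.random((n_samples, 2, n_sites - 1)) < keep_p[None, None, :]
    for j in range(1, n_sites):
        u[:, :, j] = np.where(keep[:, :, j - 1], u[:, :, j - 1],
                              fresh[:, :, j - 1])
    alleles = u < freq[None, None, :]
    return alleles.sum(axis=1).astype(np.int8)


def simulate_cohort(cfg: CohortConfig) -> tuple[GenotypeMatrix, CohortTruth]:
    """Generate the cohort genotype matrix and its ground truth.

    Deterministic given ``cfg.seed``; site positions are a uniform draw at
    the configured density; missingness is Bernoulli per call.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = ([f"H{i + 1:02d}" for i in range(cfg.n_hard)]
               + [f"S{i + 1:02d}" for i in range(cfg.n_soft)]
               + [f"U{i + 1:02d}" for i in range(cfg.n_other)])
    populations = {}
    for s in samples:
        populations[s] = (cfg.hard_label if s.startswith("H")
                          else cfg.soft_label if s.startswith("S")
                          else UNASSIGNED)

    chroms, poss, refs, alts = [], [], [], []
    p_anc_all, p_h_all, p_s_all = [], [], []
    calls_cols = []
    for chrom, length in cfg.chrom_lengths.items():
        n_sites = int(round(length / 1000.0 * cfg.snp_density_per_kb))
        pos = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1
        p_anc = rng.uniform(0.05, 0.95, size=n_sites)
        p_h = _balding_nichols(rng, p_anc, cfg.fst)
        p_s = _balding_nichols(rng, p_anc, cfg.fst)
        for sw in cfg.sweeps:
            if sw.chrom != chrom or sw.reduction <= 1.0:
                continue
            inside = (pos >= sw.start) & (pos <= sw.end)
            fix = inside & (rng.random(n_sites) < 1.0 - 1.0 / sw.reduction)
            target = p_h if sw.population == cfg.hard_label else p_s
            target[fix] = np.round(target[fix])
        ref_idx = rng.integers(0, 4, size=n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4

        g_h = _genotypes(rng, p_h, cfg.n_hard, pos, cfg.ld_decay_bp)
        g_s = _genotypes(rng, p_s, cfg.n_soft, pos, cfg.ld_decay_bp)
        g_u = _genotypes(rng, p_anc, cfg.n_other, pos, cfg.ld_decay_bp)
        g = np.concatenate([g_h, g_s, g_u], axis=0)
        if cfg.missing_rate > 0:
            g[rng.random(g.shape) < cfg.missing_rate] = MISSING

        chroms.append(np.full(n_sites, chrom, dtype=object))
        poss.append(pos)
        refs.append(_BASES[ref_idx])
        alts.append(_BASES[alt_idx])
        p_anc_all.append(p_anc)
        p_h_all.append(p_h)
        p_s_all.append(p_s)
        calls_cols.append(g)

    gm = GenotypeMatrix(
        samples=samples,
        populations=populations,
        chrom=np.concatenate(chroms),
        pos=np.concatenate(poss),
        ref=np.concatenate(refs).astype(object),
        alt=np.concatenate(alts).astype(object),
        calls=np.concatenate(calls_cols, axis=1),
    )
    truth = CohortTruth(
        fst=cfg.fst,
        sweeps=list(cfg.sweeps),
        chrom=gm.chrom.copy(),
        pos=gm.pos.copy(),
        freq_ancestral=np.concatenate(p_anc_all),
        freq_hard=np.concatenate(p_h_all),
        freq_soft=np.concatenate(p_s_all),
        seed=cfg.seed,
    )
    return gm, truth


# ---------------------------------------------------------------------------
# toy annotation and pathway map
# ---------------------------------------------------------------------------

def simulate_genes_gff3(chrom_lengths: dict[str, int], path: str | Path,
                        gene_every_bp: int = 10_000, gene_length_bp: int = 3_000,
                        n_pathways: int = 40, seed: int = 0
                        ) -> tuple[list[str], dict[str, set[str]]]:
    """Write a toy GFF3 of regularly spaced genes and return (gene ids,
    pathway -> gene set map)."""
    rng = np.random.default_rng(seed)
    genes: list[tuple[str, int, int, str]] = []
    counter = 0
    for chrom, length in chrom_lengths.items():
        start = 1
        while start + gene_length_bp - 1 <= length:
            counter += 1
            genes.append((chrom, start, start + gene_length_bp - 1,
                          f"gene{counter:06d}"))
            start += gene_every_bp
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for chrom, start, end, gid in genes:
            fh.write(f"{chrom}\tpopsweep_sim\tgene\t{start}\t{end}\t.\t+\t.\t"
                     f"ID={gid}\n")
    ids = [g[3] for g in genes]
    pathway_ids = [f"path{i + 1:03d}" for i in range(n_pathways)]
    pmap: dict[str, set[str]] = {p: set() for p in pathway_ids}
    assignment = rng.integers(0, n_pathways, size=len(ids))
    for gid, k in zip(ids, assignment):
        pmap[pathway_ids[k]].add(gid)
    return ids, {p: g for p, g in pmap.items() if g}


def simulate_pathway_map(pmap: dict[str, set[str]], path: str | Path) -> None:
    """Write pathway -> genes as a 2-column (gene, pathway) TSV."""
    with open(path, "w") as fh:
        for pathway in sorted(pmap):
            for gene in sorted(pmap[pathway]):
                fh.write(f"{gene}\t{pathway}\n")


# ---------------------------------------------------------------------------
# K2P alignment simulator
# ---------------------------------------------------------------------------

def simulate_alignment(tree, length: int, ts_tv_ratio: float = 2.0,
                       seed: int = 0) -> tuple[list[str], np.ndarray]:
    """Evolve sequences site-independently along a tree under the Kimura
    two-parameter model.

    ``tree`` is a Newick string or a ``dendropy.Tree``; branch lengths are
    expected substitutions/site.  With transition rate alpha and two
    transversion rates beta normalised so alpha + 2 beta = 1 and
    alpha/beta = ``ts_tv_ratio``, the change probabilities after branch
    length t are the standard K80 spectral forms.  Returns (taxon labels,
    (n, length) byte array).
    """
    import dendropy

    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    rng = np.random.default_rng(seed)
    kappa = ts_tv_ratio
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta

    # base codes 0..3 = A,G,C,T; transition partner = code ^ 1 within class
    ts_partner = np.array([1, 0, 3, 2])
    tv_partners = np.array([[2, 3], [2, 3], [0, 1], [0, 1]])

    def evolve(seq: np.ndarray, t: float) -> np.ndarray:
        if t <= 0:
            return seq.copy()
        e4 = np.exp(-4.0 * beta * t)
        e2 = np.exp(-2.0 * (alpha + beta) * t)
        p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
        p_tv = 0.25 - 0.25 * e4          # each of the two transversions
        u = rng.random(seq.size)
        out = seq.copy()
        mut_ts = u < p_ts
        mut_tv1 = (u >= p_ts) & (u < p_ts + p_tv)
        mut_tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
        out[mut_ts] = ts_partner[seq[mut_ts]]
        out[mut_tv1] = tv_partners[seq[mut_tv1], 0]
        out[mut_tv2] = tv_partners[seq[mut_tv2], 1]
        return out

    root = tree.seed_node
    seqs: dict = {}
    root_seq = rng.integers(0, 4, size=length)
    stack = [(root, root_seq)]
    leaves: dict[str, np.ndarray] = {}
    while stack:
        node, seq = stack.pop()
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            child_seq = evolve(seq, t)
            if child.is_leaf():
                leaves[child.taxon.label] = child_seq
            else:
                stack.append((child, child_seq))
    if root.is_leaf():
        leaves[root.taxon.label] = root_seq
    labels = sorted(leaves)
    base_order = np.array(list("AGCT"), dtype="U1")
    arr = np.stack([base_order[leaves[lab]] for lab in labels]).astype("S1")
    return labels, arr


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def _interval_union(intervals: list[tuple[str, int, int]]
                    ) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = [tuple(iv) for iv in merged]
    return out


def _covered(ivs: list[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in ivs)


def _intersection(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            lo, hi = max(s1, s2), min(e1, e2)
            if lo <= hi:
                total += hi - lo + 1
    return total


def evaluate_recovery(called: pd.DataFrame, truth: CohortTruth,
                      population: str | None = None) -> dict:
    """Base-level recovery of called regions against the true sweeps.

    sensitivity = true sweep bases covered by calls / true sweep bases;
    base_fdr = called bases outside truth / called bases (0 when nothing is
    called); boundary_error_bp = mean |called - true| endpoint offset over
    true intervals overlapped by at least one call.
    """
    sweeps = truth.sweeps
    if population is not None:
        sweeps = [s for s in sweeps if s.population == population]
    true_ivs = _interval_union([(s.chrom, s.start, s.end) for s in sweeps])
    call_list = [(r.chrom, int(r.start), int(r.end))
                 for r in called.itertuples(index=False)]
    call_ivs = _interval_union(call_list)

    true_bases = sum(_covered(v) for v in true_ivs.values())
    call_bases = sum(_covered(v) for v in call_ivs.values())
    overlap = sum(_intersection(true_ivs.get(c, []), call_ivs.get(c, []))
                  for c in set(true_ivs) | set(call_ivs))
    sensitivity = overlap / true_bases if true_bases else float("nan")
    base_fdr = (call_bases - overlap) / call_bases if call_bases else 0.0

    offsets: list[float] = []
    for sw in sweeps:
        cands = [iv for iv in call_ivs.get(sw.chrom, [])
                 if iv[0] <= sw.end and iv[1] >= sw.start]
        if cands:
            best = min(cands, key=lambda iv: abs(iv[0] - sw.start)
                       + abs(iv[1] - sw.end))
            offsets.append((abs(best[0] - sw.start) + abs(best[1] - sw.end)) / 2)
    boundary = float(np.mean(offsets)) if offsets else float("nan")
    return {"sensitivity": float(sensitivity), "base_fdr": float(base_fdr),
            "boundary_error_bp": boundary, "true_bases": int(true_bases),
            "called_bases": int(call_bases)}
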