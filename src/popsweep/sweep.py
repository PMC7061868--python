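"""Selective-sweep region calling from window statistics.

A window is a sweep candidate for population X when the diversity ratio
pi(other)/pi(X) clears a permutation-derived cut-off AND the window passes an
FST rule (top-fraction outlier set or an explicit threshold).  Candidate
windows are merged into regions, regions are annotated with overlapping genes
from a GFF3, and gene sets are tested for pathway enrichment with an
upper-tail hypergeometric test (Benjamini-Hochberg corrected by default).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .popgen import compute_window_stats, diversity_ratio
from .variants import GenotypeMatrix, round_half_up

__all__ = [
    "permutation_cutoff",
    "top_fraction_windows",
    "call_candidate_windows",
    "merge_regions",
    "annotate_regions",
    "enrich_hypergeometric",
    "read_pathway_map",
    "write_regions_bed",
]

logger = logging.getLogger(__name__)

REGION_STAT_COLS = ("mean_ratio", "max_ratio", "mean_fst", "mean_tajd_a",
                    "mean_tajd_b")


# ---------------------------------------------------------------------------
# permutation cut-off
# ---------------------------------------------------------------------------

def permutation_cutoff(gm: GenotypeMatrix, windows: pd.DataFrame,
                       numerator_pop: str, denominator_pop: str,
                       n_perm: int = 200, alpha: float = 0.05,
                       seed: int = 0, min_snps: int = 10,
                       ratio_cap: float = 100.0) -> float:
    """Permutation-null cut-off for the windowed diversity ratio.

    Sample labels are shuffled across the two populations' samples ``n_perm``
    times; the ratio pi(numerator)/pi(denominator) is recomputed over all
    windows each time; the cut-off is the (1 - alpha) quantile of the pooled
    permuted values.  Windows with fewer than ``min_snps`` matrix sites are
    masked, mirroring the observed scan.  Deterministic given ``seed``.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    rows_num = gm.sample_indices(numerator_pop)
    rows_den = gm.sample_indices(denominator_pop)
    if rows_num.size == 0 or rows_den.size == 0:
        raise ValueError("both populations must have labelled samples")

    from .popgen import _pi_site_terms, _window_sums, site_allele_counts

    windows = windows.reset_index(drop=True)
    pool = np.concatenate([rows_num, rows_den])
    k = rows_num.size
    rng = np.random.default_rng(seed)

    n_sites_w = _window_sums(gm, windows, np.ones((1, gm.n_sites)))[0]
    usable = n_sites_w >= min_snps
    size = (windows["end"] - windows["start"] + 1).to_numpy().astype(float)

    pooled: list[np.ndarray] = []
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        terms = []
        for rows in (perm[:k], perm[k:]):
            alt, n = site_allele_counts(gm, rows)
            t, _ = _pi_site_terms(alt, n)
            terms.append(t)
        sums = _window_sums(gm, windows, np.vstack(terms))
        ratio, _ = diversity_ratio(sums[0] / size, sums[1] / size, ratio_cap)
        vals = ratio[usable]
        pooled.append(vals[np.isfinite(vals)])
    values = np.concatenate(pooled)
    if values.size == 0:
        raise ValueError("no defined permuted ratios; cohort too sparse")
    return float(np.quantile(values, 1.0 - alpha))


# ---------------------------------------------------------------------------
# outlier selection and candidate calling
# ---------------------------------------------------------------------------

def top_fraction_windows(values: pd.Series | np.ndarray,
                         fraction: float = 0.05) -> np.ndarray:
    """Boolean mask of the top ``fraction`` of defined values.

    The threshold is the ceil(fraction * n_defined)-th largest defined value;
    every value >= the threshold is selected, so threshold ties are all
    included.  NaNs are excluded before ranking and never selected.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    v = np.asarray(values, dtype=float)
    defined = v[np.isfinite(v)]
    if defined.size == 0:
        return np.zeros(v.shape, dtype=bool)
    k = max(1, math.ceil(fraction * defined.size))
    threshold = np.sort(defined)[::-1][k - 1]
    with np.errstate(invalid="ignore"):
        return np.where(np.isfinite(v), v >= threshold, False)


def call_candidate_windows(stats: pd.DataFrame,
                           ratio_cutoff: float | dict[str, float],
                           fst_rule: tuple[str, float] = ("top_fraction", 0.05),
                           min_snps: int = 10,
                           combine: str = "and") -> dict[str, pd.DataFrame]:
    """Per-population sweep-candidate windows from a window-statistics table.

    ``stats`` comes from :func:`popsweep.popgen.compute_window_stats` (its
    ``attrs`` name the two populations).  A window is a candidate for
    population X when ratio(other/X) >= the cut-off for X and the window
    passes ``fst_rule`` — ``("top_fraction", f)`` for the top-f FST outlier
    set or ``("threshold", t)`` for FST >= t.  ``combine="or"`` relaxes the
    conjunction to a union.  Windows with fewer than ``min_snps`` sites are
    masked.
    """
    pop_a = stats.attrs.get("pop_a", "A")
    pop_b = stats.attrs.get("pop_b", "B")
    if isinstance(ratio_cutoff, dict):
        cutoffs = ratio_cutoff
    else:
        cutoffs = {pop_a: ratio_cutoff, pop_b: ratio_cutoff}

    usable = stats["n_sites"].to_numpy() >= min_snps
    fst = stats["fst"].to_numpy(dtype=float)
    kind, value = fst_rule
    if kind == "top_fraction":
        fst_pass = top_fraction_windows(np.where(usable, fst, np.nan), value)
    elif kind == "threshold":
        with np.errstate(invalid="ignore"):
            fst_pass = np.where(np.isfinite(fst), fst >= value, False) & usable
    else:
        raise ValueError(f"unknown fst_rule kind: {kind}")

    out: dict[str, pd.DataFrame] = {}
    for pop, ratio_col in ((pop_a, "ratio_b_over_a"), (pop_b, "ratio_a_over_b")):
        ratio = stats[ratio_col].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            ratio_pass = np.where(np.isfinite(ratio),
                                  ratio >= cutoffs[pop], False) & usable
        mask = (ratio_pass | fst_pass) if combine == "or" else (ratio_pass & fst_pass)
        sub = stats.loc[mask].copy()
        sub["ratio_other_over_target"] = sub[ratio_col]
        sub.attrs["population"] = pop
        out[pop] = sub
    return out


# ---------------------------------------------------------------------------
# region merging / annotation
# ---------------------------------------------------------------------------

def merge_regions(windows: pd.DataFrame, merge_gap_bp: int = 10_000,
                  population: str | None = None) -> pd.DataFrame:
    """Merge candidate windows into nonoverlapping sweep regions.

    Windows overlapping or separated by at most ``merge_gap_bp`` are unioned.
    Output columns: ``chrom, start, end, length_mb, n_windows`` plus mean/max
    summaries of any statistic columns present in the input, sorted by
    chromosome then start.  ``length_mb`` is half-up rounded to 2 decimals.
    """
    cols = ["chrom", "start", "end", "length_mb", "n_windows",
            *REGION_STAT_COLS, "population"]
    if len(windows) == 0:
        return pd.DataFrame(columns=cols)
    w = windows.sort_values(["chrom", "start"]).reset_index(drop=True)
    pop = population or windows.attrs.get("population", "")

    regions: list[dict] = []
    current: dict | None = None
    for row in w.itertuples(index=False):
        if (current is None or row.chrom != current["chrom"]
                or row.start > current["end"] + merge_gap_bp + 1):
            if current is not None:
                regions.append(current)
            current = {"chrom": row.chrom, "start": int(row.start),
                       "end": int(row.end), "rows": [row]}
        else:
            current["end"] = max(current["end"], int(row.end))
            current["rows"].append(row)
    if current is not None:
        regions.append(current)

    def _agg(rows, col, fn):
        vals = [getattr(r, col) for r in rows if hasattr(r, col)]
        vals = [v for v in vals if v is not None and np.isfinite(v)]
        return fn(vals) if vals else np.nan

    records = []
    for reg in regions:
        rows = reg["rows"]
        records.append({
            "chrom": reg["chrom"],
            "start": reg["start"],
            "end": reg["end"],
            "length_mb": round_half_up((reg["end"] - reg["start"] + 1) / 1e6, 2),
            "n_windows": len(rows),
            "mean_ratio": _agg(rows, "ratio_other_over_target", np.mean),
            "max_ratio": _agg(rows, "ratio_other_over_target", np.max),
            "mean_fst": _agg(rows, "fst", np.mean),
            "mean_tajd_a": _agg(rows, "tajd_a", np.mean),
            "mean_tajd_b": _agg(rows, "tajd_b", np.mean),
            "population": pop,
        })
    out = pd.DataFrame.from_records(records, columns=cols)
    out.attrs["population"] = pop
    return out


def annotate_regions(regions: pd.DataFrame, gff: str | Path,
                     featuretype: str = "gene") -> pd.DataFrame:
    """Attach IDs of genes overlapping each region by >= 1 bp.

    ``gff`` is a GFF3 path (or literal GFF3 text).  Adds ``gene_ids``
    (comma-joined) and ``n_genes`` columns; the total number of distinct
    genes over all regions is stored in ``result.attrs["n_unique_genes"]``.
    Regions on chromosomes absent from the annotation are warned about and
    annotated with zero genes.
    """
    import gffutils

    data = str(gff)
    from_string = "\n" in data or data.lstrip().startswith("##gff")
    db = gffutils.create_db(data, ":memory:", from_string=from_string,
                            merge_strategy="create_unique")
    seqids = {f.seqid for f in db.all_features()}

    out = regions.copy()
    gene_lists: list[list[str]] = []
    unmatched = 0
    for row in out.itertuples(index=False):
        if row.chrom not in seqids:
            unmatched += 1
            gene_lists.append([])
            continue
        feats = db.region(region=(row.chrom, int(row.start), int(row.end)),
                          featuretype=featuretype)
        gene_lists.append(sorted({f.id for f in feats}))
    if unmatched:
        logger.warning("annotate_regions: %d regions on chromosomes missing "
                       "from the annotation", unmatched)
    out["gene_ids"] = [",".join(g) for g in gene_lists]
    out["n_genes"] = [len(g) for g in gene_lists]
    out.attrs["n_unique_genes"] = len(set().union(*gene_lists)) if gene_lists else 0
    out.attrs["n_unmatched_regions"] = unmatched
    return out


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Write regions as BED (0-based half-open) with the population in the
    name column."""
    with open(path, "w") as fh:
        for row in regions.itertuples(index=False):
            name = getattr(row, "population", "") or "region"
            fh.write(f"{row.chrom}\t{int(row.start) - 1}\t{int(row.end)}\t{name}\n")


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def read_pathway_map(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column TSV (gene, pathway) into pathway -> gene set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "pathway"],
                     dtype=str, comment="#")
    out: dict[str, set[str]] = {}
    for gene, pathway in zip(df["gene"], df["pathway"]):
        out.setdefault(pathway, set()).add(gene)
    return out


def enrich_hypergeometric(region_genes: set[str] | list[str],
                          background_genes: set[str] | list[str],
                          pathway_map: dict[str, set[str]],
                          correction: str = "bh",
                          alpha: float = 0.05) -> pd.DataFrame:
    """Pathway over-representation by the upper-tail hypergeometric test.

    For each pathway with at least one region gene: population N = background
    size, K = background genes in the pathway, n = region-set size, k = region
    genes in the pathway; p = P(X >= k).  Correction: ``"bh"``
    (Benjamini-Hochberg, default), ``"bonferroni"``, or ``"none"``; pathways
    are flagged significant at adjusted p < ``alpha``.
    """
    region = set(region_genes)
    background = set(background_genes)
    if not region <= background:
        raise ValueError("region genes must be a subset of the background")
    rows = []
    n = len(region)
    big_n = len(background)
    for pathway, genes in sorted(pathway_map.items()):
        in_bg = genes & background
        k = len(genes & region)
        if k == 0:
            continue
        big_k = len(in_bg)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append((pathway, k, big_k, n, big_n, p))
    df = pd.DataFrame(rows, columns=["pathway", "k", "K", "n", "N", "p"])
    if df.empty:
        df["p_adj"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    elif correction == "bonferroni":
        df["p_adj"] = np.minimum(df["p"] * len(df), 1.0)
    elif correction == "none":
        df["p_adj"] = df["p"]
    else:
        raise ValueError(f"unknown correction: {correction}")
    df["significant"] = df["p_adj"] < alpha
    return df.sort_values("p_adj", kind="stable").reset_index(drop=True)
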