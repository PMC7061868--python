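"""Genotype matrices, VCF input/output, site filters and per-sample summaries.

The central container is :class:`GenotypeMatrix`: a samples x sites matrix of
alt-allele dosages (0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing) over
biallelic SNPs, with 1-based site coordinates and a sample -> population map.
Population labels are free strings (the pomegranate study used ``H`` for
hard-seeded and ``S`` for soft-seeded varieties); samples absent from the
population map carry the label ``"unassigned"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "UNASSIGNED",
    "GenotypeMatrix",
    "SiteFilterConfig",
    "FilterReport",
    "VcfParseError",
    "read_popmap",
    "read_vcf",
    "write_vcf",
    "filter_sites",
    "sample_heterozygosity",
    "variant_density",
    "round_half_up",
]

logger = logging.getLogger(__name__)

MISSING: int = -1
UNASSIGNED: str = "unassigned"

_DNA = frozenset("ACGT")


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed into a genotype matrix."""


@dataclass
class GenotypeMatrix:
    """Biallelic-SNP genotype matrix with coordinates and population labels.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (column order of the source VCF).
    populations : dict
        sample id -> population label; samples not covered by the popmap are
        labelled :data:`UNASSIGNED`.
    chrom, pos, ref, alt : ndarray
        Per-site arrays; ``pos`` is 1-based and strictly increasing within a
        chromosome; ``ref``/``alt`` are single bases.
    calls : ndarray of int8, shape (n_samples, n_sites)
        Alt-allele dosage per call, ``-1`` for missing.
    """

    samples: list[str]
    populations: dict[str, str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), self.pos.size):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)} samples, {self.pos.size} sites)"
            )
        for s in self.samples:
            self.populations.setdefault(s, UNASSIGNED)
        self._check_sorted()

    def _check_sorted(self) -> None:
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    def sample_indices(self, population: str) -> np.ndarray:
        """Row indices of samples carrying a population label."""
        return np.array(
            [i for i, s in enumerate(self.samples) if self.populations[s] == population],
            dtype=np.intp,
        )

    def population_labels(self) -> list[str]:
        """Distinct labels in sample order (unassigned included if present)."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.populations[s], None)
        return list(seen)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given site index/mask (order kept)."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            populations=dict(self.populations),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            calls=self.calls[:, idx],
        )

    def site_mask(self, chromosome: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of sites inside [start, end] (1-based inclusive)."""
        return (self.chrom == chromosome) & (self.pos >= start) & (self.pos <= end)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.populations == other.populations
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.calls, other.calls)
        )


@dataclass(frozen=True)
class SiteFilterConfig:
    """Site-retention thresholds.

    min_maf
        Minor allele frequency must be strictly greater than this
        (computed on non-missing allele copies).
    min_integrity
        Fraction of samples with a non-missing call must be >= this.
    cluster_window_bp / cluster_max_snps
        Any window of ``cluster_window_bp`` consecutive bases containing more
        than ``cluster_max_snps`` SNPs has all its SNPs removed.
    """

    min_maf: float = 0.05
    min_integrity: float = 0.5
    cluster_window_bp: int = 5
    cluster_max_snps: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_maf < 0.5):
            raise ValueError("min_maf must be in [0, 0.5)")
        if not (0.0 <= self.min_integrity <= 1.0):
            raise ValueError("min_integrity must be in [0, 1]")
        if self.cluster_window_bp < 1:
            raise ValueError("cluster_window_bp must be >= 1")


@dataclass
class FilterReport:
    """Removal counts per rule; rules are attributed in order MAF ->
    integrity -> cluster so the counts plus retained sites sum to the input."""

    n_input: int = 0
    removed_maf: int = 0
    removed_integrity: int = 0
    removed_cluster: int = 0
    n_retained: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["input", "maf", "integrity", "cluster", "retained"],
                "sites": [
                    self.n_input,
                    self.removed_maf,
                    self.removed_integrity,
                    self.removed_cluster,
                    self.n_retained,
                ],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# population map
# ---------------------------------------------------------------------------

def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (sample, population label) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    if df["sample"].duplicated().any():
        dups = sorted(df.loc[df["sample"].duplicated(), "sample"])
        raise ValueError(f"duplicate samples in popmap: {dups}")
    return dict(zip(df["sample"], df["population"]))


def write_popmap(popmap: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(popmap.items()).to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, popmap: dict[str, str] | str | Path | None = None,
             ) -> GenotypeMatrix:
    """Read a VCF (v4.2) into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are dropped (with a logged count).
    ``popmap`` may be a dict or a path to a 2-column TSV; it must cover a
    subset of the VCF samples — VCF samples it does not mention are labelled
    :data:`UNASSIGNED`, and popmap samples absent from the VCF are an error.
    """
    from cyvcf2 import VCF

    if popmap is None:
        popmap = {}
    elif not isinstance(popmap, dict):
        popmap = read_popmap(popmap)

    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    extra = sorted(set(popmap) - set(samples))
    if extra:
        raise ValueError(f"popmap samples absent from VCF: {extra}")

    chrom: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    rows: list[np.ndarray] = []
    n_dropped = 0
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    remap = np.array([0, 1, MISSING, 2], dtype=np.int8)
    try:
        for rec in vcf:
            if len(rec.ALT) != 1 or not rec.is_snp:
                n_dropped += 1
                continue
            chrom.append(rec.CHROM)
            pos.append(rec.POS)
            ref.append(rec.REF)
            alt.append(rec.ALT[0])
            rows.append(remap[np.asarray(rec.gt_types)])
    except Exception as exc:
        raise VcfParseError(
            f"malformed VCF record in {path} near "
            f"{chrom[-1] + ':' + str(pos[-1]) if pos else 'start'}: {exc}"
        ) from exc
    if n_dropped:
        logger.info("read_vcf: dropped %d multi-allelic/non-SNP records", n_dropped)

    calls = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    populations = {s: popmap.get(s, UNASSIGNED) for s in samples}
    return GenotypeMatrix(samples, populations, np.array(chrom, dtype=object),
                          np.array(pos), np.array(ref, dtype=object),
                          np.array(alt, dtype=object), calls)


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write the matrix as an uncompressed VCF v4.2; round-trips exactly
    through :func:`read_vcf`."""
    path = Path(path)
    contigs = list(pd.unique(gm.chrom))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popsweep\n")
        for c in contigs:
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j in range(gm.n_sites):
            gts = "\t".join(_GT[int(g)] for g in gm.calls[:, j])
            fh.write(f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------------

def _allele_freq(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt frequency, non-missing allele-copy count) over all samples."""
    ok = gm.calls >= 0
    n_alleles = 2 * ok.sum(axis=0)
    alt = np.where(ok, gm.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return p, n_alleles


def _cluster_mask(chrom: np.ndarray, pos: np.ndarray, window_bp: int,
                  max_snps: int) -> np.ndarray:
    """True for sites belonging to a window of ``window_bp`` consecutive bases
    containing more than ``max_snps`` SNPs (all members of the offending
    window are flagged)."""
    bad = np.zeros(pos.size, dtype=bool)
    for c in pd.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        p = pos[sel]
        # window anchored at each SNP: [p_i, p_i + window_bp - 1]
        hi = np.searchsorted(p, p + window_bp - 1, side="right")
        lo = np.arange(p.size)
        offending = np.flatnonzero(hi - lo > max_snps)
        if offending.size:
            # flag every site of every offending window via a coverage diff
            cov = np.zeros(p.size + 1, dtype=np.int64)
            np.add.at(cov, offending, 1)
            np.add.at(cov, hi[offending], -1)
            bad[sel[np.cumsum(cov[:-1]) > 0]] = True
    return bad


def filter_sites(gm: GenotypeMatrix, cfg: SiteFilterConfig = SiteFilterConfig(),
                 ) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the MAF / integrity / SNP-cluster filters.

    Retained sites have minor allele frequency strictly above ``cfg.min_maf``,
    call integrity (fraction non-missing) >= ``cfg.min_integrity``, and do not
    sit in any ``cfg.cluster_window_bp`` window holding more than
    ``cfg.cluster_max_snps`` SNPs.  The cluster rule removes every SNP of an
    offending window and is evaluated on the sites surviving the first two
    rules, which makes the whole filter idempotent.
    """
    report = FilterReport(n_input=gm.n_sites)
    if gm.n_sites == 0:
        return gm, report

    p, n_alleles = _allele_freq(gm)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    pass_maf = np.where(np.isnan(maf), False, maf > cfg.min_maf)
    report.removed_maf = int((~pass_maf).sum())

    integrity = (gm.calls >= 0).mean(axis=0)
    pass_integrity = integrity >= cfg.min_integrity
    report.removed_integrity = int((pass_maf & ~pass_integrity).sum())

    keep = pass_maf & pass_integrity
    idx = np.flatnonzero(keep)
    bad_cluster = _cluster_mask(gm.chrom[idx], gm.pos[idx],
                                cfg.cluster_window_bp, cfg.cluster_max_snps)
    report.removed_cluster = int(bad_cluster.sum())
    idx = idx[~bad_cluster]
    report.n_retained = idx.size
    return gm.take_sites(idx), report


# ---------------------------------------------------------------------------
# per-sample summaries and density arithmetic
# ---------------------------------------------------------------------------

def sample_heterozygosity(gm: GenotypeMatrix, chromosome: str | None = None,
                          start: int | None = None, end: int | None = None,
                          ) -> pd.Series:
    """Heterozygosity percentage per sample.

    H(%) = 100 * (#het calls) / (#non-missing calls), optionally restricted to
    a window [start, end] on one chromosome (1-based inclusive).  Samples with
    no non-missing call in range get NaN.
    """
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    calls = gm.calls
    if chromosome is not None:
        calls = calls[:, gm.site_mask(chromosome, start or 1,
                                      end or int(gm.pos.max()))]
    het = (calls == 1).sum(axis=1)
    nonmiss = (calls >= 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(nonmiss > 0, 100.0 * het / np.maximum(nonmiss, 1), np.nan)
    return pd.Series(h, index=gm.samples, name="heterozygosity_pct")


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding (0.25 -> 0.3 at 1 decimal), as used for all
    reported densities and percentages."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def variant_density(count: int, span_kb: float, decimals: int = 1) -> float:
    """Variants per kb over a span given in kb, half-up rounded."""
    if span_kb <= 0:
        raise ValueError("span_kb must be > 0")
    return round_half_up(count / span_kb, decimals)
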