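# popsweep

Two-population divergence and selective-sweep scanning from biallelic-SNP
genotype matrices.

`popsweep` implements the population-genomic half of a crop resequencing
study: given a VCF of cohort genotypes and a sample→population map (for
example hard-seeded `H` versus soft-seeded `S` pomegranate varieties), it

- filters sites on minor allele frequency (> 0.05), call integrity (≥ 0.5)
  and SNP clustering (≤ 2 SNPs per 5 bp window);
- computes nucleotide diversity (π), Tajima's *D* and F_ST (Hudson
  ratio-of-sums by default, Weir–Cockerham selectable) over 100 kb sliding
  windows advancing in 10 kb steps;
- calls **selective-sweep regions**: a window is a candidate for population
  *X* when the diversity ratio π(other)/π(X) exceeds a cut-off derived from
  label-permutation tests *and* the window passes an F_ST rule (top-5%
  outlier set or an explicit threshold such as F_ST > 0.55); adjacent
  candidates are merged, annotated with overlapping genes from a GFF3 and
  tested for pathway enrichment (upper-tail hypergeometric,
  Benjamini–Hochberg);
- characterises structure: LD decay curves of genotype r² with a
  permutation test for between-population decay differences, Kimura
  two-parameter distances with a bootstrapped neighbour-joining tree,
  Patterson-standardised genotype PCA, and the membership rule (> 0.7) for
  externally computed admixture proportions;
- ships a **ground-truthed cohort simulator**: Balding–Nichols population
  frequencies parameterised directly by F (Beta(p(1−F)/F, (1−p)(1−F)/F)
  around an ancestral p ~ U(0.05, 0.95)), injected sweeps modelled as local
  fixation that divides expected heterozygosity by a configured factor,
  per-call missingness, optional distance-decaying LD, plus toy GFF3/pathway
  fixtures and base-level recovery scoring.

The statistics follow the standard definitions: per-site
π = (n/(n−1))·2p(1−p) summed over sites and divided by window length
(equal to the mean pairwise difference);
D = (π_total − S/a₁)/√(e₁S + e₂S(S−1)) with the usual constants;
Hudson F_ST as the ratio of sums of (p₁−p₂)² − p₁(1−p₁)/(n₁−1) −
p₂(1−p₂)/(n₂−1) over p₁(1−p₂) + p₂(1−p₁);
K2P distance d = −½ ln[(1−2P−Q)√(1−2Q)].

## Worked example

`examples/` holds one short script per capability. The sweep scan on the
benchmark condition — one 40 Mb chromosome with a single 2 Mb sweep
(10-fold diversity reduction in `H`) on an F = 0.26 background:

```bash
$ python examples/02_sweep_scan.py
permutation cut-off for pi_S/pi_H at alpha=0.05: 1.112
chrom    start      end  length_mb  mean_fst  mean_ratio
 chr1 19950001 22030000       2.08  0.551017   12.280566
sensitivity = 1.00, base-level FDR = 0.04
```

The scan recovers the injected 20–22 Mb sweep as a single 2.08 Mb region:
the diversity ratio inside it averages ~12 (the 10-fold simulated reduction
plus sampling noise), window F_ST rises to ~0.55 against the 0.26
background, and 96% of called bases lie inside the true sweep.

Library use mirrors the scripts:

```python
import popsweep as ps

gm = ps.read_vcf("cohort.vcf", "popmap.tsv")
gm, report = ps.filter_sites(gm)
windows = ps.make_windows({"chr1": 46_000_000})
stats = ps.compute_window_stats(gm, windows, "H", "S")
```

A thin CLI wraps the same pipeline: `popsweep simulate` writes a synthetic
cohort, `popsweep run --config cfg.yaml` executes
filter → stats → sweep → LD → tree → PCA → enrichment and writes TSV/BED/
Newick outputs plus a JSON manifest; single stages run as subcommands.

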