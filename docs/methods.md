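# Methods

## Scope and data model

`popsweep` analyses a cohort of diploid samples genotyped at biallelic SNPs.
The in-memory container (`GenotypeMatrix`) stores alt-allele dosages
(0/1/2, −1 missing) with 1-based coordinates strictly increasing within each
chromosome, plus a sample→population map; samples without a label are
`unassigned` and are carried through I/O and structure analyses but excluded
from two-population statistics. Multi-allelic and non-SNP VCF records are
dropped at read time (not split) because every downstream statistic assumes
biallelic sites. Coordinates are 1-based inclusive everywhere internally;
BED exports convert to 0-based half-open.

## Site filters

Three retention rules, applied and attributed in a fixed order so the
removal counts plus retained sites always sum to the input:

1. **MAF** — minor allele frequency strictly greater than `min_maf`
   (default 0.05), computed on non-missing allele copies;
2. **integrity** — fraction of samples with a call at least `min_integrity`
   (default 0.5);
3. **cluster** — any 5 bp window containing more than 2 SNPs has *all* its
   SNPs removed. Removing the whole offending window (rather than an
   arbitrary "excess") is deterministic and mirrors standard cluster-filter
   behaviour. The rule is evaluated on the sites surviving the first two
   rules, which makes the composite filter idempotent.

The strict `>` for MAF and `≥` for integrity match the thresholds' printed
operators. Reported densities and percentages round half-up at the stated
decimals.

## Window statistics

Windows are `size_bp` = 100 kb sliding by `step_bp` = 10 kb, starting at
position 1 and emitted only when fully contained in the chromosome. Window
aggregation uses prefix sums over per-site arrays, so full-genome scans and
label permutations cost a cumulative sum plus two binary searches per
window.

- **π** per site: Σ over sites of (nᵢ/(nᵢ−1))·2pᵢ(1−pᵢ) divided by window
  length, with pᵢ, nᵢ the non-missing alt frequency and allele-copy count.
  This unbiased frequency form equals the mean pairwise difference among
  sampled copies (verified exactly against an enumeration oracle). A site
  contributes to a population only where ≥ 2 copies are callable. Values
  are per site; reports also render per kb (×1000) because the source
  study's "per kb" unit is ambiguous at the magnitudes it prints.
- **Tajima's D** uses the standard a₁…e₂ constants. Missing data makes the
  copy number vary across sites, but the constants need a single n; we use
  the rounded mean callable copy count over segregating sites in the window
  (exact when data are complete, a second-order approximation otherwise).
  Windows with S = 0 are undefined and excluded from summaries.
- **F_ST** defaults to Hudson's estimator as a ratio of sums across sites —
  chosen because it is least sensitive to unequal sample sizes (the target
  design is 8 vs 12) — with the two-population Weir–Cockerham estimator
  (with observed-heterozygosity terms) selectable. Negative estimates are
  reported as computed. Genome-wide F_ST is reported both pooled
  (ratio-of-sums over all sites) and window-averaged, since either
  convention is defensible for a headline "average F_ST".
- **Diversity ratio** π_num/π_den per window; 0/0 is undefined, x/0 with
  x > 0 is capped at 100 and flagged.

Windows with fewer than 10 matrix sites (configurable) are masked from
sweep scanning to control estimator variance.

## Sweep calling

The permutation cut-off shuffles sample labels across the two populations'
samples (the natural exchangeable null for "no differentiation"), recomputes
the windowed diversity ratio each time, pools all permuted window values
genome-wide and takes the (1 − α) quantile (α = 0.05). Pooling genome-wide
rather than per-window keeps the cut-off stable at modest permutation
counts; calibration is checked empirically (type-I error ≈ α on F = 0
cohorts). Note the null requires exchangeable labels: with a differentiated
background the cut-off is anticonservative by design, which is exactly what
makes differentiated outlier windows callable.

Candidate windows for population X require ratio(other/X) ≥ cut-off **and**
an F_ST rule — the top-5% outlier set by default, or an explicit threshold.
"Combining" the two lines of evidence is interpreted as conjunction (the
operator and both criteria are config-exposed; `combine="or"` relaxes it).
Top-fraction selection takes the ⌈f·n⌉-th largest defined value as the
threshold and includes all ties, making it deterministic and
order-independent. Candidates are merged when overlapping or separated by at
most `merge_gap_bp` (default = the 10 kb step, so adjacent sliding windows
merge); region length is reported in Mb, half-up at 2 decimals.

Genes belong to a region if their GFF3 span overlaps it by ≥ 1 bp
(gffutils interval queries). Enrichment is the upper-tail hypergeometric
test per pathway over a user-supplied gene→pathway map, with BH correction
by default (the study said only "corrected P"); pathways flagged at
adjusted p < 0.05. Only pathways containing at least one region gene are
tested.

One structural caveat: a top-5% F_ST rule caps the candidate set at 5% of
windows, so a sweep whose footprint exceeds 5% of the scanned genome cannot
be fully recovered under the conjunction — the default cohort's large
chromosome-1 region (26.2 of 326 Mb ≈ 8%) is deliberately in this regime
and is recovered piecewise; the explicit-threshold rule suits such genomes.

## LD decay

r² is the squared Pearson correlation of unphased genotype dosages across
samples, with pairwise deletion of missing calls — a composite,
deterministic quantity that differs from haplotype-frequency r² (which would
need phase or an EM step; data here are unphased). Pairs are taken within
chromosomes up to 1000 kb and binned (10 kb default); the genome-wide curve
pools bins over chromosomes, i.e. a pair-count-weighted average. Pairs with
a monomorphic member are skipped; under independence mean r² sits at the
~1/n sampling floor, which is visible in all curves.

The decay comparison uses the difference of areas under the two binned
curves over bins occupied in both, with sample-label permutation for the
null and a two-sided (1 + exceed)/(n_perm + 1) p-value; the population with
the smaller area decays faster. Power analysis on simulated data shows the
test needs many independent LD blocks (many chromosomes or long spans) and
is sample-size limited at 8 + 12; the test-suite power check therefore uses
20 + 20 samples over 24 chromosome blocks, where the direction and p < 0.01
are decisively recovered.

## Structure

SNP matrices are bridged to sequence space by emitting one base per site
per sample: hom calls give the ref/alt base, missing gives a gap (excluded
pairwise), and heterozygotes are resolved by a seeded random allele
(default) or an IUPAC code excluded from comparisons — the source study
used an external tree program whose het handling is unstated, so both
policies are explicit here. K2P distance is
d = −½ ln[(1−2P−Q)√(1−2Q)] over pairwise compared columns; saturated pairs
(non-positive log arguments) are flagged undefined and are an error for
tree building. Neighbour-joining uses the Saitou–Nei agglomeration
(delegated to scikit-bio; exact on additive matrices, verified for all
random 4–8 taxon cases). Bootstrap support resamples SNP columns with
replacement and reports the percentage of replicates containing each
internal bipartition.

PCA follows the Patterson convention: monomorphic sites dropped, dosages
centred by 2p̂ and scaled by √(p̂(1−p̂)), missing values mean-imputed (zero
after centring), eigendecomposition of the sample×sample covariance;
variance fractions are eigenvalues over the full trace, so a reported top-k
subset sums to ≤ 1. Admixture proportions are consumed, not estimated
(membership > 0.7 assigns a cluster, otherwise "mixed"; rows must sum to 1
within 0.01).

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes,
not sequence-level realism. Defaults are the study conditions: 8 H + 12 S +
6 unassigned samples; 8 chromosomes (chr1 46 Mb, others 40 Mb) at 1 SNP/kb;
F = 0.26; 2% missingness; sweeps = a large chr1 region (16.33–42.53 Mb,
10-fold reduction, H) plus a 2 Mb region on chr3 (S). Balding–Nichols was
chosen over coalescent simulation for exact, direct control of F with no
external machinery; sweeps are modelled phenomenologically (probabilistic
local fixation that divides expected heterozygosity by exactly the
configured factor) because the scan detects diversity contrast, not
trajectories. Unassigned samples draw from the ancestral frequencies and
exercise the popmap-subset logic.

Sites are unlinked by default; setting `ld_decay_bp` adds LD through latent
uniform copying per allele copy (the copy survives between adjacent sites
with probability exp(−Δ/scale)), which preserves marginal frequencies
exactly while giving exponentially decaying r². What the simulator does
*not* emulate: mutation-model realism, linked selection footprints shaped
by recombination maps, call-quality artefacts, or indels — so passing
recovery tests demonstrates the scan logic under its own model assumptions,
not performance on real resequencing data.

The `recovery_benchmark_config` condition — one 40 Mb chromosome with a
single 2 Mb sweep (10×, H) on the F = 0.26 background — is the reference
experiment for sweep recovery: mean base-level sensitivity ≥ 0.8 and FDR
≤ 0.2 over 20 seeds, which the suite verifies (observed ≈ 0.97 / ≈ 0.04).

A separate K2P alignment simulator (site-independent evolution along a
Newick tree with the standard K80 transition probabilities, α + 2β = 1)
provides fixtures for distance/tree estimator-consistency checks.

## Numerical and engineering choices

- Half-up decimal rounding for all reported densities/percentages/lengths.
- Ratio cap 100 for π-ratios with a zero denominator; capped values flagged.
- Permutation p-values use the (1 + exceed)/(n + 1) convention; cut-offs use
  the empirical quantile of pooled permuted values.
- All RNG is `numpy.random.default_rng` seeded from explicit config fields;
  identical config ⇒ byte-identical outputs (manifests carry no wall-clock
  state).
- Problem sizes in the shipped experiments (window scans on 40–326 Mb
  simulated genomes, 100–300 permutations, 100 bootstrap replicates,
  LD on deterministically thinned sites, tree building on ≤ 20 k thinned
  SNPs) were chosen to keep each experiment at desk scale — seconds to a
  few minutes — while leaving estimator error well inside the asserted
  tolerances.

## Known limitations

- Tajima's D with heavy, uneven missingness uses a single per-window n
  (rounded mean over segregating sites); windows mixing very different
  callable depths are approximated.
- Genotype-based r² underestimates haplotype r² when phase matters;
  comparisons between populations remain valid since both use the same
  definition.
- The permutation decay-difference test has limited power at small sample
  sizes (8 + 12); report effect direction alongside p.
- The hypergeometric enrichment assumes an exchangeable background gene set;
  no gene-length or SNP-density bias correction is applied.
- Sweep calling under the top-fraction F_ST rule cannot recover swept
  fractions of the genome larger than the fraction itself (see above).
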