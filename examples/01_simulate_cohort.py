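"""Simulate a two-population cohort and check its differentiation.

Builds the default synthetic panel (8 hard-seeded H + 12 soft-seeded S + 6
unassigned samples, 8 chromosomes at ~1 SNP/kb, Balding-Nichols F = 0.26,
a large sweep on chromosome 1) and verifies that the Hudson FST estimate
recovers the simulation parameter.
"""

import popsweep as ps

cfg = ps.CohortConfig(seed=1, sweeps=[])  # background differentiation only
gm, truth = ps.simulate_cohort(cfg)
print(f"cohort: {gm.n_samples} samples, {gm.n_sites} SNPs over "
      f"{len(cfg.chrom_lengths)} chromosomes")

fst = ps.genome_fst(gm, "H", "S")
print(f"genome-wide Hudson FST = {fst:.3f} (simulated F = {cfg.fst})")

het = ps.sample_heterozygosity(gm)
print(f"mean sample heterozygosity = {het.mean():.1f}%")

# With sweeps disabled the Hudson estimate isolates the Balding-Nichols
# background and should sit within sampling error of F; injected sweeps
# (the default config carries them) push the genome-wide value upward.
# Heterozygosity is the per-sample percentage of heterozygous calls.
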