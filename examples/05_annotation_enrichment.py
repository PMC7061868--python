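"""Annotate sweep regions with genes and test pathway enrichment.

Writes a toy GFF3 + pathway map, annotates a called region with the genes it
overlaps, and runs the upper-tail hypergeometric test with BH correction.
"""

import tempfile
from pathlib import Path

import pandas as pd

import popsweep as ps
from popsweep.simulate import simulate_genes_gff3

with tempfile.TemporaryDirectory() as d:
    lengths = {"chr1": 1_000_000}
    gene_ids, pathway_map = simulate_genes_gff3(lengths, Path(d) / "genes.gff3",
                                                seed=6)
    regions = pd.DataFrame({"chrom": ["chr1"], "start": [200_001],
                            "end": [400_000]})
    annotated = ps.annotate_regions(regions, str(Path(d) / "genes.gff3"))
    print(f"region chr1:200001-400000 overlaps "
          f"{annotated['n_genes'].iloc[0]} of {len(gene_ids)} genes")

    region_genes = set(annotated["gene_ids"].iloc[0].split(","))
    background = set(gene_ids)
    enr = ps.enrich_hypergeometric(region_genes, background, pathway_map)
    print(enr.head(5).to_string(index=False))

# k of K pathway genes among the n region genes out of N background genes;
# p is the upper-tail hypergeometric probability, p_adj the BH-corrected
# value (flagged significant below 0.05).  A random region should show no
# enrichment.
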