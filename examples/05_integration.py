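"""Join methylome and transcriptome: expression bins, Spearman correlation
of region methylation with expression, and E/M quadrants of DEG-DMG genes.
"""

from pathlib import Path

import pandas as pd

from hybridscope import (
    CrossSimConfig, simulate_cross, read_gff3, read_cx_report, call_dmrs,
    annotate_dmr_genes, compute_fpkm, call_degs, bin_expression,
    methylation_by_bin, region_levels, common_genes,
)
from hybridscope.genemodels import genes_table

out = simulate_cross(CrossSimConfig(n_genes=100, seed=1), Path("example_cross"))
counts = pd.read_csv(out["counts"], sep="\t", index_col=0)
models = read_gff3(str(out["gff3"]))
lengths = genes_table(models).set_index("gene_id").eval("end - start")
fpkm = compute_fpkm(counts, lengths)
expr = fpkm[[c for c in fpkm.columns if c.startswith("hybrid")]].mean(axis=1)

print("expression bins:", bin_expression(expr).value_counts().to_dict())

hybrid = read_cx_report(str(out["methylation"]["hybrid"]))
levels = region_levels(hybrid, models)
profile = methylation_by_bin(expr, levels)
print(profile[["region", "rho", "p", "n"]].round(3).to_string(index=False))
# rho is the gene-wise Spearman correlation between expression and region
# methylation; the generator plants no coupling, so rho is near zero.

maternal = read_cx_report(str(out["methylation"]["maternal"]))
dmgs = annotate_dmr_genes(call_dmrs(hybrid, maternal), models)
groups = {c: ("hybrid" if c.startswith("hybrid") else "maternal") for c in counts.columns}
degs = call_degs(counts, groups)
records = common_genes(degs, dmgs)
print(f"{records['gene_id'].nunique()} genes both DE and DM")
print(records["quadrant"].value_counts().to_string())
# E+M- for example means up-regulated in the hybrid with a hypomethylated
# differential region.
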