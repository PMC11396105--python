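"""Generate a synthetic hybrid cross and inspect its ground truth.

The generator emits everything the downstream stages consume: a parental
VCF, gene models, per-replicate allele-depth tables, methylation tables for
both groups, a count matrix, ortholog similarity tables and a ground-truth
manifest of planted effects.
"""

from collections import Counter
from pathlib import Path

from hybridscope import CrossSimConfig, simulate_cross

workdir = Path("example_cross")
config = CrossSimConfig(n_genes=100, seed=1)
out = simulate_cross(config, workdir)

truth = out["truth"]
print("files:", sorted(p.name for p in workdir.iterdir()))
print("planted allelic bias:", Counter(truth.biased_genes.values()))
print("planted DMR windows:", len(truth.dmr_windows), "e.g.", truth.dmr_windows[0])
print("planted DEGs:", Counter(truth.deg_genes.values()))
# The Counter lines show how many genes carry each planted effect; the DMR
# tuple is (chrom, start, end, context, direction) of one planted window.
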