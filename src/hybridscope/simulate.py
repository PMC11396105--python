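"""Synthetic hybrid-cross generator with known ground truth.

Emulates the data layout of a two-species cross profiled by parental
whole-genome resequencing (diagnostic SNPs), hybrid RNA-seq with
allele-resolved read counts, whole-genome bisulfite sequencing in three
cytosine contexts, and a bulk count matrix for hybrid vs maternal groups.

Everything downstream operates on counts, so methylation is emitted directly
as per-cytosine (methylated, unmethylated) pairs and allele-specific
expression as per-SNP allele depths — no read-level simulation. All
randomness flows from a single seed; each output file draws from a substream
derived from a stable label, so adding an output never perturbs the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

_BASES = "ACGT"
_CONTEXTS = ("CG", "CHG", "CHH")
GENES_PER_CHROM = 50
_GENE_GAP = 5000  # intergenic spacing, keeps 2 kb flanks off neighbouring bodies
_SITE_SPACING = 10  # one cytosine every 10 bp within gene body +/- 2 kb


class ConfigError(ValueError):
    """Raised when a CrossSimConfig field is out of range; names the field."""


@dataclass
class CrossSimConfig:
    """Parameters of the synthetic cross.

    Defaults encode the study conditions the downstream callers are designed
    for: ~5 exonic diagnostic SNPs per gene (diverged parental species),
    4-fold allelic imbalance in planted biased genes, 60 allele-informative
    reads per gene per replicate, high CG methylation (0.8) with near-zero
    non-CG methylation as in vertebrate genomes, planted CG DMRs shifted by
    0.5 (twice the CG calling threshold) at 20x cytosine coverage, and
    4-fold planted expression changes with moderate biological dispersion.
    """

    n_genes: int = 200
    gene_length_range: tuple[int, int] = (1000, 2000)
    snps_per_gene: float = 5.0
    frac_paternal_biased: float = 0.15
    frac_maternal_biased: float = 0.15
    bias_fold: float = 4.0
    n_replicates: int = 3
    rna_depth_per_gene: float = 60.0
    frac_dmr_genes: float = 0.2
    dmr_delta: float = 0.5
    meth_baseline: dict = field(
        default_factory=lambda: {"CG": 0.8, "CHG": 0.02, "CHH": 0.02}
    )
    meth_coverage: float = 20.0
    frac_deg: float = 0.3
    deg_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_paternal_biased", "frac_maternal_biased", "frac_dmr_genes", "frac_deg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.frac_paternal_biased + self.frac_maternal_biased > 1.0:
            raise ConfigError(
                "frac_paternal_biased + frac_maternal_biased must be <= 1"
            )
        if not 0.0 <= self.dmr_delta <= 1.0:
            raise ConfigError(f"dmr_delta must be in [0, 1], got {self.dmr_delta}")
        for ctx, v in self.meth_baseline.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"meth_baseline[{ctx}] must be in [0, 1], got {v}")
        if self.n_genes <= 0:
            raise ConfigError(f"n_genes must be positive, got {self.n_genes}")
        if self.n_replicates <= 0:
            raise ConfigError(f"n_replicates must be positive, got {self.n_replicates}")
        if self.bias_fold <= 1.0:
            raise ConfigError(f"bias_fold must be > 1, got {self.bias_fold}")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ConfigError(f"gene_length_range must be a positive interval, got {self.gene_length_range}")


@dataclass
class GroundTruth:
    """Planted effects, keyed by the gene/window identifiers in the outputs."""

    biased_genes: dict  # gene_id -> {"paternal" | "maternal" | "none"}
    dmr_windows: list  # [(chrom, start, end, context, direction), ...]
    deg_genes: dict  # gene_id -> {"up" | "down" | "ns"}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "biased_genes": self.biased_genes,
            "dmr_windows": [list(w) for w in self.dmr_windows],
            "deg_genes": self.deg_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            biased_genes=payload["biased_genes"],
            dmr_windows=[tuple(w) for w in payload["dmr_windows"]],
            deg_genes=payload["deg_genes"],
        )


def _rng(seed: int, label: str) -> np.random.Generator:
    # stable per-file substream: seed entropy + crc32 of the label
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


def _gene_layout(config: CrossSimConfig) -> pd.DataFrame:
    """Place genes on pseudo-chromosomes: 50 per chromosome, non-overlapping,
    alternating strands, 0-based half-open coordinates."""
    rng = _rng(config.seed, "layout")
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    rows = []
    for i in range(config.n_genes):
        chrom_idx, pos_idx = divmod(i, GENES_PER_CHROM)
        if pos_idx == 0:
            cursor = _GENE_GAP
        start = cursor
        end = start + int(lengths[i])
        cursor = end + _GENE_GAP
        rows.append(
            {
                "gene_id": f"Pg{i + 1:06d}",
                "chrom": f"chr{chrom_idx + 1}",
                "start": start,
                "end": end,
                "strand": "+" if i % 2 == 0 else "-",
            }
        )
    return pd.DataFrame(rows)


def _write_gff3(genes: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples(index=False):
            s, e = g.start + 1, g.end  # to 1-based inclusive
            base = f"{g.chrom}\tsim\t"
            tail = f"\t{s}\t{e}\t.\t{g.strand}\t.\t"
            fh.write(f"{base}gene{tail}ID={g.gene_id}\n")
            fh.write(f"{base}mRNA{tail}ID={g.gene_id}.t1;Parent={g.gene_id}\n")
            fh.write(f"{base}exon{tail}ID={g.gene_id}.e1;Parent={g.gene_id}.t1\n")


def _write_fasta_stub(genes: pd.DataFrame, path: Path) -> None:
    # placeholder sequence only; coordinates in the GFF exceed these stubs
    with open(path, "w") as fh:
        for chrom in genes["chrom"].unique():
            fh.write(f">{chrom}\n{'N' * 60}\n")


def _plant_snps(config: CrossSimConfig, genes: pd.DataFrame) -> pd.DataFrame:
    """Diagnostic SNPs: Poisson count per gene, uniform within the exon
    (= gene body here), father homozygous reference, mother homozygous alt."""
    rng = _rng(config.seed, "snps")
    rows = []
    for g in genes.itertuples(index=False):
        k = rng.poisson(config.snps_per_gene)
        k = min(k, g.end - g.start)
        if k == 0:
            continue
        offsets = np.sort(rng.choice(g.end - g.start, size=k, replace=False))
        for off in offsets:
            ref = _BASES[rng.integers(4)]
            alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "pos": g.start + int(off) + 1,  # VCF 1-based
                    "ref": ref,
                    "alt": alt,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "pos", "ref", "alt"])


def _write_vcf(config: CrossSimConfig, genes: pd.DataFrame, snps: pd.DataFrame, path: Path) -> None:
    """Write the parental VCF: planted diagnostic sites (father 0/0, mother
    1/1 on the paternal reference) plus decoy sites that are heterozygous or
    fail the standard hard filters, to exercise the filtering stage."""
    records = []
    for s in snps.itertuples(index=False):
        records.append(
            (s.chrom, s.pos, s.ref, s.alt,
             "QD=25.0;FS=1.0;MQ=60.0", "0/0:90", "1/1:90")
        )
    # decoys: one heterozygous and one quality-failing site per ~10 genes
    for g in genes.iloc[::10].itertuples(index=False):
        pos_het = g.start - 100  # intergenic
        if pos_het > 0:
            records.append(
                (g.chrom, pos_het, "A", "G", "QD=25.0;FS=1.0;MQ=60.0", "0/1:90", "0/0:90")
            )
        pos_bad = g.end + 100
        records.append(
            (g.chrom, pos_bad, "C", "T", "QD=1.0;FS=80.0;MQ=20.0", "0/0:90", "1/1:90")
        )
    records.sort(key=lambda r: (int(r[0][3:]), r[1]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in genes["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tFATHER\tMOTHER\n")
        for chrom, pos, ref, alt, info, fgt, mgt in records:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t100\t.\t{info}\tGT:GQ\t{fgt}\t{mgt}\n"
            )


def _assign_bias(config: CrossSimConfig, genes: pd.DataFrame) -> dict:
    rng = _rng(config.seed, "bias-design")
    n = config.n_genes
    n_pat = int(round(config.frac_paternal_biased * n))
    n_mat = int(round(config.frac_maternal_biased * n))
    order = rng.permutation(genes["gene_id"].to_numpy())
    labels = {g: "none" for g in genes["gene_id"]}
    for g in order[:n_pat]:
        labels[g] = "paternal"
    for g in order[n_pat:n_pat + n_mat]:
        labels[g] = "maternal"
    return labels


def _write_allele_depths(
    config: CrossSimConfig, snps: pd.DataFrame, bias: dict, outdir: Path
) -> list[Path]:
    """Per replicate: total informative reads per gene ~ Poisson(depth),
    split multinomially across the gene's SNPs, then binomially between
    alleles at p = fold/(fold+1) (paternal-biased), 1/(fold+1)
    (maternal-biased) or 1/2 (unbiased)."""
    f = config.bias_fold
    p_by_label = {"paternal": f / (f + 1.0), "maternal": 1.0 / (f + 1.0), "none": 0.5}
    paths = []
    snp_groups = dict(tuple(snps.groupby("gene_id", sort=False))) if len(snps) else {}
    gene_ids = snps["gene_id"].unique() if len(snps) else []
    for rep in range(1, config.n_replicates + 1):
        rng = _rng(config.seed, f"rna-rep{rep}")
        rows = []
        for gene_id in gene_ids:
            gsnps = snp_groups[gene_id]
            total = rng.poisson(config.rna_depth_per_gene)
            k = len(gsnps)
            per_snp = rng.multinomial(total, np.full(k, 1.0 / k))
            p_pat = p_by_label[bias[gene_id]]
            pat = rng.binomial(per_snp, p_pat)
            for (snp, n_s, n_pat) in zip(gsnps.itertuples(index=False), per_snp, pat):
                rows.append(
                    {
                        "chrom": snp.chrom,
                        "pos": snp.pos,
                        "gene_id": gene_id,
                        "replicate": f"rep{rep}",
                        "pat_count": int(n_pat),
                        "mat_count": int(n_s - n_pat),
                    }
                )
        path = outdir / f"allele_depth_rep{rep}.tsv"
        pd.DataFrame(
            rows, columns=["chrom", "pos", "gene_id", "replicate", "pat_count", "mat_count"]
        ).to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def _cytosine_sites(genes: pd.DataFrame, flank: int = 2000) -> pd.DataFrame:
    """Fixed cytosine grid: one site every 10 bp across each gene body and
    its +/- 2 kb flanks, contexts cycling CG/CHG/CHH, strands alternating."""
    frames = []
    for g in genes.itertuples(index=False):
        lo = max(0, g.start - flank)
        hi = g.end + flank
        pos = np.arange(lo - lo % _SITE_SPACING + _SITE_SPACING, hi, _SITE_SPACING)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": g.chrom,
                    "pos": pos + 1,  # 1-based, CX-report style
                    "strand": np.where(pos // _SITE_SPACING % 2 == 0, "+", "-"),
                    "context": [
                        _CONTEXTS[i % 3] for i in pos // _SITE_SPACING
                    ],
                }
            )
        )
    sites = pd.concat(frames, ignore_index=True)
    sites = sites.drop_duplicates(["chrom", "pos"]).sort_values(
        ["chrom", "pos"], kind="stable"
    )
    return sites.reset_index(drop=True)


def _plant_dmrs(config: CrossSimConfig, genes: pd.DataFrame, window: int = 200) -> list:
    """Pick DMR genes and, for each, the first 200-bp tile fully inside the
    gene body; planted in the CG context, hypomethylated in the hybrid
    (baseline CG is high, so the shift must go down)."""
    rng = _rng(config.seed, "dmr-design")
    n_dmr = int(round(config.frac_dmr_genes * config.n_genes))
    chosen = rng.permutation(config.n_genes)[:n_dmr]
    windows = []
    for idx in np.sort(chosen):
        g = genes.iloc[int(idx)]
        start = ((g["start"] // window) + 1) * window
        end = start + window
        if end > g["end"]:
            continue  # gene too short to host an aligned tile
        windows.append((g["chrom"], int(start), int(end), "CG", "hypo"))
    return windows


def _write_methylomes(
    config: CrossSimConfig, genes: pd.DataFrame, dmr_windows: list, outdir: Path
) -> dict:
    sites = _cytosine_sites(genes)
    base = sites["context"].map(config.meth_baseline).to_numpy(float)
    # hybrid levels: baseline, except CG sites inside planted windows
    level_hybrid = base.copy()
    for chrom, start, end, context, direction in dmr_windows:
        mask = (
            (sites["chrom"] == chrom).to_numpy()
            & (sites["pos"].to_numpy() > start)
            & (sites["pos"].to_numpy() <= end)
            & (sites["context"] == context).to_numpy()
        )
        shift = -config.dmr_delta if direction == "hypo" else config.dmr_delta
        level_hybrid[mask] = np.clip(level_hybrid[mask] + shift, 0.0, 1.0)
    paths = {}
    for group, levels in (("hybrid", level_hybrid), ("maternal", base)):
        rng = _rng(config.seed, f"meth-{group}")
        cov = rng.poisson(config.meth_coverage, size=len(sites))
        m = rng.binomial(cov, levels)
        out = sites.copy()
        out["count_M"] = m
        out["count_U"] = cov - m
        path = outdir / f"methylation_{group}.cx.tsv"
        out.to_csv(path, sep="\t", index=False)
        paths[group] = path
    return paths


def _assign_degs(config: CrossSimConfig, genes: pd.DataFrame) -> dict:
    rng = _rng(config.seed, "deg-design")
    n_deg = int(round(config.frac_deg * config.n_genes))
    order = rng.permutation(genes["gene_id"].to_numpy())
    labels = {g: "ns" for g in genes["gene_id"]}
    for i, g in enumerate(order[:n_deg]):
        labels[g] = "up" if i % 2 == 0 else "down"
    return labels


def _write_counts(config: CrossSimConfig, genes: pd.DataFrame, degs: dict, path: Path) -> None:
    rng = _rng(config.seed, "counts")
    n = config.n_genes
    base_mean = rng.gamma(shape=2.0, scale=100.0, size=n) + 5.0
    fc = np.ones(n)
    labels = np.array([degs[g] for g in genes["gene_id"]])
    fc[labels == "up"] = 2.0 ** config.deg_log2fc
    fc[labels == "down"] = 2.0 ** (-config.deg_log2fc)
    disp = config.nb_dispersion
    r = 1.0 / disp

    def nb_draw(mu, size):
        return rng.negative_binomial(r, r / (r + mu), size=size)

    data = {"gene_id": genes["gene_id"]}
    for rep in range(1, config.n_replicates + 1):
        data[f"hybrid_{rep}"] = nb_draw(base_mean * fc, n)
    for rep in range(1, config.n_replicates + 1):
        data[f"maternal_{rep}"] = nb_draw(base_mean, n)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def _write_ortholog_hits(genes: pd.DataFrame, outdir: Path) -> dict:
    """All-vs-all similarity stubs: the true ortholog pair (Pg_i, Mg_i) gets
    the top bitscore in both directions, plus a weaker off-target hit."""
    pat = genes["gene_id"].tolist()
    mat = [g.replace("Pg", "Mg") for g in pat]
    ab_rows, ba_rows = [], []
    n = len(pat)
    for i, (p, m) in enumerate(zip(pat, mat)):
        ab_rows.append((p, m, 500.0, 1e-50))
        ba_rows.append((m, p, 500.0, 1e-50))
        ab_rows.append((p, mat[(i + 1) % n], 120.0, 1e-8))
        ba_rows.append((m, pat[(i + 1) % n], 120.0, 1e-8))
    paths = {}
    for name, rows in (("ab", ab_rows), ("ba", ba_rows)):
        path = outdir / f"ortholog_hits_{name}.tsv"
        pd.DataFrame(rows, columns=["qseqid", "sseqid", "bitscore", "evalue"]).to_csv(
            path, sep="\t", index=False, header=False,
            columns=["qseqid", "sseqid", "bitscore", "evalue"],
        )
        paths[name] = path
    return paths


def simulate_cross(config: CrossSimConfig, outdir: str | Path) -> dict:
    """Generate the full synthetic cross into ``outdir``.

    Returns a dict of output paths plus the ``GroundTruth``. Identical
    config and seed produce byte-identical files.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genes = _gene_layout(config)
    snps = _plant_snps(config, genes)
    bias = _assign_bias(config, genes)
    degs = _assign_degs(config, genes)
    dmr_windows = _plant_dmrs(config, genes)

    gff = outdir / "genes.gff3"
    _write_gff3(genes, gff)
    fasta = outdir / "genome.fa"
    _write_fasta_stub(genes, fasta)
    vcf = outdir / "parents.vcf"
    _write_vcf(config, genes, snps, vcf)
    depth_paths = _write_allele_depths(config, snps, bias, outdir)
    meth_paths = _write_methylomes(config, genes, dmr_windows, outdir)
    counts = outdir / "counts.tsv"
    _write_counts(config, genes, degs, counts)
    hit_paths = _write_ortholog_hits(genes, outdir)

    truth = GroundTruth(biased_genes=bias, dmr_windows=dmr_windows, deg_genes=degs)
    truth_path = outdir / "ground_truth.json"
    truth.to_json(truth_path)
    config_path = outdir / "config.json"
    config_path.write_text(json.dumps(asdict(config), indent=1, sort_keys=True, default=list))

    return {
        "gff3": gff,
        "fasta": fasta,
        "vcf": vcf,
        "allele_depths": depth_paths,
        "methylation": meth_paths,
        "counts": counts,
        "ortholog_hits": hit_paths,
        "ground_truth": truth_path,
        "truth": truth,
        "genes": genes,
    }


def simulate_null_methylome(config: CrossSimConfig, outdir: str | Path) -> dict:
    """Two methylation tables drawn from identical per-site levels.

    Both groups are exchangeable binomial draws at the configured per-context
    baselines; any differential call on this pair is a false positive.
    With ``meth_coverage == 0`` the tables are empty.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = _gene_layout(config)
    sites = _cytosine_sites(genes)
    levels = sites["context"].map(config.meth_baseline).to_numpy(float)
    paths = {}
    for group in ("groupA", "groupB"):
        rng = _rng(config.seed, f"null-meth-{group}")
        out = sites.copy()
        if config.meth_coverage <= 0:
            out = out.iloc[0:0]
            out["count_M"] = pd.Series(dtype=int)
            out["count_U"] = pd.Series(dtype=int)
        else:
            cov = rng.poisson(config.meth_coverage, size=len(sites))
            m = rng.binomial(cov, levels)
            out["count_M"] = m
            out["count_U"] = cov - m
        path = outdir / f"null_methylation_{group}.cx.tsv"
        out.to_csv(path, sep="\t", index=False)
        paths[group] = path
    return paths
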