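"""Gene-model handling: GFF3 reading and strand-aware region derivation.

Coordinates follow the usual conventions: GFF3 and VCF are 1-based inclusive
on disk; every in-memory interval in this package is 0-based half-open.
The conversion happens here and in the VCF reader, nowhere else.
"""

from __future__ import annotations

import pandas as pd
import gffutils

REGION_LABELS = ("upstream2kb", "gene_body", "downstream2kb")


def read_gff3(path: str) -> pd.DataFrame:
    """Load gene models from a GFF3 file.

    Returns a DataFrame with one row per exon:
    ``gene_id, chrom, strand, gene_start, gene_end, exon_start, exon_end``
    (all starts/ends 0-based half-open). Genes without exon children get a
    single exon spanning the gene body.
    """
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        exons = list(db.children(gene, featuretype="exon"))
        if not exons:
            exons = [gene]
        for ex in exons:
            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": gene.seqid,
                    "strand": gene.strand,
                    "gene_start": gene.start - 1,
                    "gene_end": gene.end,
                    "exon_start": ex.start - 1,
                    "exon_end": ex.end,
                }
            )
    if not rows:
        raise ValueError(f"no gene features found in {path}")
    return pd.DataFrame(rows)


def genes_table(models: pd.DataFrame) -> pd.DataFrame:
    """Collapse an exon-level table to one row per gene."""
    return (
        models.groupby("gene_id", as_index=False)
        .agg(
            chrom=("chrom", "first"),
            strand=("strand", "first"),
            start=("gene_start", "first"),
            end=("gene_end", "first"),
        )
        .sort_values(["chrom", "start"], kind="stable")
        .reset_index(drop=True)
    )


def gene_regions(models: pd.DataFrame, flank: int = 2000) -> pd.DataFrame:
    """Derive strand-aware upstream / gene body / downstream regions per gene.

    Upstream is the ``flank`` bp 5' of the TSS (on the gene's strand);
    downstream the ``flank`` bp 3' of the TES. Intervals are 0-based
    half-open and clipped at zero.

    Returns columns ``gene_id, chrom, strand, region, start, end``.
    """
    genes = genes_table(models) if "exon_start" in models.columns else models
    rows = []
    for g in genes.itertuples(index=False):
        body = (g.start, g.end)
        if g.strand == "-":
            up = (g.end, g.end + flank)
            down = (max(0, g.start - flank), g.start)
        else:
            up = (max(0, g.start - flank), g.start)
            down = (g.end, g.end + flank)
        for region, (s, e) in zip(REGION_LABELS, (up, body, down)):
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "strand": g.strand,
                    "region": region,
                    "start": s,
                    "end": e,
                }
            )
    return pd.DataFrame(rows)
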