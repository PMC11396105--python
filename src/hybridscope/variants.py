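"""Parental VCF hard filtering and diagnostic-SNP selection.

A diagnostic SNP is a site where the two parents are homozygous for
different alleles, so every hybrid read covering it can be assigned a
parent of origin. Sites are first hard-filtered on the standard GATK
annotations (QD, FS, MQ, per-sample GQ); the inequalities are applied
exactly as printed — strict — so boundary values pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pandas as pd
from cyvcf2 import VCF
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

QD_MIN = 2.0
FS_MAX = 60.0
MQ_MIN = 40.0
GQ_MIN = 20


@dataclass
class VariantRecord:
    """One biallelic site with the annotations the hard filter consumes.

    ``genotypes`` maps sample name to an allele-index pair (``None`` for
    missing calls); ``gq`` maps sample name to genotype quality.
    """

    chrom: str
    pos: int  # 1-based, as in the VCF
    ref: str
    alt: str
    genotypes: dict
    qd: Optional[float] = None
    fs: Optional[float] = None
    mq: Optional[float] = None
    gq: dict = field(default_factory=dict)


@dataclass
class DiagnosticSnp:
    """A parent-diagnostic site: both parents homozygous, different alleles."""

    chrom: str
    pos: int
    paternal_allele: str
    maternal_allele: str
    reference_side: str = "paternal_genome"
    gene_id: Optional[str] = None
    ambiguous: bool = False


@dataclass
class FilterStats:
    """Tallies of records dropped by the reader/filter, for logging."""

    seen: int = 0
    passed: int = 0
    missing_annotation: int = 0
    multiallelic: int = 0
    malformed: int = 0


def read_vcf(path: str, stats: FilterStats | None = None) -> Iterator[VariantRecord]:
    """Stream biallelic SNP records from a VCF (plain or bgzipped).

    Multi-allelic sites are skipped with a logged tally: the 0/0 x 1/1
    diagnostic pattern presumes biallelic sites.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    for v in vcf:
        if stats is not None:
            stats.seen += 1
        if len(v.ALT) != 1:
            if stats is not None:
                stats.multiallelic += 1
            continue
        try:
            genotypes = {}
            gq = {}
            gq_vals = None
            try:
                gq_vals = v.format("GQ")
            except KeyError:
                gq_vals = None
            for i, s in enumerate(samples):
                a = v.genotypes[i]
                alleles = tuple(x if x >= 0 else None for x in a[:-1])
                genotypes[s] = alleles
                gq[s] = float(gq_vals[i][0]) if gq_vals is not None else None
        except Exception:
            if stats is not None:
                stats.malformed += 1
            logger.warning("malformed genotype at %s:%s, record dropped", v.CHROM, v.POS)
            continue
        yield VariantRecord(
            chrom=v.CHROM,
            pos=v.POS,
            ref=v.REF,
            alt=v.ALT[0],
            genotypes=genotypes,
            qd=_info_float(v, "QD"),
            fs=_info_float(v, "FS"),
            mq=_info_float(v, "MQ"),
            gq=gq,
        )


def _info_float(v, key: str) -> Optional[float]:
    val = v.INFO.get(key)
    return float(val) if val is not None else None


def passes_hard_filter(rec: VariantRecord) -> bool:
    """Site-level pass predicate: NOT (QD < 2.0 or FS > 60.0 or MQ < 40.0),
    and every sample's GQ >= 20. Missing annotations fail (conservative)."""
    if rec.qd is None or rec.fs is None or rec.mq is None:
        return False
    if rec.qd < QD_MIN or rec.fs > FS_MAX or rec.mq < MQ_MIN:
        return False
    for s in rec.genotypes:
        g = rec.gq.get(s)
        if g is None or g < GQ_MIN:
            return False
    return True


def hard_filter(
    records: Iterable[VariantRecord], stats: FilterStats | None = None
) -> list[VariantRecord]:
    """Apply the hard filter to a record stream; idempotent by construction."""
    out = []
    n_missing = 0
    for rec in records:
        if rec.qd is None or rec.fs is None or rec.mq is None or any(
            rec.gq.get(s) is None for s in rec.genotypes
        ):
            n_missing += 1
        if passes_hard_filter(rec):
            out.append(rec)
    if stats is not None:
        stats.passed += len(out)
        stats.missing_annotation += n_missing
    if n_missing:
        logger.info("%d records failed for missing QD/FS/MQ/GQ annotations", n_missing)
    return out


def select_diagnostic(
    records: Iterable[VariantRecord],
    father: str,
    mother: str,
    reference_side: str = "paternal_genome",
) -> list[DiagnosticSnp]:
    """Keep sites where both parents are homozygous for different alleles.

    Allele-of-origin labels come from the parent roles: the paternal allele
    is whichever base the father is homozygous for, regardless of which
    parental genome served as the alignment reference (``reference_side``
    is recorded for provenance).
    """
    out = []
    for rec in records:
        try:
            fgt = rec.genotypes[father]
            mgt = rec.genotypes[mother]
        except KeyError as e:
            raise ValueError(
                f"sample {e} not present in VCF; map parent roles explicitly"
            ) from None
        if None in fgt or None in mgt:
            continue
        if len(set(fgt)) != 1 or len(set(mgt)) != 1:
            continue  # heterozygous parent: non-diagnostic
        fa, ma = fgt[0], mgt[0]
        if fa == ma:
            continue  # no divergence
        alleles = (rec.ref, rec.alt)
        out.append(
            DiagnosticSnp(
                chrom=rec.chrom,
                pos=rec.pos,
                paternal_allele=alleles[fa],
                maternal_allele=alleles[ma],
                reference_side=reference_side,
            )
        )
    return out


def assign_to_genes(
    snps: list[DiagnosticSnp], gene_models: pd.DataFrame
) -> list[DiagnosticSnp]:
    """Attach gene ids to SNPs falling in exonic spans.

    RNA reads cover exons, so assignment is exonic-only. A SNP in the
    overlap of two genes yields one record per gene, flagged ambiguous;
    intergenic/intronic SNPs keep ``gene_id=None``.
    """
    trees: dict[str, IntervalTree] = {}
    for row in gene_models.itertuples(index=False):
        if row.exon_end > row.exon_start:
            trees.setdefault(row.chrom, IntervalTree()).addi(
                row.exon_start, row.exon_end, row.gene_id
            )
    out = []
    for snp in snps:
        tree = trees.get(snp.chrom)
        hits = sorted({iv.data for iv in tree[snp.pos - 1]}) if tree else []
        if not hits:
            out.append(snp)
            continue
        ambiguous = len(hits) > 1
        for gene_id in hits:
            out.append(
                DiagnosticSnp(
                    chrom=snp.chrom,
                    pos=snp.pos,
                    paternal_allele=snp.paternal_allele,
                    maternal_allele=snp.maternal_allele,
                    reference_side=snp.reference_side,
                    gene_id=gene_id,
                    ambiguous=ambiguous,
                )
            )
    return out


def diagnostics_to_frame(snps: list[DiagnosticSnp]) -> pd.DataFrame:
    """Tabular view (chrom, pos, pat_allele, mat_allele, gene_id, ambiguous)."""
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "pat_allele": s.paternal_allele,
                "mat_allele": s.maternal_allele,
                "gene_id": s.gene_id,
                "ambiguous": s.ambiguous,
            }
            for s in snps
        ],
        columns=["chrom", "pos", "pat_allele", "mat_allele", "gene_id", "ambiguous"],
    )
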