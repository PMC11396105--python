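"""Allele-specific expression: per-gene allele counting, bias testing and
subgenome-dominance summarisation.

Per gene and replicate, reads carrying the paternal vs maternal diagnostic
allele are summed over the gene's diagnostic SNPs. Bias is tested with a
two-sided exact binomial test of the paternal count against a 0.5 allelic
ratio, BH-adjusted across genes. A gene is called paternal-biased iff the
paternal:maternal ratio is >= 2 in every replicate and q <= 0.01
(maternal-biased: ratio <= 0.5 in every replicate). By default the q gate
is evaluated on replicate-pooled counts — one test per gene — which matches
designs where replicate libraries are pooled; a strict per-replicate q mode
(every replicate must individually reach q <= 0.01) is also provided.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

RATIO_HI = 2.0
RATIO_LO = 0.5
ALPHA_Q = 0.01
MIN_TOTAL = 10


class BiasResult(NamedTuple):
    """Per-replicate test table and per-gene classifications."""

    per_replicate: pd.DataFrame  # gene_id, replicate, pat, mat, ratio, p, q
    calls: pd.DataFrame  # gene_id, classification, low_coverage


def count_alleles(
    depths: pd.DataFrame, diagnostics: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Aggregate per-SNP allele depths to per-(gene, replicate) counts.

    ``depths`` needs columns ``replicate, pat_count, mat_count`` plus either
    ``gene_id`` or ``chrom, pos`` joinable to ``diagnostics`` (the
    diagnostic-SNP table with ``chrom, pos, gene_id``). Rows that match no
    diagnostic site, or whose site has no gene, are skipped with a logged
    tally. Genes with no diagnostic SNPs are absent from the output.
    """
    if depths.empty:
        return pd.DataFrame(columns=["gene_id", "replicate", "pat_count", "mat_count"])
    df = depths
    if "gene_id" not in df.columns or df["gene_id"].isna().any():
        if diagnostics is None:
            raise ValueError("depth rows lack gene_id and no diagnostics table given")
        key = diagnostics.dropna(subset=["gene_id"])[["chrom", "pos", "gene_id"]]
        df = df.drop(columns=["gene_id"], errors="ignore").merge(
            key, on=["chrom", "pos"], how="left"
        )
    n_unmatched = int(df["gene_id"].isna().sum())
    if n_unmatched:
        logger.info("%d depth rows matched no diagnostic site; skipped", n_unmatched)
        df = df.dropna(subset=["gene_id"])
    out = (
        df.groupby(["gene_id", "replicate"], as_index=False)[["pat_count", "mat_count"]]
        .sum()
        .sort_values(["gene_id", "replicate"], kind="stable")
        .reset_index(drop=True)
    )
    return out


def _binom_two_sided(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorised two-sided exact binomial p at p0 = 0.5.

    At p0 = 0.5 the distribution is symmetric, so the two-sided p equals
    min(1, 2 * min(cdf(k), sf(k-1)))."""
    k = np.asarray(k, dtype=int)
    n = np.asarray(n, dtype=int)
    lo = stats.binom.cdf(k, n, 0.5)
    hi = stats.binom.sf(k - 1, n, 0.5)
    return np.minimum(1.0, 2.0 * np.minimum(lo, hi))


def test_bias(
    counts: pd.DataFrame,
    min_total: int = MIN_TOTAL,
    alpha_q: float = ALPHA_Q,
    ratio_hi: float = RATIO_HI,
    ratio_lo: float = RATIO_LO,
    q_mode: str = "pooled",
) -> BiasResult:
    """Test per-gene allelic bias and classify subgenome dominance.

    The ratio gate is always applied per replicate: a paternal call needs
    ratio >= ratio_hi in every replicate (maternal: <= ratio_lo). The
    significance gate q <= alpha_q is evaluated on the replicate-pooled
    counts by default (``q_mode="pooled"``; one exact binomial test per
    gene, BH across genes — the natural reading when replicate libraries
    are pooled), or per replicate with every replicate required to pass
    (``q_mode="per_replicate"``, the strictest reading).

    Parameters
    ----------
    counts
        Output of :func:`count_alleles`.
    min_total
        A gene with any replicate total below this is flagged low-coverage
        and left unbiased: a handful of reads cannot support a dominance call.
    """
    if q_mode not in ("pooled", "per_replicate"):
        raise ValueError("q_mode must be 'pooled' or 'per_replicate'")
    if counts.empty:
        empty = pd.DataFrame(
            columns=["gene_id", "replicate", "pat_count", "mat_count", "ratio", "p", "q"]
        )
        return BiasResult(
            empty, pd.DataFrame(columns=["gene_id", "classification", "low_coverage", "q"])
        )

    def annotate(df):
        pat = df["pat_count"].to_numpy(float)
        mat = df["mat_count"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            df["ratio"] = np.where(mat > 0, pat / mat, np.where(pat > 0, np.inf, np.nan))
        df["p"] = _binom_two_sided(pat.astype(int), (pat + mat).astype(int))
        return df

    df = annotate(counts.copy())
    df["q"] = np.nan
    for rep, idx in df.groupby("replicate").groups.items():
        df.loc[idx, "q"] = multipletests(df.loc[idx, "p"], method="fdr_bh")[1]

    pooled = annotate(
        df.groupby("gene_id", as_index=False)[["pat_count", "mat_count"]].sum()
    )
    pooled["q"] = multipletests(pooled["p"], method="fdr_bh")[1]
    pooled = pooled.set_index("gene_id")

    total = df["pat_count"] + df["mat_count"]
    low = df.assign(total=total).groupby("gene_id")["total"].min().lt(min_total)
    ratio_pat = df.groupby("gene_id")["ratio"].agg(lambda r: bool((r >= ratio_hi).all()))
    ratio_mat = df.groupby("gene_id")["ratio"].agg(lambda r: bool((r <= ratio_lo).all()))
    if q_mode == "pooled":
        q_gene = pooled["q"].reindex(ratio_pat.index)
        q_ok = q_gene <= alpha_q
    else:
        q_ok = df.groupby("gene_id")["q"].agg(lambda q: bool((q <= alpha_q).all()))
        q_gene = df.groupby("gene_id")["q"].max()

    calls = pd.DataFrame({"gene_id": ratio_pat.index})
    calls["low_coverage"] = low.reindex(ratio_pat.index).to_numpy()
    pat_call = ratio_pat.to_numpy() & q_ok.to_numpy()
    mat_call = ratio_mat.to_numpy() & q_ok.to_numpy()
    calls["classification"] = np.where(
        calls["low_coverage"],
        "unbiased",
        np.where(pat_call, "paternal", np.where(mat_call, "maternal", "unbiased")),
    )
    calls["q"] = q_gene.to_numpy()
    calls = calls[["gene_id", "classification", "low_coverage", "q"]].reset_index(drop=True)
    return BiasResult(df.reset_index(drop=True), calls)


test_bias.__test__ = False  # keep pytest from collecting the API name


def dominance_summary(
    bias_paternal_ref: pd.DataFrame,
    bias_maternal_ref: pd.DataFrame,
    deg_tables: dict[str, pd.DataFrame],
    orthologs: pd.DataFrame | None = None,
    fpkm: pd.Series | None = None,
) -> dict:
    """Summarise subgenome dominance across the two reference alignments.

    Parameters
    ----------
    bias_paternal_ref, bias_maternal_ref
        ``calls`` tables from :func:`test_bias` for the paternal- and
        maternal-reference alignments (maternal-reference gene ids are
        translated through ``orthologs``).
    deg_tables
        tissue -> DEG table (``gene_id, status``) on paternal-reference ids.
    orthologs
        ``paternal_gene, maternal_gene`` pairs; maternal-reference genes
        without a mapping are counted as reference-unique.
    fpkm
        Optional per-gene expression used to compare the expression level of
        the paternal- vs maternal-bias sets (mean over each set).

    Returns a dict with per-tissue bias-DEG counts, the expression
    comparison, and the shared-set partition (up / down / mixed direction
    across tissues), which sums to the shared total.
    """
    biased_p = bias_paternal_ref[bias_paternal_ref["classification"] != "unbiased"]
    biased_m = bias_maternal_ref[bias_maternal_ref["classification"] != "unbiased"]

    # translate maternal-reference ids into paternal-reference id space
    unmapped_maternal_ref = 0
    if orthologs is not None and not biased_m.empty:
        m2p = orthologs.set_index("maternal_gene")["paternal_gene"]
        translated = biased_m["gene_id"].map(m2p)
        unmapped_maternal_ref = int(translated.isna().sum())
        biased_m = biased_m.assign(gene_id=translated).dropna(subset=["gene_id"])

    per_tissue = {}
    deg_any: dict[str, dict] = {}
    for tissue, deg in deg_tables.items():
        de = deg[deg["status"].isin(["up", "down"])].set_index("gene_id")["status"]
        for g, s in de.items():
            deg_any.setdefault(g, {})[tissue] = s
        per_tissue[tissue] = {
            "paternal_bias_degs": int(biased_p[biased_p["classification"] == "paternal"]["gene_id"].isin(de.index).sum()),
            "maternal_bias_degs": int(biased_p[biased_p["classification"] == "maternal"]["gene_id"].isin(de.index).sum()),
        }

    de_genes = set(deg_any)
    bias_deg_p = set(biased_p["gene_id"]) & de_genes
    bias_deg_m = set(biased_m["gene_id"]) & de_genes
    shared = sorted(bias_deg_p & bias_deg_m)

    up = down = mixed = 0
    for g in shared:
        directions = set(deg_any[g].values())
        if directions == {"up"}:
            up += 1
        elif directions == {"down"}:
            down += 1
        else:
            mixed += 1

    expression_comparison: dict = {"defined": False}
    if fpkm is not None:
        pat_set = biased_p.loc[biased_p["classification"] == "paternal", "gene_id"]
        mat_set = biased_p.loc[biased_p["classification"] == "maternal", "gene_id"]
        if len(pat_set) and len(mat_set):
            expression_comparison = {
                "defined": True,
                "paternal_bias_mean_fpkm": float(fpkm.reindex(pat_set).mean()),
                "maternal_bias_mean_fpkm": float(fpkm.reindex(mat_set).mean()),
            }

    return {
        "per_tissue": per_tissue,
        "bias_degs_paternal_ref": len(bias_deg_p),
        "bias_degs_maternal_ref": len(bias_deg_m),
        "shared_bias_degs": len(shared),
        "shared_partition": {"up": up, "down": down, "mixed": mixed},
        "unmapped_maternal_ref": unmapped_maternal_ref,
        "expression_comparison": expression_comparison,
    }
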