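"""Methylation-level computation and differential methylation calling.

Input is a CX-report-style table with one row per cytosine:
``chrom, pos (1-based), strand, context (CG/CHG/CHH), count_M, count_U``.

Methylated-cytosine calling tests each site's methylated count against the
bisulfite non-conversion error with a one-sided binomial test. Differential
calls compare two groups' pooled counts in fixed non-overlapping 200-bp
tiles (DMRs) or at single sites (DMCs) with Fisher's exact test, BH-adjusted
per context, under context-specific eligibility rules: CG/CHG windows need
>= 5 eligible cytosines and |difference| >= 0.25; CHH windows >= 15 sites
and >= 0.15; all-context windows >= 20 sites and >= 0.20; all at q <= 0.05.
Sites must have coverage >= 4 in both groups to be eligible.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from hybridscope.genemodels import gene_regions

WINDOW = 200
MIN_COV = 4
Q_MAX = 0.05
CONVERSION_ERROR = 0.01

# context -> (minimum eligible cytosines per window, minimum |delta|)
DMR_CRITERIA: dict[str, tuple[int, float]] = {
    "CG": (5, 0.25),
    "CHG": (5, 0.25),
    "CHH": (15, 0.15),
    "allC": (20, 0.20),
}

# DMC screening (single-site): coverage gate as above, delta/q as CG windows
DMC_MIN_DELTA = 0.25

CX_COLUMNS = ["chrom", "pos", "strand", "context", "count_M", "count_U"]


def read_cx_report(path: str) -> pd.DataFrame:
    """Read a CX-report-style TSV (header optional)."""
    first = pd.read_csv(path, sep="\t", nrows=1, header=None)
    header = 0 if str(first.iloc[0, 0]) == "chrom" else None
    df = pd.read_csv(path, sep="\t", header=header)
    df.columns = CX_COLUMNS[: df.shape[1]]
    return df


def call_methylcytosines(
    sites: pd.DataFrame, conversion_error: float = CONVERSION_ERROR
) -> pd.DataFrame:
    """Flag methylated cytosines against the non-conversion error rate.

    One-sided binomial test P(X >= count_M | n = coverage, p = error), BH
    across sites; a site is methylated iff q <= 0.05. Zero-coverage sites
    are flagged unevaluated and excluded from the BH family.
    """
    if not 0.0 < conversion_error < 1.0:
        raise ValueError("conversion_error must be in (0, 1)")
    out = sites.copy()
    cov = (out["count_M"] + out["count_U"]).to_numpy(int)
    m = out["count_M"].to_numpy(int)
    evaluable = cov > 0
    p = np.full(len(out), np.nan)
    p[evaluable] = stats.binom.sf(m[evaluable] - 1, cov[evaluable], conversion_error)
    q = np.full(len(out), np.nan)
    if evaluable.any():
        q[evaluable] = multipletests(p[evaluable], method="fdr_bh")[1]
    out["p"] = p
    out["q"] = q
    out["methylated"] = evaluable & (q <= Q_MAX)
    out["unevaluated"] = ~evaluable
    return out


def pooled_level(sites: pd.DataFrame) -> float | None:
    """Coverage-weighted methylation level sum(M)/sum(M+U); None if uncovered."""
    m = sites["count_M"].sum()
    n = m + sites["count_U"].sum()
    return float(m / n) if n > 0 else None


def methylation_levels(
    sites: pd.DataFrame, by: tuple[str, ...] = ("context",)
) -> pd.DataFrame:
    """Pooled methylation levels grouped by any site columns (context,
    chrom, ...). Groups with no coverage are absent, not zero."""
    g = sites.groupby(list(by), as_index=False)[["count_M", "count_U"]].sum()
    cov = g["count_M"] + g["count_U"]
    g = g[cov > 0].copy()
    g["level"] = g["count_M"] / (g["count_M"] + g["count_U"])
    return g.drop(columns=["count_M", "count_U"])


def region_levels(
    sites: pd.DataFrame, gene_models: pd.DataFrame, flank: int = 2000
) -> pd.DataFrame:
    """Per-gene methylation level in upstream/gene-body/downstream regions.

    Strand-aware regions from the gene models; levels are coverage-weighted
    pooled per (gene, region, context) plus an all-context row. Regions with
    no covered site are absent from the output.
    """
    regions = gene_regions(gene_models, flank=flank)
    covered = sites[(sites["count_M"] + sites["count_U"]) > 0]
    frames = []
    for chrom, reg in regions.groupby("chrom"):
        sub = covered[covered["chrom"] == chrom]
        if sub.empty:
            continue
        sub_pos = sub["pos"].to_numpy() - 1
        for r in reg.itertuples(index=False):
            in_reg = sub[(sub_pos >= r.start) & (sub_pos < r.end)]
            if in_reg.empty:
                continue
            g = in_reg.groupby("context")[["count_M", "count_U"]].sum()
            g.loc["allC"] = g.sum()
            lev = g["count_M"] / (g["count_M"] + g["count_U"])
            for ctx, v in lev.items():
                frames.append(
                    {
                        "gene_id": r.gene_id,
                        "region": r.region,
                        "context": ctx,
                        "level": float(v),
                    }
                )
    return pd.DataFrame(frames, columns=["gene_id", "region", "context", "level"])


@lru_cache(maxsize=200_000)
def _fisher_cached(ma: int, ua: int, mb: int, ub: int) -> float:
    return float(stats.fisher_exact([[ma, ua], [mb, ub]])[1])


def _fisher_pvalues(ma, ua, mb, ub) -> np.ndarray:
    return np.array(
        [_fisher_cached(int(a), int(b), int(c), int(d)) for a, b, c, d in zip(ma, ua, mb, ub)]
    )


def _merge_groups(
    sites_a: pd.DataFrame, sites_b: pd.DataFrame, min_cov: int, merge_cg_strands: bool
) -> pd.DataFrame:
    a = sites_a.copy()
    b = sites_b.copy()
    if merge_cg_strands:
        # symmetric CpG: collapse the - strand site onto the + strand position
        for df in (a, b):
            cg_minus = (df["context"] == "CG") & (df["strand"] == "-")
            df.loc[cg_minus, "pos"] = df.loc[cg_minus, "pos"] - 1
            df.loc[df["context"] == "CG", "strand"] = "+"
        a = a.groupby(["chrom", "pos", "strand", "context"], as_index=False)[["count_M", "count_U"]].sum()
        b = b.groupby(["chrom", "pos", "strand", "context"], as_index=False)[["count_M", "count_U"]].sum()
    merged = a.merge(
        b, on=["chrom", "pos", "strand", "context"], suffixes=("_a", "_b"), how="inner"
    )
    cov_a = merged["count_M_a"] + merged["count_U_a"]
    cov_b = merged["count_M_b"] + merged["count_U_b"]
    return merged[(cov_a >= min_cov) & (cov_b >= min_cov)].copy()


def call_dmrs(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    window: int = WINDOW,
    min_cov: int = MIN_COV,
    criteria: dict[str, tuple[int, float]] | None = None,
    q_max: float = Q_MAX,
    merge_cg_strands: bool = False,
) -> pd.DataFrame:
    """Call differentially methylated regions between two groups.

    The genome is tiled with fixed non-overlapping windows anchored at
    coordinate 0. Per window and context (plus an all-context 'allC' pass),
    both groups' counts over eligible sites are pooled and compared with a
    two-sided Fisher exact test; BH is applied per context across all tested
    windows. ``status`` is hyper/hypo (group A relative to B) only when the
    window passes its context's site-count and |delta| minima and q <= q_max.

    Returns columns ``chrom, start, end, context, n_sites, level_a, level_b,
    delta, p, q, status``.
    """
    criteria = DMR_CRITERIA if criteria is None else criteria
    merged = _merge_groups(sites_a, sites_b, min_cov, merge_cg_strands)
    cols = ["chrom", "start", "end", "context", "n_sites",
            "level_a", "level_b", "delta", "p", "q", "status"]
    if merged.empty:
        return pd.DataFrame(columns=cols)
    merged["start"] = ((merged["pos"] - 1) // window) * window

    frames = []
    for context in criteria:
        sub = merged if context == "allC" else merged[merged["context"] == context]
        if sub.empty:
            continue
        g = sub.groupby(["chrom", "start"], as_index=False).agg(
            n_sites=("pos", "size"),
            ma=("count_M_a", "sum"),
            ua=("count_U_a", "sum"),
            mb=("count_M_b", "sum"),
            ub=("count_U_b", "sum"),
        )
        g["context"] = context
        frames.append(g)
    if not frames:
        return pd.DataFrame(columns=cols)
    tab = pd.concat(frames, ignore_index=True)
    tab["end"] = tab["start"] + window
    tab["level_a"] = tab["ma"] / (tab["ma"] + tab["ua"])
    tab["level_b"] = tab["mb"] / (tab["mb"] + tab["ub"])
    tab["delta"] = tab["level_a"] - tab["level_b"]
    tab["p"] = _fisher_pvalues(tab["ma"], tab["ua"], tab["mb"], tab["ub"])
    tab["q"] = np.nan
    for context, idx in tab.groupby("context").groups.items():
        tab.loc[idx, "q"] = multipletests(tab.loc[idx, "p"], method="fdr_bh")[1]

    min_n = tab["context"].map(lambda c: criteria[c][0])
    min_d = tab["context"].map(lambda c: criteria[c][1])
    significant = (
        (tab["q"] <= q_max)
        & (tab["delta"].abs() >= min_d)
        & (tab["n_sites"] >= min_n)
    )
    tab["status"] = np.where(
        significant, np.where(tab["delta"] > 0, "hyper", "hypo"), "none"
    )
    return tab[cols].sort_values(["context", "chrom", "start"], kind="stable").reset_index(drop=True)


def call_dmcs(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    min_cov: int = MIN_COV,
    min_delta: float = DMC_MIN_DELTA,
    q_max: float = Q_MAX,
) -> pd.DataFrame:
    """Single-cytosine differential calls (per-site Fisher, BH per context).

    Screening thresholds: coverage >= min_cov in both groups, |delta| >=
    min_delta, q <= q_max — an explicit convention, exposed as parameters.
    """
    merged = _merge_groups(sites_a, sites_b, min_cov, merge_cg_strands=False)
    cols = ["chrom", "pos", "context", "level_a", "level_b", "delta", "p", "q", "status"]
    if merged.empty:
        return pd.DataFrame(columns=cols)
    merged["level_a"] = merged["count_M_a"] / (merged["count_M_a"] + merged["count_U_a"])
    merged["level_b"] = merged["count_M_b"] / (merged["count_M_b"] + merged["count_U_b"])
    merged["delta"] = merged["level_a"] - merged["level_b"]
    merged["p"] = _fisher_pvalues(
        merged["count_M_a"], merged["count_U_a"], merged["count_M_b"], merged["count_U_b"]
    )
    merged["q"] = np.nan
    for context, idx in merged.groupby("context").groups.items():
        merged.loc[idx, "q"] = multipletests(merged.loc[idx, "p"], method="fdr_bh")[1]
    significant = (merged["q"] <= q_max) & (merged["delta"].abs() >= min_delta)
    merged["status"] = np.where(
        significant, np.where(merged["delta"] > 0, "hyper", "hypo"), "none"
    )
    return merged[cols].reset_index(drop=True)


def annotate_dmr_genes(
    calls: pd.DataFrame, gene_models: pd.DataFrame, flank: int = 2000
) -> pd.DataFrame:
    """Associate differential calls with genes by region overlap.

    A gene is differentially methylated (a DMG) iff at least one DMR with
    ``status != none`` overlaps its gene body or +/- 2 kb flanks (half-open
    interval overlap, strand-aware region labels).

    Returns one row per (gene, region, DMR): ``gene_id, region, chrom,
    start, end, context, delta, q, status``.
    """
    regions = gene_regions(gene_models, flank=flank)
    hits = calls[calls["status"] != "none"]
    rows = []
    for chrom, reg in regions.groupby("chrom"):
        sub = hits[hits["chrom"] == chrom]
        if sub.empty:
            continue
        for r in reg.itertuples(index=False):
            ov = sub[(sub["start"] < r.end) & (sub["end"] > r.start)]
            for d in ov.itertuples(index=False):
                rows.append(
                    {
                        "gene_id": r.gene_id,
                        "region": r.region,
                        "chrom": d.chrom,
                        "start": d.start,
                        "end": d.end,
                        "context": d.context,
                        "delta": d.delta,
                        "q": d.q,
                        "status": d.status,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "region", "chrom", "start", "end", "context", "delta", "q", "status"],
    )
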