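"""FPKM computation, differential expression and DEG set accounting.

The differential test is a deliberately simple negative-binomial Wald test:
median-of-ratios library normalisation, tagwise method-of-moments dispersion
with a common-dispersion floor, and a normal approximation on the log fold
change. It is a documented stand-in — externally computed DEG tables with
``gene_id, log2fc, padj`` columns are accepted by every downstream step, so
the test is swappable. DEG status uses the conventional thresholds
adjusted p < 0.05 and |log2FC| >= 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PADJ_MAX = 0.05
LFC_MIN = 1.0


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``fpkm = count * 1e9 / (gene_length * library_size)`` per gene x sample.
    ``counts`` is genes x samples (gene ids as index); ``library_sizes``
    defaults to the column sums of ``counts``.
    """
    lengths = gene_lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for all genes in counts")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any() or library_sizes.isna().any():
        raise ValueError("library sizes must be positive for all samples")
    return counts * 1e9 / np.outer(lengths, library_sizes)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, falling back to total-count scaling
    when no gene is expressed in every sample (geometric means vanish)."""
    log_counts = np.log(counts.where(counts > 0))
    log_geomean = log_counts.mean(axis=1)
    usable = log_geomean.notna() & np.isfinite(log_geomean)
    if usable.sum() >= 1:
        ratios = log_counts.loc[usable].sub(log_geomean[usable], axis=0)
        sf = np.exp(ratios.median(axis=0))
        if sf.notna().all() and (sf > 0).all():
            return sf
    totals = counts.sum(axis=0)
    return totals / totals.mean()


def _nb_wald(
    counts: pd.DataFrame, group_a: list[str], group_b: list[str]
) -> pd.DataFrame:
    sf = size_factors(counts)
    norm = counts / sf
    a = norm[group_a]
    b = norm[group_b]
    mu_a = a.mean(axis=1)
    mu_b = b.mean(axis=1)

    # tagwise method-of-moments dispersion pooled over within-group variance
    def disp_part(x, mu):
        if x.shape[1] < 2:
            return pd.Series(0.0, index=x.index)
        v = x.var(axis=1, ddof=1)
        return (v - mu) / mu.clip(lower=1e-8) ** 2

    disp = pd.concat([disp_part(a, mu_a), disp_part(b, mu_b)], axis=1).mean(axis=1)
    floor = max(0.01, float(np.nanmedian(disp.clip(lower=0))))
    disp = disp.clip(lower=0.0) * 0.5 + floor * 0.5  # shrink toward the common value

    log2fc = np.log2((mu_a + 0.5) / (mu_b + 0.5))
    # delta-method variance of log(mean) for a NB mean of n replicates
    var_log_a = (1.0 / mu_a.clip(lower=0.5) + disp) / len(group_a)
    var_log_b = (1.0 / mu_b.clip(lower=0.5) + disp) / len(group_b)
    se_log2 = np.sqrt(var_log_a + var_log_b) / np.log(2)
    z = log2fc / se_log2
    p = 2 * stats.norm.sf(np.abs(z))

    out = pd.DataFrame(
        {"gene_id": counts.index, "base_mean": (mu_a + mu_b) / 2, "log2fc": log2fc, "pvalue": p}
    ).reset_index(drop=True)
    all_zero = (counts.sum(axis=1) == 0).to_numpy()
    out.loc[all_zero, "pvalue"] = 1.0
    out.loc[all_zero, "log2fc"] = 0.0
    out["zero_expression"] = all_zero
    return out


def call_degs(
    counts: pd.DataFrame,
    groups: pd.Series | dict,
    padj_max: float = PADJ_MAX,
    lfc_min: float = LFC_MIN,
) -> pd.DataFrame:
    """Call differentially expressed genes, hybrid relative to maternal.

    Parameters
    ----------
    counts
        Raw counts, genes x samples.
    groups
        sample -> {"hybrid", "maternal"}. log2FC is hybrid over maternal.

    Returns ``gene_id, base_mean, log2fc, pvalue, padj, status`` with status
    in {up, down, ns}; ``status != ns`` iff padj < padj_max and
    |log2fc| >= lfc_min. All-zero genes are ns with a zero-expression flag.
    """
    groups = pd.Series(groups)
    hybrid = [s for s in counts.columns if groups.get(s) == "hybrid"]
    maternal = [s for s in counts.columns if groups.get(s) == "maternal"]
    if not hybrid or not maternal:
        raise ValueError("both a hybrid and a maternal group are required")
    res = _nb_wald(counts, hybrid, maternal)
    res["padj"] = multipletests(res["pvalue"], method="fdr_bh")[1]
    significant = (res["padj"] < padj_max) & (res["log2fc"].abs() >= lfc_min)
    res["status"] = np.where(
        significant, np.where(res["log2fc"] > 0, "up", "down"), "ns"
    )
    return res


def shared_gene_partition(deg_tables: dict[str, pd.DataFrame]) -> dict:
    """Partition the genes differentially expressed in every tissue by
    direction consistency: all up, all down, or inconsistent.

    The three categories are disjoint and their sizes sum to the shared
    total. Also reports pairwise intersection sizes between tissues.
    """
    status = {
        tissue: deg[deg["status"].isin(["up", "down"])].set_index("gene_id")["status"]
        for tissue, deg in deg_tables.items()
    }
    tissues = list(status)
    shared = set.intersection(*(set(s.index) for s in status.values())) if tissues else set()
    all_up = {g for g in shared if all(status[t][g] == "up" for t in tissues)}
    all_down = {g for g in shared if all(status[t][g] == "down" for t in tissues)}
    inconsistent = shared - all_up - all_down
    pairwise = {
        f"{t1}&{t2}": len(set(status[t1].index) & set(status[t2].index))
        for i, t1 in enumerate(tissues)
        for t2 in tissues[i + 1:]
    }
    return {
        "shared": shared,
        "all_up": all_up,
        "all_down": all_down,
        "inconsistent": inconsistent,
        "pairwise_counts": pairwise,
        "per_tissue_counts": {t: len(s) for t, s in status.items()},
    }


def reference_venn(
    deg_paternal: set, deg_maternal: set, orthologs: pd.DataFrame
) -> dict:
    """Overlap of DEG sets called against the two reference alignments.

    Maternal-reference gene ids are translated into paternal-reference id
    space through the ortholog map; maternal DEGs without an ortholog count
    as maternal-unique. Returns disjoint sets whose sizes satisfy
    |overlap| + |unique_paternal| = |paternal set|.
    """
    m2p = orthologs.set_index("maternal_gene")["paternal_gene"]
    mapped = {m2p[g] for g in deg_maternal if g in m2p.index}
    unmapped = {g for g in deg_maternal if g not in m2p.index}
    overlap = set(deg_paternal) & mapped
    return {
        "overlap": overlap,
        "unique_paternal": set(deg_paternal) - mapped,
        "unique_maternal": (mapped - set(deg_paternal)) | unmapped,
    }
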