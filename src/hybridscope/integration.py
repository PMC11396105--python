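"""Methylation-expression integration.

Genes are binned by expression level (non / low / middle / high on the RPKM
scale), region methylation is profiled per bin and correlated gene-wise with
expression by Spearman's rank correlation, and the DEG/DMG intersection is
classified into E+/- x M+/- quadrants (E = expression direction,
M = methylation direction of the overlapping differential region).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

# half-open on the left as printed: non (-inf,1], low (1,10], middle (10,100], high (100,inf)
BIN_EDGES = [-np.inf, 1.0, 10.0, 100.0, np.inf]
BIN_LABELS = ["non", "low", "middle", "high"]

QUADRANTS = {
    ("up", "hyper"): "E+M+",
    ("up", "hypo"): "E+M-",
    ("down", "hyper"): "E-M+",
    ("down", "hypo"): "E-M-",
}


def bin_expression(fpkm: pd.Series) -> pd.Series:
    """Assign each gene to an expression class.

    non: RPKM <= 1; low: 1 < RPKM <= 10; middle: 10 < RPKM <= 100;
    high: RPKM > 100. The bins partition every nonnegative input.
    """
    return pd.cut(fpkm, bins=BIN_EDGES, labels=BIN_LABELS, right=True)


def methylation_by_bin(
    expression: pd.Series, region_levels: pd.DataFrame, context: str = "allC"
) -> pd.DataFrame:
    """Per-region methylation-expression relationship.

    For each region (upstream2kb / gene_body / downstream2kb): Spearman rho
    and p between per-gene expression and region methylation level
    (gene-wise pairing), plus the mean level per expression bin. A constant
    methylation vector leaves rho/p absent (NaN).

    Returns columns ``region, rho, p, n, mean_non, mean_low, mean_middle,
    mean_high`` (bin means NaN where a bin is empty).
    """
    lv = region_levels[region_levels["context"] == context]
    bins = bin_expression(expression)
    rows = []
    for region, sub in lv.groupby("region"):
        joined = sub.set_index("gene_id")["level"].to_frame().join(
            expression.rename("expr"), how="inner"
        )
        if len(joined) < 2 or joined["level"].nunique() < 2:
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(joined["expr"], joined["level"])
        row = {"region": region, "rho": rho, "p": p, "n": len(joined)}
        joined["bin"] = bins.reindex(joined.index)
        means = joined.groupby("bin", observed=False)["level"].mean()
        for label in BIN_LABELS:
            row[f"mean_{label}"] = float(means.get(label, np.nan))
        rows.append(row)
    return pd.DataFrame(rows)


def common_genes(deg_table: pd.DataFrame, dmg_table: pd.DataFrame) -> pd.DataFrame:
    """Intersect DEGs with DMGs and label E/M quadrants.

    One record per (gene, region, differential region); a gene whose region
    carries DMRs in both directions yields one record per DMR, flagged
    ``multi_hit``. The record also carries the region's coverage-weighted
    consensus direction (sign of the mean delta over its DMRs). Genes that
    are DE-only or DM-only are excluded.
    """
    de = deg_table[deg_table["status"].isin(["up", "down"])][["gene_id", "status"]]
    dm = dmg_table[dmg_table["status"].isin(["hyper", "hypo"])]
    merged = dm.merge(de, on="gene_id", how="inner", suffixes=("", "_deg"))
    if merged.empty:
        return pd.DataFrame(
            columns=["gene_id", "region", "context", "deg_status", "dmg_direction",
                     "region_direction", "quadrant", "multi_hit", "delta", "q"]
        )
    grp = merged.groupby(["gene_id", "region"])
    consensus = grp["delta"].mean().apply(lambda d: "hyper" if d > 0 else "hypo")
    n_dirs = grp["status"].nunique()
    out = merged.rename(columns={"status": "dmg_direction", "status_deg": "deg_status"})
    key = list(zip(out["gene_id"], out["region"]))
    out["region_direction"] = [consensus[k] for k in key]
    out["multi_hit"] = [n_dirs[k] > 1 for k in key]
    out["quadrant"] = [
        QUADRANTS[(d, m)] for d, m in zip(out["deg_status"], out["dmg_direction"])
    ]
    return out[
        ["gene_id", "region", "context", "deg_status", "dmg_direction",
         "region_direction", "quadrant", "multi_hit", "delta", "q"]
    ].reset_index(drop=True)


def build_report(config: dict | None = None, **stages) -> dict:
    """Assemble a machine-readable run summary.

    ``stages`` maps a stage name to its summary payload (any JSON-friendly
    structure); stages not run are simply absent. The config echo always
    appears, so threshold overrides are visible in every report.
    """
    report = {"config": config or {}, "stages": {}}
    for name, payload in stages.items():
        if payload is not None:
            report["stages"][name] = payload
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
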