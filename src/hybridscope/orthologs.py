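"""Reciprocal best-hit (RBH) orthology from all-vs-all similarity tables.

Two genes are paired iff each is the other's top-scoring cross-set hit
after discarding hits above the e-value cutoff (default 1e-5). "Best" means
highest bitscore, ties broken by smallest e-value, then lexicographic
subject id, so the output is deterministic.
"""

from __future__ import annotations

import pandas as pd

EVALUE_CUTOFF = 1e-5

# 12-column tabular hit format (BLAST outfmt 6)
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits(path: str) -> pd.DataFrame:
    """Read a tab-separated similarity table.

    Accepts the full 12-column tabular format or a reduced
    ``qseqid sseqid bitscore evalue`` table (no header in either case).
    """
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] >= 12:
        df.columns = OUTFMT6_COLUMNS + [f"extra{i}" for i in range(df.shape[1] - 12)]
    elif df.shape[1] == 4:
        df.columns = ["qseqid", "sseqid", "bitscore", "evalue"]
    else:
        raise ValueError(
            f"{path}: expected 4 or >=12 tab-separated columns, got {df.shape[1]}"
        )
    return df[["qseqid", "sseqid", "bitscore", "evalue"]].astype(
        {"bitscore": float, "evalue": float}
    )


def _best_hits(hits: pd.DataFrame, cutoff: float) -> pd.Series:
    """Best surviving subject per query (bitscore desc, evalue asc, sseqid asc)."""
    surviving = hits[hits["evalue"] <= cutoff]
    if surviving.empty:
        return pd.Series(dtype=object)
    ranked = surviving.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="stable",
    )
    best = ranked.drop_duplicates("qseqid", keep="first")
    return best.set_index("qseqid")["sseqid"]


def reciprocal_best_hits(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    evalue_cutoff: float = EVALUE_CUTOFF,
) -> pd.DataFrame:
    """Compute RBH ortholog pairs.

    Parameters
    ----------
    hits_ab, hits_ba
        Similarity tables for the two search directions (columns
        ``qseqid, sseqid, bitscore, evalue``; extra columns ignored).
    evalue_cutoff
        Hits with ``evalue > cutoff`` are removed before ranking.

    Returns
    -------
    DataFrame with columns ``paternal_gene, maternal_gene`` (query side of
    ``hits_ab`` is taken as paternal). The result is a partial matching:
    every gene appears in at most one pair.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be positive")
    best_ab = _best_hits(hits_ab, evalue_cutoff)
    best_ba = _best_hits(hits_ba, evalue_cutoff)
    pairs = [
        (a, b)
        for a, b in best_ab.items()
        if best_ba.get(b) == a
    ]
    return pd.DataFrame(pairs, columns=["paternal_gene", "maternal_gene"])
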