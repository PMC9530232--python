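"""Cross-species fold-change concordance through an ortholog map.

Fold-change tables from two species are joined through a one-to-one ortholog
pairing (many-to-many rows dropped by default, so no gene is double
counted), and concordance is summarized by Spearman correlation with a
Fisher-z confidence interval — at transcript level directly on the paired
fold changes, or at gene-set level on per-species preranked GSEA normalized
enrichment scores.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .scoring import GeneSet, GeneSetCollection, preranked_gsea
from .stratify import spearman_ci

__all__ = ["map_orthologs", "concordance"]


def _as_fc_series(fc: pd.DataFrame | pd.Series) -> pd.Series:
    if isinstance(fc, pd.DataFrame):
        if "logFC_e" not in fc.columns:
            raise ValueError("fold-change table must have a 'logFC_e' column")
        fc = fc["logFC_e"]
    if fc.index.has_duplicates:
        raise ValueError("duplicate gene ids in fold-change table")
    if not np.isfinite(fc.to_numpy(dtype=float)).all():
        raise ValueError("fold changes must be finite")
    return fc.astype(float)


def map_orthologs(
    fc_a: pd.DataFrame | pd.Series,
    fc_b: pd.DataFrame | pd.Series,
    orthologs: pd.DataFrame,
    policy: str = "drop_ambiguous",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Pair two species' fold changes through an ortholog map.

    ``orthologs`` needs columns ``gene_a`` and ``gene_b``.  Under
    ``drop_ambiguous`` (the only policy), every mapping row whose gene id
    appears more than once on either side is removed before the inner join.
    Returns the paired table (gene_a, gene_b, fc_a, fc_b) and a report of
    dropped/unmatched counts.
    """
    if policy != "drop_ambiguous":
        raise ValueError(f"unknown policy {policy!r}")
    for col in ("gene_a", "gene_b"):
        if col not in orthologs.columns:
            raise ValueError(f"ortholog map missing column {col!r}")
    sa = _as_fc_series(fc_a)
    sb = _as_fc_series(fc_b)
    m = orthologs[["gene_a", "gene_b"]].copy()
    dup = m["gene_a"].duplicated(keep=False) | m["gene_b"].duplicated(keep=False)
    n_ambiguous = int(dup.sum())
    m = m[~dup]
    paired = (
        m.merge(sa.rename("fc_a"), left_on="gene_a", right_index=True)
        .merge(sb.rename("fc_b"), left_on="gene_b", right_index=True)
        .reset_index(drop=True)
    )
    if paired.empty:
        raise ValueError("ortholog join produced no pairs")
    report = {
        "n_pairs": len(paired),
        "n_map_rows": len(orthologs),
        "n_dropped_ambiguous": n_ambiguous,
        "n_unmatched_a": int(len(sa) - paired["gene_a"].nunique()),
        "n_unmatched_b": int(len(sb) - paired["gene_b"].nunique()),
    }
    return paired, report


def concordance(
    paired: pd.DataFrame,
    level: str = "transcript",
    sets: GeneSetCollection | Iterable[GeneSet] | None = None,
    set_gene_column: str = "gene_a",
    n_perm: int = 1000,
    seed: int = 0,
    conf: float = 0.95,
) -> dict:
    """Spearman concordance of paired fold changes.

    ``transcript`` level correlates the fold changes directly.  ``set`` level
    runs preranked GSEA per species against ``sets`` (defined over
    ``set_gene_column`` ids) and correlates the normalized enrichment scores
    across sets — a permutation-GSEA substitute for proprietary pathway
    activation z-scores, recorded in the output metadata.
    """
    if len(paired) < 4:
        raise ValueError("need at least 4 ortholog pairs")
    if level == "transcript":
        out = spearman_ci(paired["fc_a"], paired["fc_b"], conf=conf)
        out["level"] = "transcript"
        return out
    if level != "set":
        raise ValueError("level must be 'transcript' or 'set'")
    if sets is None:
        raise ValueError("set-level concordance requires a gene-set collection")
    ranked_a = pd.Series(paired["fc_a"].to_numpy(), index=paired[set_gene_column])
    ranked_b = pd.Series(paired["fc_b"].to_numpy(), index=paired[set_gene_column])
    res_a = preranked_gsea(ranked_a, sets, n_perm=n_perm, seed=seed)
    res_b = preranked_gsea(ranked_b, sets, n_perm=n_perm, seed=seed + 1)
    joined = res_a[["NES"]].join(res_b[["NES"]], lsuffix="_a", rsuffix="_b").dropna()
    if len(joined) < 4:
        raise ValueError("need at least 4 sets with defined NES in both species")
    out = spearman_ci(joined["NES_a"], joined["NES_b"], conf=conf)
    out["level"] = "set"
    out["score"] = "preranked-GSEA NES (permutation null)"
    return out
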