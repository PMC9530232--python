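"""Signature derivation and gene-set enrichment engines.

Three single-sample / preranked enrichment statistics are implemented from
their published definitions:

* GSVA: per-gene Gaussian-kernel CDF statistic across samples, symmetric
  rank weighting, and a Kolmogorov-Smirnov-like random walk per set.  The
  reported ES is (maximum positive deviation) + (minimum negative
  deviation), bounded in [-1, 1].
* ssGSEA: per-sample difference between the weighted in-set ECDF and the
  unweighted out-of-set ECDF, summed over the ranking; weights are
  (rank from bottom)^alpha with alpha = 0.25 by default, and scores are
  normalized by the global score range.
* preranked GSEA: weighted running sum over a score-ranked gene list with a
  gene-label permutation null, normalized enrichment scores and empirical
  p-values.

Plus the top-n signature constructor and hypergeometric overlap statistics.
Gene ids are matched by exact, case-sensitive string equality throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import hypergeom

from ._rng import substream
from .de import bh_adjust

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "top_n_signature",
    "gsva_scores",
    "ssgsea_scores",
    "preranked_gsea",
    "overlap_stats",
]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (GMT semantics: name, description, members)."""

    name: str
    description: str = ""
    genes: tuple[str, ...] = ()
    short_set: bool = False  # fewer members than requested at construction

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} has no members")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection:
    """Ordered collection of gene sets with unique names."""

    def __init__(self, sets: Iterable[GeneSet]):
        self.sets = list(sets)
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names: {dupes}")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def _as_collection(sets: GeneSetCollection | GeneSet | Iterable[GeneSet]) -> GeneSetCollection:
    if isinstance(sets, GeneSetCollection):
        return sets
    if isinstance(sets, GeneSet):
        return GeneSetCollection([sets])
    return GeneSetCollection(list(sets))


# --------------------------------------------------------------------------
# signature derivation
# --------------------------------------------------------------------------

def top_n_signature(
    de: pd.DataFrame,
    n: int = 50,
    direction: str = "up",
    fdr: float = 0.01,
    name: str | None = None,
) -> GeneSet:
    """Top-n signature from a DE table (columns ``logFC_e``, ``p``, ``q``).

    Among genes significant at BH q < ``fdr`` with fold change in the stated
    direction, the ``n`` genes of largest |logFC_e| are returned; ties are
    broken by smaller p, then lexicographic gene id.  If fewer than ``n``
    genes qualify, all of them are returned with ``short_set`` flagged.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if de.empty:
        raise ValueError("empty DE table")
    tab = de.copy()
    if "filtered" in tab.columns:
        tab = tab[~tab["filtered"].astype(bool)]
    sig = tab[(tab["q"] < fdr)
              & ((tab["logFC_e"] > 0) if direction == "up" else (tab["logFC_e"] < 0))]
    if sig.empty:
        raise ValueError(f"no genes with q < {fdr} and {direction}-regulated fold change")
    ranked = sig.assign(_absfc=sig["logFC_e"].abs(), _gene=sig.index).sort_values(
        by=["_absfc", "p", "_gene"], ascending=[False, True, True], kind="stable"
    )
    chosen = list(ranked.index[:n])
    short = len(chosen) < n
    if short:
        warnings.warn(
            f"only {len(chosen)} genes qualify for a top-{n} {direction} signature"
        )
    return GeneSet(
        name=name or f"top{n}_{direction}",
        description=f"top {n} {direction}-regulated genes at q<{fdr}",
        genes=tuple(chosen),
        short_set=short,
    )


# --------------------------------------------------------------------------
# GSVA
# --------------------------------------------------------------------------

def _gsva_kcdf(x: np.ndarray, bandwidth_factor: float) -> np.ndarray:
    """Gaussian-kernel CDF statistic per gene across samples. x: (G, n)."""
    sd = x.std(axis=1, ddof=1)
    h = sd / bandwidth_factor
    G, n = x.shape
    out = np.empty_like(x)
    # chunk genes so the (chunk, n, n) difference tensor stays modest
    chunk = max(1, int(2e7) // max(n * n, 1))
    for lo in range(0, G, chunk):
        hi = min(lo + chunk, G)
        diff = (x[lo:hi, :, None] - x[lo:hi, None, :]) / h[lo:hi, None, None]
        out[lo:hi] = ndtr(diff).mean(axis=2)
    return out


def gsva_scores(
    expr: pd.DataFrame,
    sets: GeneSetCollection | GeneSet | Iterable[GeneSet],
    min_size: int = 2,
    tau: float = 1.0,
    max_diff: bool = True,
    bandwidth_factor: float = 4.0,
) -> pd.DataFrame:
    """Gene set variation analysis scores (sets x samples), in [-1, 1].

    Expression is first transformed gene-wise to a Gaussian-kernel CDF
    statistic across samples (bandwidth sd/``bandwidth_factor``); per sample,
    genes are ranked by that statistic and weighted symmetrically
    (|G/2 - rank|^tau); the set's random walk yields the enrichment score.
    With ``max_diff`` (default) the ES is the sum of the maximum positive and
    minimum negative deviation, otherwise the single maximum-magnitude
    deviation.  Zero-variance genes are dropped with a warning; sets with
    fewer than ``min_size`` matching genes get a row of NaN.
    """
    collection = _as_collection(sets)
    if expr.shape[1] < 3:
        raise ValueError("GSVA requires at least 3 samples")
    x = expr.to_numpy(dtype=float)
    keep = x.std(axis=1, ddof=1) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance genes for GSVA")
    x = x[keep]
    genes = list(expr.index[keep])
    if len(genes) < 2:
        raise ValueError("fewer than 2 genes with non-zero variance")
    G, n = x.shape
    z = _gsva_kcdf(x, bandwidth_factor)
    # rank 1 = highest statistic, per sample; ties broken by input gene order
    order = np.argsort(-z, axis=0, kind="stable")  # (G, n): gene index at each rank pos
    ranks = np.empty_like(order)
    pos = np.arange(1, G + 1)[:, None] * np.ones((1, n), dtype=int)
    np.put_along_axis(ranks, order, pos, axis=0)
    weight = np.abs(G / 2.0 - ranks) ** tau  # (G, n), symmetric rank statistic
    gene_pos = {g: i for i, g in enumerate(genes)}

    out = np.full((len(collection), n), np.nan)
    for si, gs in enumerate(collection):
        members = [gene_pos[g] for g in gs.genes if g in gene_pos]
        if len(members) < min_size:
            warnings.warn(
                f"set {gs.name!r} has {len(members)} matching genes "
                f"(min_size={min_size}); scores set to NaN"
            )
            continue
        in_set = np.zeros(G, dtype=bool)
        in_set[members] = True
        m_ord = in_set[order]  # (G, n) membership in rank order
        w_ord = np.take_along_axis(weight, order, axis=0)
        inc = np.where(m_ord, w_ord, 0.0)
        denom_in = inc.sum(axis=0)
        dec = np.where(m_ord, 0.0, 1.0) / (G - len(members))
        walk = np.cumsum(inc / denom_in[None, :] - dec, axis=0)
        if max_diff:
            es = np.maximum(walk, 0.0).max(axis=0) + np.minimum(walk, 0.0).min(axis=0)
        else:
            idx = np.argmax(np.abs(walk), axis=0)
            es = walk[idx, np.arange(n)]
        out[si] = es
    res = pd.DataFrame(out, index=collection.names, columns=expr.columns)
    res.attrs["method"] = "gsva"
    return res


# --------------------------------------------------------------------------
# ssGSEA
# --------------------------------------------------------------------------

def ssgsea_scores(
    expr: pd.DataFrame,
    sets: GeneSetCollection | GeneSet | Iterable[GeneSet],
    alpha: float = 0.25,
    normalize: bool = True,
    min_size: int = 1,
) -> pd.DataFrame:
    """Single-sample GSEA scores (sets x samples).

    Per sample, genes are ranked by decreasing expression (ties by input
    order); the ES is the sum over rank positions of the difference between
    the weighted in-set ECDF (weight = rank-from-bottom ^ alpha) and the
    unweighted out-of-set ECDF.  With ``normalize`` the whole matrix is
    divided by its global score range.
    """
    collection = _as_collection(sets)
    x = expr.to_numpy(dtype=float)
    G, n = x.shape
    if G < 2:
        raise ValueError("need at least 2 genes")
    genes = list(expr.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    order = np.argsort(-x, axis=0, kind="stable")
    rank_from_bottom = (G - np.arange(G))[:, None].astype(float)  # position i -> G-i
    w = rank_from_bottom**alpha

    out = np.full((len(collection), n), np.nan)
    for si, gs in enumerate(collection):
        members = [gene_pos[g] for g in gs.genes if g in gene_pos]
        if len(members) == G:
            raise ValueError(f"set {gs.name!r} covers all genes: empty complement")
        if len(members) < min_size:
            warnings.warn(f"set {gs.name!r} has {len(members)} matching genes; NaN")
            continue
        in_set = np.zeros(G, dtype=bool)
        in_set[members] = True
        m_ord = in_set[order]  # (G, n)
        inc = np.where(m_ord, w, 0.0)
        p_in = np.cumsum(inc, axis=0) / inc.sum(axis=0, keepdims=True)
        p_out = np.cumsum(~m_ord, axis=0) / float(G - len(members))
        out[si] = (p_in - p_out).sum(axis=0)
    if normalize:
        rng_ = np.nanmax(out) - np.nanmin(out)
        if rng_ > 0:
            out = out / rng_
    res = pd.DataFrame(out, index=collection.names, columns=expr.columns)
    res.attrs["method"] = "ssgsea"
    return res


# --------------------------------------------------------------------------
# preranked GSEA
# --------------------------------------------------------------------------

def _walk_es(
    m_ord: np.ndarray, scores_ord: np.ndarray, weight: float
) -> tuple[np.ndarray, np.ndarray]:
    """Running sum and signed max-deviation ES. m_ord: (..., G) bool."""
    w = np.abs(scores_ord) ** weight
    inc = np.where(m_ord, w, 0.0)
    denom = inc.sum(axis=-1, keepdims=True)
    denom = np.where(denom > 0, denom, 1.0)
    n_out = m_ord.shape[-1] - m_ord.sum(axis=-1, keepdims=True)
    dec = np.where(m_ord, 0.0, 1.0) / n_out
    walk = np.cumsum(inc / denom - dec, axis=-1)
    idx = np.argmax(np.abs(walk), axis=-1)
    es = np.take_along_axis(walk, idx[..., None], axis=-1)[..., 0]
    return walk, es


def preranked_gsea(
    ranked: pd.Series,
    sets: GeneSetCollection | GeneSet | Iterable[GeneSet],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    min_size: int = 2,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-label permutation null.

    ``ranked`` maps gene id to a real score (e.g. log fold change); genes are
    ordered by decreasing score.  Per set: ES is the maximum-magnitude
    deviation of the weighted running sum; the null redistributes the set
    over gene labels ``n_perm`` times; NES divides ES by the mean |null ES|
    of matching sign; empirical p is floored at 1/(n_perm+1); q is BH across
    sets.  Degenerate sets get an error record instead of a score row.
    """
    collection = _as_collection(sets)
    if ranked.index.has_duplicates:
        raise ValueError("duplicate gene ids in ranked list")
    s = ranked.to_numpy(dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("ranked scores must be finite")
    if len(s) < 2:
        raise ValueError("ranked list needs at least 2 genes")
    order = np.argsort(-s, kind="stable")
    s_ord = s[order]
    genes_ord = np.asarray(ranked.index)[order]
    gene_set = set(ranked.index)
    G = len(s)
    rng = substream(seed, "gsea_perm")

    rows = []
    for gs in collection:
        members = [g for g in gs.genes if g in gene_set]
        if len(members) < min_size or len(members) == G:
            rows.append(
                {
                    "set": gs.name, "size": len(members), "ES": np.nan,
                    "NES": np.nan, "p": np.nan, "leading_edge": "",
                    "error": "degenerate set (too few matching genes or full universe)",
                }
            )
            continue
        m_ord = np.isin(genes_ord, list(members))
        walk, es = _walk_es(m_ord, s_ord, weight)
        es = float(es)
        peak = int(np.argmax(np.abs(walk)))
        if es >= 0:
            leading = [g for g, m in zip(genes_ord[: peak + 1], m_ord[: peak + 1]) if m]
        else:
            leading = [g for g, m in zip(genes_ord[peak:], m_ord[peak:]) if m]
        # permutation null: redistribute |members| labels uniformly
        k = len(members)
        u = rng.random((n_perm, G))
        sel = np.argpartition(u, k - 1, axis=1)[:, :k]
        m_null = np.zeros((n_perm, G), dtype=bool)
        np.put_along_axis(m_null, sel, True, axis=1)
        _, es_null = _walk_es(m_null, s_ord[None, :], weight)
        same = es_null >= 0 if es >= 0 else es_null < 0
        n_same = int(same.sum())
        mean_mag = float(np.abs(es_null[same]).mean()) if n_same else np.nan
        nes = es / mean_mag if mean_mag and np.isfinite(mean_mag) else np.nan
        if n_same:
            p = float(np.mean(np.abs(es_null[same]) >= abs(es)))
        else:
            p = 0.0
        p = min(max(p, 1.0 / (n_perm + 1)), 1.0)
        rows.append(
            {
                "set": gs.name, "size": k, "ES": es, "NES": nes, "p": p,
                "leading_edge": ",".join(leading), "error": "",
            }
        )
    res = pd.DataFrame(rows).set_index("set")
    ok = res["p"].notna()
    res["q"] = np.nan
    if ok.any():
        res.loc[ok, "q"] = bh_adjust(res.loc[ok, "p"].to_numpy())
    return res


# --------------------------------------------------------------------------
# overlap statistics
# --------------------------------------------------------------------------

def overlap_stats(
    query: GeneSet | Sequence[str],
    reference: GeneSet | Sequence[str],
    universe: Sequence[str],
) -> dict[str, float]:
    """Hypergeometric overlap of two gene sets within a universe.

    Returns k (observed overlap), expected overlap under independence, fold
    enrichment (k / expected) and the upper-tail hypergeometric p-value
    Pr(X >= k).
    """
    q = list(query.genes) if isinstance(query, GeneSet) else list(query)
    r = list(reference.genes) if isinstance(reference, GeneSet) else list(reference)
    uni = set(universe)
    if len(uni) != len(list(universe)):
        raise ValueError("universe contains duplicate ids")
    bad_q = sorted(set(q) - uni)
    bad_r = sorted(set(r) - uni)
    if bad_q or bad_r:
        raise ValueError(
            f"sets must be subsets of the universe; offending ids: "
            f"query={bad_q[:10]}, reference={bad_r[:10]}"
        )
    N = len(uni)
    k = len(set(q) & set(r))
    expected = len(q) * len(r) / N
    fold = k / expected if expected > 0 else np.nan
    p = float(hypergeom.sf(k - 1, N, len(r), len(q)))
    return {
        "k": k,
        "n_query": len(q),
        "n_reference": len(r),
        "universe": N,
        "expected": expected,
        "fold_enrichment": fold,
        "p_hyper": p,
        "percent_of_reference": 100.0 * k / len(r) if r else np.nan,
    }
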