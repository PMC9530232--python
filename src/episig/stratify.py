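"""Enrichment-score stratification of a cohort against outcomes.

Patients are binned by their signature enrichment score (default cutpoints 0
and 0.25, honouring both the "ES < 0" low stratum and the "ES >= 0.25" high
stratum conventions simultaneously), outcome rates are tabulated per stratum
and treatment arm with exact pairwise tests, and continuous / ordinal
covariates are compared by Spearman correlation with Fisher-z confidence
intervals and Kruskal-Wallis with Dunn's pairwise follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StrataConfig",
    "normalize_to_reference",
    "assign_strata",
    "outcome_rates",
    "spearman_ci",
    "kruskal_dunn",
]


def normalize_to_reference(
    expr: pd.DataFrame, control_ids: Sequence[str]
) -> pd.DataFrame:
    """Centre every gene on the mean of the reference (control) samples.

    Log-scale expression minus the per-gene control mean; control columns are
    retained in the output.
    """
    controls = list(control_ids)
    missing = sorted(set(controls) - set(expr.columns))
    if missing:
        raise ValueError(f"control ids not in expression matrix: {missing}")
    if len(controls) < 2:
        raise ValueError("need at least 2 control samples to normalize")
    ref_mean = expr[controls].mean(axis=1)
    return expr.sub(ref_mean, axis=0)


@dataclass(frozen=True)
class StrataConfig:
    """Ordered thresholds and labels for enrichment-score strata.

    Intervals are left-closed on thresholds: (-inf, t1), [t1, t2), ...,
    [tk, inf).  With defaults, ES < 0 -> low, 0 <= ES < 0.25 -> mid,
    ES >= 0.25 -> high.
    """

    thresholds: tuple[float, ...] = (0.0, 0.25)
    labels: tuple[str, ...] = ("low", "mid", "high")

    def __post_init__(self) -> None:
        th = np.asarray(self.thresholds, dtype=float)
        if not np.all(np.diff(th) > 0):
            raise ValueError("thresholds must be strictly increasing")
        if len(self.labels) != len(self.thresholds) + 1:
            raise ValueError("need exactly len(thresholds)+1 labels")


def assign_strata(es: pd.Series, cfg: StrataConfig | None = None) -> pd.Series:
    """Assign each sample's enrichment score to a stratum label."""
    cfg = cfg or StrataConfig()
    vals = np.asarray(es, dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("enrichment scores must be finite")
    idx = np.searchsorted(np.asarray(cfg.thresholds), vals, side="right")
    labels = np.asarray(cfg.labels, dtype=object)[idx]
    return pd.Series(
        pd.Categorical(labels, categories=list(cfg.labels), ordered=True),
        index=es.index,
        name="stratum",
    )


def outcome_rates(
    cohort: pd.DataFrame,
    strata: pd.Series,
    outcome: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outcome rates per stratum x arm, with pairwise exact stratum tests.

    ``cohort`` must carry an ``arm`` column and a 0/1 (or NaN) column named
    ``outcome``; samples with missing outcome (e.g. controls) are excluded.
    Returns (rates, pairwise): the first holds numerator / denominator / rate
    per stratum and arm (empty strata reported with NaN rate), the second
    two-sided Fisher exact p-values for every stratum pair within each arm
    (classical convention: summing tables with probability <= observed).
    """
    if outcome not in cohort.columns:
        raise ValueError(f"unknown outcome {outcome!r}")
    df = cohort.join(strata.rename("stratum"), how="inner")
    df = df[df[outcome].notna()]
    strata_levels = (
        list(strata.cat.categories)
        if isinstance(strata.dtype, pd.CategoricalDtype)
        else sorted(df["stratum"].unique())
    )
    arms = list(pd.unique(df["arm"]))
    rows = []
    for arm in arms:
        sub = df[df["arm"] == arm]
        for st in strata_levels:
            cell = sub[sub["stratum"] == st]
            num = int(cell[outcome].sum())
            den = int(len(cell))
            rows.append(
                {
                    "arm": arm, "stratum": st, "outcome": outcome,
                    "numerator": num, "denominator": den,
                    "rate": num / den if den else np.nan,
                }
            )
    rates = pd.DataFrame(rows)
    pw = []
    for arm in arms:
        sub = rates[(rates["arm"] == arm) & (rates["denominator"] > 0)]
        for (_, a), (_, b) in combinations(sub.iterrows(), 2):
            table = [
                [a["numerator"], a["denominator"] - a["numerator"]],
                [b["numerator"], b["denominator"] - b["numerator"]],
            ]
            _, p = stats.fisher_exact(table, alternative="two-sided")
            pw.append(
                {
                    "arm": arm, "stratum_a": a["stratum"], "stratum_b": b["stratum"],
                    "outcome": outcome, "p_fisher": float(p),
                }
            )
    pairwise = pd.DataFrame(pw, columns=["arm", "stratum_a", "stratum_b", "outcome", "p_fisher"])
    return rates, pairwise


def spearman_ci(
    x: Sequence[float],
    y: Sequence[float],
    conf: float = 0.95,
) -> dict[str, float]:
    """Spearman rank correlation with a Fisher-z confidence interval.

    Ties receive average ranks.  The CI back-transforms
    atanh(r) +/- z * 1/sqrt(n-3) through tanh.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be paired 1-d arrays")
    if len(xa) < 4:
        raise ValueError("need at least 4 pairs")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValueError("values must be finite")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.spearmanr(xa, ya)
    n = len(xa)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    zq = stats.norm.ppf(0.5 + conf / 2.0)
    lo, hi = np.tanh(z - zq * se), np.tanh(z + zq * se)
    return {"r": float(r), "ci_low": float(lo), "ci_high": float(hi),
            "n": n, "p": float(p)}


def kruskal_dunn(
    values: Sequence[float],
    groups: Sequence,
    adjust: str = "bonferroni",
) -> dict:
    """Kruskal-Wallis H test with Dunn's pairwise comparisons.

    H uses the tie correction (scipy); Dunn z statistics compare mean ranks
    with the pooled-variance tie correction, adjusted by Bonferroni (default)
    or BH.  Returns H, the global p, and a pairwise table.
    """
    vals = np.asarray(values, dtype=float)
    grp = np.asarray(groups)
    if vals.shape != grp.shape:
        raise ValueError("values and groups must align")
    levels = list(pd.unique(grp))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [vals[grp == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one value")
    if np.ptp(vals) == 0:
        h, p_global = 0.0, 1.0
    else:
        h, p_global = stats.kruskal(*samples)
    n = len(vals)
    ranks = stats.rankdata(vals)
    _, counts = np.unique(vals, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    mean_rank = {g: ranks[grp == g].mean() for g in levels}
    sizes = {g: int((grp == g).sum()) for g in levels}
    pairs = list(combinations(levels, 2))
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p_raw": float(p_raw)})
    pairwise = pd.DataFrame(rows)
    if adjust == "bonferroni":
        pairwise["p_adj"] = np.minimum(pairwise["p_raw"] * len(pairs), 1.0)
    elif adjust == "bh":
        from .de import bh_adjust

        pairwise["p_adj"] = bh_adjust(np.clip(pairwise["p_raw"].to_numpy(), 1e-300, 1.0))
    else:
        raise ValueError("adjust must be 'bonferroni' or 'bh'")
    return {"H": float(h), "p_global": float(p_global), "pairwise": pairwise}
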