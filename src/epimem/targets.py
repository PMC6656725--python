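"""Regulatory-potential target inference (BETA-style).

Each gene receives a regulatory-potential score summing exponentially
decaying contributions from binding-region centers within a window of its
TSS:

    S_g = sum over peaks with |center - TSS| <= window of e^{-(0.5 + 4 d)}

with d the TSS distance as a fraction of the window (100 kb by default).
A peak on the TSS contributes e^-0.5, one at the window edge e^-4.5.

Activating/repressive function is inferred by comparing the score
distributions of up-, down-regulated and static gene groups with a
two-sided two-sample Kolmogorov–Smirnov test and cumulative score-rank
curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TssRecord
from .intervals import IntervalSet

__all__ = [
    "RegulatoryPotential",
    "KsResult",
    "regulatory_potential",
    "regulatory_potential_table",
    "ks_statistic",
    "activating_repressive",
    "predicted_targets",
    "expression_groups",
]


@dataclass(frozen=True)
class RegulatoryPotential:
    gene_id: str
    score: float
    n_peaks_in_window: int


@dataclass(frozen=True)
class KsResult:
    group: str
    D: float
    p: float
    direction: int  # sign of the score shift vs the static background


def regulatory_potential(
    tss: TssRecord, peaks: IntervalSet, window: int = 100_000
) -> RegulatoryPotential:
    """Score one gene from peak centers within ``window`` bp of its TSS."""
    if window <= 0:
        raise ValueError("window must be > 0")
    score = 0.0
    n = 0
    for iv in peaks:
        if iv.chrom != tss.chrom:
            continue
        delta = abs(iv.center - tss.position)
        if delta <= window:
            score += math.exp(-(0.5 + 4.0 * delta / window))
            n += 1
    return RegulatoryPotential(gene_id=tss.gene_id, score=score, n_peaks_in_window=n)


def regulatory_potential_table(
    tss: Sequence[TssRecord], peaks: IntervalSet, window: int = 100_000
) -> pd.DataFrame:
    rows = [regulatory_potential(t, peaks, window) for t in tss]
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "score": [r.score for r in rows],
            "n_peaks_in_window": [r.n_peaks_in_window for r in rows],
        }
    )


def ks_statistic(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided two-sample KS statistic and asymptotic p-value.

    D is the supremum over pooled sample points of |F_x - F_y|; p comes
    from the asymptotic Kolmogorov distribution with effective sample size
    n_x n_y / (n_x + n_y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("KS test requires non-empty samples")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    # floor keeps p in (0, 1] when the Kolmogorov tail underflows
    return float(res.statistic), float(max(res.pvalue, 5e-324))


def expression_groups(
    expression: pd.DataFrame,
    q_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> Tuple[List[str], List[str], List[str]]:
    """Split a (gene, log2fc, q) table into up / down / static gene lists
    (FDR < 0.05 and |log2FC| > 1 by default)."""
    sig = (expression["q"] < q_threshold) & (
        expression["log2fc"].abs() > lfc_threshold
    )
    up = list(expression.loc[sig & (expression["log2fc"] > 0), "gene_id"])
    down = list(expression.loc[sig & (expression["log2fc"] < 0), "gene_id"])
    static = list(expression.loc[~sig, "gene_id"])
    return up, down, static


def activating_repressive(
    scores: pd.DataFrame,
    up_genes: Sequence[str],
    down_genes: Sequence[str],
    static_genes: Sequence[str],
) -> Tuple[KsResult, KsResult, pd.DataFrame]:
    """KS comparison of up- and down-regulated genes against the static
    background, plus cumulative curves over the score-rank axis.

    Genes are ranked by descending regulatory potential; for each group the
    curve gives the cumulative fraction of the group's genes found within
    the top-k ranks. An activating factor pushes the up-group curve above
    the static curve (direction +1).
    """
    up_s, down_s, static_s = set(up_genes), set(down_genes), set(static_genes)
    if (up_s & down_s) or (up_s & static_s) or (down_s & static_s):
        raise ValueError("gene groups must be disjoint")
    for name, grp in (("up", up_s), ("down", down_s), ("static", static_s)):
        if len(grp) < 10:
            raise ValueError(f"group {name!r} has fewer than 10 genes")
    score_map = dict(zip(scores["gene_id"], scores["score"]))
    missing = (up_s | down_s | static_s) - set(score_map)
    if missing:
        raise ValueError(f"genes without scores: {sorted(missing)[:5]}...")

    def vec(genes: set) -> np.ndarray:
        return np.array([score_map[g] for g in sorted(genes)])

    results = []
    for name, genes in (("up", up_s), ("down", down_s)):
        v, s = vec(genes), vec(static_s)
        D, p = ks_statistic(v, s)
        direction = int(np.sign(np.mean(stats.rankdata(np.concatenate([v, s]))[: len(v)])
                                - (len(v) + len(s) + 1) / 2.0))
        results.append(KsResult(group=name, D=D, p=p, direction=direction))

    ranked = scores.sort_values(
        ["score", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
    curves = {"rank": np.arange(1, len(ranked) + 1)}
    for name, genes in (("up", up_s), ("down", down_s), ("static", static_s)):
        member = ranked["gene_id"].isin(genes).to_numpy()
        cum = np.cumsum(member) / max(1, len(genes))
        curves[name] = cum
    return results[0], results[1], pd.DataFrame(curves)


def predicted_targets(
    scores: pd.DataFrame,
    up_genes: Sequence[str],
    down_genes: Sequence[str],
    static_genes: Sequence[str],
    score_quantile: float = 0.5,
) -> List[str]:
    """Differentially expressed genes whose regulatory potential exceeds the
    given quantile of the static-gene score distribution."""
    score_map = dict(zip(scores["gene_id"], scores["score"]))
    static_scores = np.array([score_map[g] for g in static_genes])
    cutoff = float(np.quantile(static_scores, score_quantile))
    de = list(up_genes) + list(down_genes)
    return sorted(g for g in de if score_map.get(g, 0.0) > cutoff)
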