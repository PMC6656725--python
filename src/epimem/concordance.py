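"""Cross-dataset enhancer concordance between conventional (T_M) and innate
(T_IM) memory CD8 T cells.

Each enhancer region carries a log2 fold-change and FDR-adjusted p from
three memory-vs-naive comparisons: two conventional-memory datasets (an
LCMV infection model and a Listeria infection model) and the innate-memory
thymocyte comparison. The two conventional datasets are collapsed to a
consensus status, and the (consensus T_M, T_IM) status pair maps onto six
concordance clusters:

=========  =========  =======
T_M        T_IM       cluster
=========  =========  =======
up         none       C1  (gain specific to conventional memory)
up         up         C2  (shared gain)
none       up         C3  (gain specific to innate memory)
down       none       C4  (loss specific to conventional memory)
down       down       C5  (shared loss)
none       down       C6  (loss specific to innate memory)
=========  =========  =======

Contradictory sign pairs (up, down) / (down, up) are dropped with a
warning; (none, none) is unlabelled.
"""

from __future__ import annotations

import logging
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .diff import log2_fold_change, normalize_to_lowest
from .intervals import IntervalSet, overlap_fraction

logger = logging.getLogger(__name__)

__all__ = [
    "CLUSTERS",
    "consensus_tm_status",
    "assign_cluster",
    "composition",
    "median_replicate_lfc",
    "wilcoxon_signed_rank",
    "cluster_expression_shift",
    "cluster_tf_overlap",
]

CLUSTERS = ("C1", "C2", "C3", "C4", "C5", "C6")

_CLUSTER_TABLE: Dict[Tuple[str, str], str] = {
    ("up", "none"): "C1",
    ("up", "up"): "C2",
    ("none", "up"): "C3",
    ("down", "none"): "C4",
    ("down", "down"): "C5",
    ("none", "down"): "C6",
    ("none", "none"): "none",
}


def consensus_tm_status(
    lcmv: Tuple[float, float],
    listeria: Tuple[float, float],
    alpha: float = 0.05,
    require_both: bool = False,
) -> str:
    """Consensus conventional-memory status from two (lfc, q) datasets.

    Default rule: a sign wins when at least one dataset is significant with
    that sign and the other is not significantly of the opposite sign.
    ``require_both=True`` switches to the strict rule (both datasets
    significant with the same sign).
    """
    def status(lfc: float, q: float) -> str:
        if q < alpha and lfc > 0:
            return "up"
        if q < alpha and lfc < 0:
            return "down"
        return "none"

    s1, s2 = status(*lcmv), status(*listeria)
    if require_both:
        return s1 if s1 == s2 and s1 != "none" else "none"
    if s1 == "none":
        return s2
    if s2 == "none" or s2 == s1:
        return s1
    return "none"  # significant contradiction


def assign_cluster(tm: str, tim: str) -> str:
    """Map a (T_M status, T_IM status) pair onto C1..C6 / none."""
    for s in (tm, tim):
        if s not in ("up", "down", "none"):
            raise ValueError(f"status must be up/down/none, got {s!r}")
    if (tm, tim) in (("up", "down"), ("down", "up")):
        logger.warning(
            "contradictory T_M/T_IM signs (%s, %s); region left unclustered",
            tm,
            tim,
        )
        return "none"
    return _CLUSTER_TABLE[(tm, tim)]


def composition(labels: Sequence[str]) -> pd.DataFrame:
    """Counts and percentages per cluster, split by gain/loss side.

    C1-C3 form the *more_active* side, C4-C6 the *less_active* side;
    percentages sum to 100 within each side. Unlabelled regions are
    excluded. Raises when a side has no labelled region.
    """
    counts = {c: 0 for c in CLUSTERS}
    for lab in labels:
        if lab in counts:
            counts[lab] += 1
    rows = []
    for side, members in (("more_active", CLUSTERS[:3]), ("less_active", CLUSTERS[3:])):
        total = sum(counts[c] for c in members)
        if total == 0:
            raise ValueError(f"no labelled regions on side {side!r}")
        for c in members:
            rows.append(
                {
                    "side": side,
                    "cluster": c,
                    "count": counts[c],
                    "percent": 100.0 * counts[c] / total,
                }
            )
    return pd.DataFrame(rows)


def median_replicate_lfc(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    library_sizes_a: Sequence[float],
    library_sizes_b: Sequence[float],
    pseudocount: float = 1.0,
) -> float:
    """Robust per-region log2 fold-change: normalize every replicate to the
    lowest library, take the median per condition, then the log2 ratio."""
    counts = np.array(list(counts_a) + list(counts_b), dtype=np.int64)
    libs = np.array(list(library_sizes_a) + list(library_sizes_b))
    norm = normalize_to_lowest(counts[None, :], libs)[0]
    k = len(counts_a)
    med_a = float(np.median(norm[:k]))
    med_b = float(np.median(norm[k:]))
    return log2_fold_change(med_a, med_b, pseudocount)


def _signed_rank_exact_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p over all 2^n sign assignments, by subset-sum DP.

    Works with midranks (tie-averaged ranks): doubling makes them integers,
    and the null distribution of W+ stays symmetric about half the rank
    total under independent sign flips.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: len(dist) - r]
        dist += shifted
    w2 = int(round(2 * w_plus))
    mean = total / 2.0
    dev = abs(w2 - mean)
    support = np.arange(total + 1)
    mass = dist[np.abs(support - mean) >= dev - 1e-9].sum()
    return min(1.0, float(mass / 2.0 ** len(ranks)))


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped (Wilcoxon's original treatment); if all
    differences vanish the test is vacuous and p = 1 by convention. The
    exact permutation null is used for n <= 25 (ties handled via midranks),
    the normal approximation with continuity correction above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if len(x) < 5:
        raise ValueError("need n >= 5 pairs for a meaningful signed-rank test")
    d = x - y
    d = d[d != 0]
    if len(d) == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if len(d) <= 25:
        return w_plus, _signed_rank_exact_p(w_plus, ranks)
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
    return w_plus, float(res.pvalue)


def cluster_expression_shift(
    tm_gene_lfc: Dict[str, float],
    tim_gene_lfc: Dict[str, float],
    cluster_gene_sets: Dict[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-cluster paired test of conventional- vs innate-memory expression
    shifts of cluster-associated genes.

    For each cluster, genes present in both LFC tables are paired and the
    two-sided signed-rank test compares their T_M/naive and T_IM/naive
    log2 fold-changes.
    """
    rows = []
    for cluster, genes in cluster_gene_sets.items():
        common = [g for g in genes if g in tm_gene_lfc and g in tim_gene_lfc]
        if len(common) < 5:
            raise ValueError(
                f"cluster {cluster!r} has only {len(common)} paired genes (need >= 5)"
            )
        a = [tm_gene_lfc[g] for g in common]
        b = [tim_gene_lfc[g] for g in common]
        w, p = wilcoxon_signed_rank(a, b)
        rows.append(
            {
                "cluster": cluster,
                "n_genes": len(common),
                "W": w,
                "p": p,
                "median_tm": float(np.median(a)),
                "median_tim": float(np.median(b)),
            }
        )
    return pd.DataFrame(rows)


def cluster_tf_overlap(
    cluster_regions: Dict[str, IntervalSet],
    tf_peaks: Dict[str, IntervalSet],
) -> pd.DataFrame:
    """Percentage of each cluster's regions overlapping each factor's peaks."""
    rows = []
    for cluster, regions in cluster_regions.items():
        if len(regions) == 0:
            raise ValueError(f"cluster {cluster!r} is empty")
        for factor, peaks in tf_peaks.items():
            frac = (
                overlap_fraction(regions, peaks) if len(peaks) else 0.0
            )
            rows.append(
                {
                    "cluster": cluster,
                    "factor": factor,
                    "percent": 100.0 * frac,
                    "n_regions": len(regions),
                }
            )
    return pd.DataFrame(rows)
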