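"""Differential chromatin activity over an atlas: Poisson test with
lowest-library normalization.

The test compares two conditions region by region. Replicate counts are
pooled by summation per condition, every sample is scaled to the smallest
total library size (rounding half away from zero), and each region gets

* a log2 fold-change ``log2((n_a + c) / (n_b + c))`` with pseudocount ``c``;
* a two-sided Poisson p-value under the equal-split null
  ``lambda = (n_a + n_b) / 2``, ``p = min(1, 2 * min(P[X <= min],
  P[X >= max]))`` — exact, symmetric, 1 at (0, 0);
* optionally a "proportion of library" filter, expressed as the exact
  conditional binomial test ``k_a ~ Bin(k_a + k_b, N_a / (N_a + N_b))`` on
  the *raw* pooled counts and library sizes.

P-values are Benjamini–Hochberg adjusted over all atlas regions; a region
is called up/down when its adjusted p (and, when the filter is enabled, the
filter's adjusted p as well) clears ``fdr_alpha`` and |log2FC| exceeds
``lfc_threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import AtlasRegion, IntervalSet

__all__ = [
    "CountMatrix",
    "DiffConfig",
    "count_fragments",
    "normalize_to_lowest",
    "poisson_two_sided_p",
    "proportion_filter_p",
    "log2_fold_change",
    "bh_adjust",
    "call_differential",
    "read_counts_tsv",
    "write_results_tsv",
]


@dataclass
class CountMatrix:
    """Region x sample integer counts with library sizes and conditions."""

    region_ids: List[str]
    sample_ids: List[str]
    counts: np.ndarray  # (n_regions, n_samples) int
    library_sizes: np.ndarray  # (n_samples,)
    condition: Dict[str, str]  # sample_id -> condition label

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        if self.counts.shape != (len(self.region_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match region/sample ids")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.library_sizes) != len(self.sample_ids):
            raise ValueError("one library size per sample required")
        missing = [s for s in self.sample_ids if s not in self.condition]
        if missing:
            raise ValueError(f"samples without condition: {missing}")

    @property
    def conditions(self) -> List[str]:
        """Condition labels in order of first appearance among samples."""
        seen: List[str] = []
        for s in self.sample_ids:
            c = self.condition[s]
            if c not in seen:
                seen.append(c)
        return seen


@dataclass
class DiffConfig:
    pseudocount: float = 1.0
    fdr_alpha: float = 0.05  # 0.001 for the Eomes-transgenic ATAC comparison
    lfc_threshold: float = 0.0  # 1.0 for expression tables
    use_proportion_filter: bool = False
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


def count_fragments(
    atlas: Sequence[AtlasRegion],
    fragments: Dict[str, IntervalSet],
    condition: Dict[str, str],
    library_sizes: Dict[str, int] | None = None,
) -> CountMatrix:
    """Count fragments per atlas region (a fragment hits every region it
    overlaps by >=1 bp; atlas disjointness bounds this at two regions for a
    gap-spanning fragment).

    ``library_sizes`` defaults to each sample's total fragment count.
    """
    sample_ids = list(fragments)
    region_ids = [f"region_{i}" for i in range(len(atlas))]
    counts = np.zeros((len(atlas), len(sample_ids)), dtype=np.int64)
    regions_by_chrom: Dict[str, List[tuple]] = {}
    for i, reg in enumerate(atlas):
        iv = reg.interval
        regions_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
    for ch in regions_by_chrom:
        regions_by_chrom[ch].sort()
    import bisect

    for j, sid in enumerate(sample_ids):
        for frag in fragments[sid]:
            regs = regions_by_chrom.get(frag.chrom, [])
            starts = [r[0] for r in regs]
            k = bisect.bisect_right(starts, frag.end) - 1
            # walk left while regions may still overlap the fragment
            while k >= 0:
                rs, re, idx = regs[k]
                if re <= frag.start:
                    # disjoint sorted regions: everything further left ends
                    # earlier still
                    break
                if min(re, frag.end) > max(rs, frag.start):
                    counts[idx, j] += 1
                k -= 1
    if library_sizes is None:
        libs = np.array([len(fragments[s]) for s in sample_ids], dtype=np.int64)
    else:
        libs = np.array([library_sizes[s] for s in sample_ids], dtype=np.int64)
    return CountMatrix(region_ids, sample_ids, counts, libs, dict(condition))


def normalize_to_lowest(
    counts: np.ndarray, library_sizes: np.ndarray
) -> np.ndarray:
    """Scale each sample's counts to the smallest total library size.

    A count ``k`` from a sample of size ``N`` becomes
    ``round(k * Nmin / N)`` with rounding half away from zero; samples
    already at ``Nmin`` are untouched.
    """
    counts = np.asarray(counts)
    libs = np.asarray(library_sizes, dtype=float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    ratio = libs.min() / libs
    scaled = counts * ratio
    return np.floor(scaled + 0.5).astype(np.int64)  # counts >= 0: half away from zero


def poisson_two_sided_p(n_a, n_b, two_sided: bool = True):
    """Exact Poisson p-value for equal counts under the equal-split null.

    lambda = (n_a + n_b)/2; two-sided p = min(1, 2 * min(lower tail at
    min(n_a, n_b), upper tail at max(n_a, n_b))), both tails including the
    point mass. Symmetric in its arguments; (0, 0) -> 1. Accepts scalars or
    arrays.
    """
    a = np.asarray(n_a)
    b = np.asarray(n_b)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    lam = (a + b) / 2.0
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    lower = stats.poisson.cdf(lo, lam)
    upper = stats.poisson.sf(hi - 1, lam)  # P[X >= hi]
    tail = np.minimum(lower, upper)
    p = np.minimum(1.0, (2.0 if two_sided else 1.0) * tail)
    return p if p.ndim else float(p)


def proportion_filter_p(k_a, k_b, N_a, N_b):
    """Exact conditional binomial test on raw counts and library sizes.

    Conditional on the total ``n = k_a + k_b``, under the null
    ``k_a ~ Binomial(n, N_a / (N_a + N_b))``; two-sided
    p = min(1, 2 * min(tails)). (0, 0) -> 1.
    """
    ka = np.asarray(k_a)
    kb = np.asarray(k_b)
    Na = np.asarray(N_a, dtype=float)
    Nb = np.asarray(N_b, dtype=float)
    if (Na <= 0).any() or (Nb <= 0).any():
        raise ValueError("library sizes must be positive")
    n = ka + kb
    p0 = Na / (Na + Nb)
    lower = stats.binom.cdf(ka, n, p0)
    upper = stats.binom.sf(ka - 1, n, p0)
    p = np.where(n == 0, 1.0, np.minimum(1.0, 2.0 * np.minimum(lower, upper)))
    return p if p.ndim else float(p)


def log2_fold_change(n_a, n_b, pseudocount: float = 1.0):
    """log2((n_a + c) / (n_b + c)); antisymmetric, 0 at (0, 0)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    a = np.asarray(n_a, dtype=float)
    b = np.asarray(n_b, dtype=float)
    out = np.log2((a + pseudocount) / (b + pseudocount))
    return out if out.ndim else float(out)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (R ``p.adjust`` "fdr")."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    m: CountMatrix,
    cfg: DiffConfig = DiffConfig(),
    conditions: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Run the full differential test on a two-condition count matrix.

    Returns a table with columns region_id, n_a, n_b, log2fc, p_poisson,
    p_proportion, q, q_proportion, direction. ``n_a``/``n_b`` are the
    pooled, lowest-library-normalized counts; direction is up when
    condition A exceeds condition B. ``conditions`` fixes the (A, B)
    ordering; by default A is the condition of the first sample.
    """
    conds = m.conditions
    if len(conds) != 2:
        raise ValueError(
            f"call_differential needs exactly two conditions, got {conds}; "
            "run pairwise comparisons for multi-condition designs"
        )
    if conditions is not None:
        if sorted(conditions) != sorted(conds):
            raise ValueError(f"conditions {conditions} do not match matrix {conds}")
        cond_a, cond_b = conditions
    else:
        cond_a, cond_b = conds
    idx_a = [j for j, s in enumerate(m.sample_ids) if m.condition[s] == cond_a]
    idx_b = [j for j, s in enumerate(m.sample_ids) if m.condition[s] == cond_b]
    raw_a = m.counts[:, idx_a].sum(axis=1)
    raw_b = m.counts[:, idx_b].sum(axis=1)
    lib_a = int(m.library_sizes[idx_a].sum())
    lib_b = int(m.library_sizes[idx_b].sum())
    pooled = np.column_stack([raw_a, raw_b])
    norm = normalize_to_lowest(pooled, np.array([lib_a, lib_b]))
    n_a, n_b = norm[:, 0], norm[:, 1]
    lfc = log2_fold_change(n_a, n_b, cfg.pseudocount)
    p_pois = poisson_two_sided_p(n_a, n_b, two_sided=cfg.two_sided)
    q = bh_adjust(p_pois)
    if cfg.use_proportion_filter:
        p_prop = proportion_filter_p(raw_a, raw_b, lib_a, lib_b)
        q_prop = bh_adjust(p_prop)
    else:
        p_prop = np.ones_like(p_pois)
        q_prop = np.ones_like(p_pois)
    sig = q < cfg.fdr_alpha
    if cfg.use_proportion_filter:
        sig &= q_prop < cfg.fdr_alpha
    sig &= np.abs(lfc) > cfg.lfc_threshold
    direction = np.where(~sig, "ns", np.where(lfc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "region_id": m.region_ids,
            "n_a": n_a,
            "n_b": n_b,
            "log2fc": lfc,
            "p_poisson": p_pois,
            "p_proportion": p_prop,
            "q": q,
            "q_proportion": q_prop,
            "direction": direction,
        }
    )


def read_counts_tsv(
    counts_path: str | Path, samples_path: str | Path
) -> CountMatrix:
    """Load a counts TSV (region_id + one integer column per sample) and a
    samples TSV (sample_id, condition, optional library_size).

    When library_size is absent it defaults to the sample's in-atlas total.
    """
    df = pd.read_csv(counts_path, sep="\t")
    if df.columns[0] != "region_id":
        raise ValueError("first counts column must be region_id")
    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    sample_ids = list(samples["sample_id"])
    missing = [s for s in sample_ids if s not in df.columns]
    if missing:
        raise ValueError(f"samples missing from counts table: {missing}")
    counts = df[sample_ids].to_numpy(dtype=np.int64)
    if "library_size" in samples.columns and samples["library_size"].notna().all():
        libs = samples["library_size"].to_numpy(dtype=np.int64)
    else:
        libs = counts.sum(axis=0)
    condition = dict(zip(samples["sample_id"], samples["condition"]))
    return CountMatrix(
        list(df["region_id"].astype(str)), sample_ids, counts, libs, condition
    )


def write_results_tsv(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)
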