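"""Promoter/enhancer classification from histone-mark geometry around TSSs.

Two promoter conventions coexist in this pipeline and are both implemented:

* histone analyses — a strand-aware window from −5 kb to +2 kb around the
  TSS; H3K4me3+ regions overlapping such a window (>=1 bp) are promoters,
  and H3K4me1+ regions at least 2 kb from every TSS that do not overlap a
  promoter are enhancers;
* accessibility (ATAC) analyses — a strand-independent ±2 kb window around
  the TSS; peaks touching it are promoter-class, all others enhancer-class.

The constants live in :class:`AnnotationConfig` and are selected per
pipeline stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .intervals import (
    AtlasRegion,
    GenomicInterval,
    IntervalSet,
    distance_to_nearest,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TssRecord",
    "AnnotationConfig",
    "AnnotatedRegion",
    "read_tss_table",
    "promoter_windows",
    "atac_promoter_windows",
    "define_promoters",
    "define_enhancers",
    "classify_activity_atlas",
    "classify_atac_peaks",
    "nearest_gene",
    "genomic_distribution",
]


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site: gene id, chromosome, 0-based position, strand."""

    gene_id: str
    chrom: str
    position: int
    strand: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("TSS position must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class AnnotationConfig:
    """Window sizes (bp) for promoter/enhancer geometry.

    promoter_upstream/promoter_downstream: strand-aware histone promoter
    window (−5 kb / +2 kb around the TSS). enhancer_exclusion: minimum
    TSS distance for enhancers. atac_window: half-width of the
    strand-independent promoter window used for accessibility peaks.
    """

    promoter_upstream: int = 5000
    promoter_downstream: int = 2000
    enhancer_exclusion: int = 2000
    atac_window: int = 2000

    def __post_init__(self) -> None:
        for name in (
            "promoter_upstream",
            "promoter_downstream",
            "enhancer_exclusion",
            "atac_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class AnnotatedRegion:
    interval: GenomicInterval
    reg_class: str  # promoter | enhancer | unclassified
    nearest_gene: str | None = None
    signed_distance: float | None = None  # negative = upstream of TSS (gene strand)


def read_tss_table(path: str | Path) -> List[TssRecord]:
    """Read a TSS table (TSV with header gene_id, chrom, position, strand)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "position", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValueError("gene_id values must be unique")
    return [
        TssRecord(r.gene_id, r.chrom, int(r.position), r.strand)
        for r in df.itertuples(index=False)
    ]


def promoter_windows(
    tss: Sequence[TssRecord], cfg: AnnotationConfig = AnnotationConfig()
) -> IntervalSet:
    """One strand-aware promoter window per TSS (−upstream / +downstream).

    For a + strand gene the window is ``[pos − upstream, pos + downstream)``;
    for − strand it mirrors to ``[pos − downstream, pos + upstream)``.
    Windows are clipped at 0 and NOT merged.
    """
    out = []
    for t in tss:
        if t.strand == "+":
            lo, hi = t.position - cfg.promoter_upstream, t.position + cfg.promoter_downstream
        else:
            lo, hi = t.position - cfg.promoter_downstream, t.position + cfg.promoter_upstream
        out.append(GenomicInterval(t.chrom, max(0, lo), hi, name=t.gene_id))
    return IntervalSet(label="promoter_windows", intervals=out)


def atac_promoter_windows(
    tss: Sequence[TssRecord], cfg: AnnotationConfig = AnnotationConfig()
) -> IntervalSet:
    """Strand-independent ±atac_window promoter windows around each TSS."""
    out = [
        GenomicInterval(
            t.chrom,
            max(0, t.position - cfg.atac_window),
            t.position + cfg.atac_window,
            name=t.gene_id,
        )
        for t in tss
    ]
    return IntervalSet(label="atac_promoter_windows", intervals=out)


def _overlaps_any(iv: GenomicInterval, by_chrom: Dict[str, list]) -> bool:
    for w in by_chrom.get(iv.chrom, []):
        if w.start >= iv.end:
            break
        if min(w.end, iv.end) > max(w.start, iv.start):
            return True
    return False


def define_promoters(
    h3k4me3: IntervalSet,
    tss: Sequence[TssRecord],
    cfg: AnnotationConfig = AnnotationConfig(),
) -> IntervalSet:
    """H3K4me3+ regions overlapping any −5/+2 kb TSS window by >=1 bp."""
    windows = promoter_windows(tss, cfg).by_chrom()
    hits = [iv for iv in h3k4me3 if _overlaps_any(iv, windows)]
    return IntervalSet(label="promoters", intervals=hits)


def define_enhancers(
    h3k4me1: IntervalSet,
    tss: Sequence[TssRecord],
    promoters: IntervalSet,
    cfg: AnnotationConfig = AnnotationConfig(),
) -> IntervalSet:
    """H3K4me1+ regions >=enhancer_exclusion bp from every TSS with no promoter overlap.

    Distance is measured from the region's closest edge to the nearest TSS.
    Regions on chromosomes absent from the TSS table are enhancer-eligible
    (distance +inf); a warning is logged once per such chromosome.
    """
    import bisect

    pos_by_chrom: Dict[str, List[int]] = {}
    for t in tss:
        pos_by_chrom.setdefault(t.chrom, []).append(t.position)
    for ch in pos_by_chrom:
        pos_by_chrom[ch].sort()
    prom = promoters.by_chrom()
    warned: set = set()
    out = []
    for iv in h3k4me1:
        positions = pos_by_chrom.get(iv.chrom)
        if positions is None:
            if iv.chrom not in warned:
                logger.warning(
                    "chromosome %s absent from TSS table; regions there are "
                    "enhancer-eligible by distance",
                    iv.chrom,
                )
                warned.add(iv.chrom)
            d = math.inf
        else:
            # nearest-point gap via bisect on the sorted TSS positions;
            # matches distance_to_nearest's edge convention (end - 1)
            d = math.inf
            k = bisect.bisect_left(positions, iv.start)
            for p in positions[max(0, k - 1) : k + 2]:
                if iv.start <= p < iv.end:
                    d = 0
                    break
                d = min(d, iv.start - p if p < iv.start else p - (iv.end - 1))
        if d >= cfg.enhancer_exclusion and not _overlaps_any(iv, prom):
            out.append(iv)
    return IntervalSet(label="enhancers", intervals=out)


def classify_activity_atlas(
    h3k27ac_atlas: Sequence[AtlasRegion] | IntervalSet,
    promoters: IntervalSet,
    enhancers: IntervalSet,
) -> List[AnnotatedRegion]:
    """Label each activity (H3K27ac) region promoter / enhancer / unclassified.

    Promoter takes precedence when a region overlaps both classes.
    """
    prom = promoters.by_chrom()
    enh = enhancers.by_chrom()
    regions = [
        r.interval if isinstance(r, AtlasRegion) else r for r in h3k27ac_atlas
    ]
    out = []
    for iv in regions:
        if _overlaps_any(iv, prom):
            cls = "promoter"
        elif _overlaps_any(iv, enh):
            cls = "enhancer"
        else:
            cls = "unclassified"
        out.append(AnnotatedRegion(interval=iv, reg_class=cls))
    return out


def classify_atac_peaks(
    peaks: IntervalSet,
    tss: Sequence[TssRecord],
    cfg: AnnotationConfig = AnnotationConfig(),
) -> List[AnnotatedRegion]:
    """Accessibility peaks: promoter-class iff within ±atac_window of a TSS."""
    windows = atac_promoter_windows(tss, cfg).by_chrom()
    return [
        AnnotatedRegion(
            interval=iv,
            reg_class="promoter" if _overlaps_any(iv, windows) else "enhancer",
        )
        for iv in peaks
    ]


def nearest_gene(
    iv: GenomicInterval, tss: Sequence[TssRecord]
) -> Tuple[str | None, float]:
    """Nearest gene by TSS distance and the signed distance to its TSS.

    The sign follows the gene's strand: negative = region lies upstream of
    the TSS. Ties break to the lexicographically smaller gene_id.
    """
    best: Tuple[float, str] | None = None
    best_rec = None
    for t in tss:
        if t.chrom != iv.chrom:
            continue
        d = distance_to_nearest(iv, [(t.chrom, t.position)])
        key = (d, t.gene_id)
        if best is None or key < best:
            best, best_rec = key, t
    if best_rec is None:
        return None, math.inf
    d = best[0]
    # signed: is the region upstream of the TSS in gene orientation?
    region_right_of_tss = iv.start > best_rec.position
    if best_rec.strand == "+":
        signed = d if region_right_of_tss else -d
    else:
        signed = -d if region_right_of_tss else d
    return best_rec.gene_id, signed


_FEATURE_PRECEDENCE = ("promoter", "5utr", "exon", "intron")


def genomic_distribution(
    peaks: IntervalSet,
    features: pd.DataFrame,
    tss: Sequence[TssRecord] | None = None,
    cfg: AnnotationConfig = AnnotationConfig(),
) -> pd.DataFrame:
    """Percentage of peaks per genomic category.

    ``features`` is a table with columns feature ∈ {5utr, exon, intron},
    chrom, start, end. Promoter windows are built from ``tss`` (±atac_window,
    strand-independent) when given; ``features`` may also carry explicit
    ``promoter`` rows. Each peak gets exactly one category by precedence
    promoter > 5'UTR > exon > intron > distal intergenic.
    """
    by_class: Dict[str, Dict[str, list]] = {}
    for name in _FEATURE_PRECEDENCE:
        sub = features[features["feature"] == name] if len(features) else features
        ivs = [
            GenomicInterval(str(r.chrom), int(r.start), int(r.end))
            for r in sub.itertuples(index=False)
        ] if len(sub) else []
        by_class[name] = IntervalSet(label=name, intervals=ivs).by_chrom()
    if tss is not None:
        windows = atac_promoter_windows(tss, cfg).by_chrom()
        merged_prom = {
            ch: sorted(
                by_class["promoter"].get(ch, []) + ivs, key=lambda x: (x.start, x.end)
            )
            for ch in set(by_class["promoter"]) | set(windows)
            for ivs in [windows.get(ch, [])]
        }
        by_class["promoter"] = merged_prom
    counts = {name: 0 for name in _FEATURE_PRECEDENCE}
    counts["distal_intergenic"] = 0
    for iv in peaks:
        for name in _FEATURE_PRECEDENCE:
            if _overlaps_any(iv, by_class[name]):
                counts[name] += 1
                break
        else:
            counts["distal_intergenic"] += 1
    n = max(1, len(peaks))
    rows = [
        {"category": k, "count": v, "percent": 100.0 * v / n}
        for k, v in counts.items()
    ]
    return pd.DataFrame(rows)
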