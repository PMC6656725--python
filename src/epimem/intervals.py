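"""Genomic interval data model and >=1 bp overlap algebra.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
The central construct is the *peak atlas* — the merged union of peak sets from
several samples or populations, where two intervals belong to the same atlas
region iff they overlap by at least ``min_overlap`` base pairs (1 bp by
default). Book-ended intervals (zero-bp overlap) are deliberately *not*
merged, which differs from the default of some genome-arithmetic tools.

Strand is carried through I/O but ignored by merge/overlap operations: peak
calls are unstranded; only TSS-anchored annotation (see
:mod:`epimem.annotation`) is strand-aware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "AtlasRegion",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "build_atlas",
    "write_atlas",
    "venn_counts",
    "overlap_fraction",
    "distance_to_nearest",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared base pairs (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class IntervalSet:
    """A labelled, sorted collection of intervals (one sample x mark)."""

    label: str
    intervals: List[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def by_chrom(self) -> Dict[str, List[GenomicInterval]]:
        out: Dict[str, List[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


@dataclass
class AtlasRegion:
    """A merged atlas interval with per-source membership flags."""

    interval: GenomicInterval
    membership: Dict[str, bool]

    def __post_init__(self) -> None:
        if not any(self.membership.values()):
            raise ValueError("atlas region must belong to at least one source")


# ---------------------------------------------------------------------------
# BED I/O

def read_bed(path: str | Path, label: str | None = None) -> IntervalSet:
    """Read a BED3/BED6 file into a sorted :class:`IntervalSet`.

    ``track``, ``browser`` and ``#`` comment lines are skipped. Strand is
    taken from column 6 when present, name/score from columns 4-5.

    Raises
    ------
    ValueError
        On non-integer coordinates or ``start >= end``, naming the line.
    """
    path = Path(path)
    label = label if label is not None else path.stem
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinate in {parts[1:3]}"
                ) from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                score = float(parts[4])
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            intervals.append(
                GenomicInterval(chrom, start, end, strand, name, score)
            )
    return IntervalSet(label=label, intervals=intervals)


def write_bed(s: IntervalSet | Sequence[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED (3-6 columns depending on populated fields)."""
    ivs = s.intervals if isinstance(s, IntervalSet) else list(s)
    with open(path, "w") as fh:
        for iv in ivs:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand != ".":
                cols.append(f"{iv.score:g}" if iv.score is not None else ".")
            if iv.strand != ".":
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Overlap algebra

def merge_intervals(s: IntervalSet, min_overlap: int = 1) -> IntervalSet:
    """Merge intervals overlapping by ``>= min_overlap`` bp (sorted sweep).

    The result is the transitive closure of the overlap relation, each
    equivalence class replaced by its spanning interval. Book-ended
    intervals (gap 0, overlap 0) are never merged. Name/score are dropped
    on merge — a merged region has no single parent.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    ivs = s.intervals  # already sorted by (chrom, start, end)
    merged: List[GenomicInterval] = []
    if min_overlap == 1:
        # classic sweep: the spanning interval of a component is gap-free,
        # so comparing against the growing span is exact
        cur: GenomicInterval | None = None
        for iv in ivs:
            if cur is not None and iv.chrom == cur.chrom and iv.start < cur.end:
                if iv.end > cur.end:
                    cur = GenomicInterval(cur.chrom, cur.start, iv.end)
            else:
                if cur is not None:
                    merged.append(cur)
                cur = GenomicInterval(iv.chrom, iv.start, iv.end)
        if cur is not None:
            merged.append(cur)
        return IntervalSet(label=s.label, intervals=merged)
    # general threshold: components of the pairwise >=min_overlap relation
    # (a component's span may overlap an outside interval by >= min_overlap
    # without any member doing so, so the span shortcut is invalid here)
    parent = list(range(len(ivs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    max_end = 0
    for i, a in enumerate(ivs):
        j = i + 1
        while j < len(ivs) and ivs[j].chrom == a.chrom and ivs[j].start <= a.end - min_overlap:
            if min(a.end, ivs[j].end) - max(a.start, ivs[j].start) >= min_overlap:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
            j += 1
    groups: Dict[int, List[GenomicInterval]] = {}
    for i, iv in enumerate(ivs):
        groups.setdefault(find(i), []).append(iv)
    for g in groups.values():
        merged.append(
            GenomicInterval(
                g[0].chrom, min(iv.start for iv in g), max(iv.end for iv in g)
            )
        )
    return IntervalSet(label=s.label, intervals=merged)


def build_atlas(
    sets: Sequence[IntervalSet], min_overlap: int = 1
) -> List[AtlasRegion]:
    """Pool labelled peak sets into a non-overlapping atlas with memberships.

    Each atlas region is a merged interval of the pooled input; its
    ``membership[label]`` flag is true iff some interval of that source
    overlaps the region by ``>= min_overlap`` bp.
    """
    if not sets:
        raise ValueError("build_atlas requires at least one input set")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate source labels: {labels}")
    pooled = IntervalSet(
        label="pooled", intervals=[iv for s in sets for iv in s.intervals]
    )
    merged = merge_intervals(pooled, min_overlap=min_overlap)
    per_source = {s.label: s.by_chrom() for s in sets}
    atlas: List[AtlasRegion] = []
    # sweep pointers per (source, chrom)
    pointers: Dict[Tuple[str, str], int] = {}
    for region in merged.intervals:
        membership = {}
        for lab in labels:
            ivs = per_source[lab].get(region.chrom, [])
            k = pointers.get((lab, region.chrom), 0)
            # advance past intervals wholly left of the region
            while k < len(ivs) and ivs[k].end - region.start < min_overlap:
                k += 1
            pointers[(lab, region.chrom)] = k
            hit = False
            m = k
            while m < len(ivs) and ivs[m].start < region.end:
                if min(ivs[m].end, region.end) - max(
                    ivs[m].start, region.start
                ) >= min_overlap:
                    hit = True
                    break
                m += 1
            membership[lab] = hit
        atlas.append(AtlasRegion(interval=region, membership=membership))
    return atlas


def write_atlas(
    atlas: Sequence[AtlasRegion], bed_path: str | Path, membership_path: str | Path
) -> None:
    """Write atlas as BED4 plus a sidecar TSV of 0/1 membership flags."""
    labels = list(atlas[0].membership) if atlas else []
    with open(bed_path, "w") as fh:
        for i, reg in enumerate(atlas):
            iv = reg.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tregion_{i}\n")
    with open(membership_path, "w") as fh:
        fh.write("region_id\t" + "\t".join(labels) + "\n")
        for i, reg in enumerate(atlas):
            flags = "\t".join(str(int(reg.membership[l])) for l in labels)
            fh.write(f"region_{i}\t{flags}\n")


def venn_counts(
    atlas: Sequence[AtlasRegion], a: str, b: str
) -> Tuple[int, int, int]:
    """Two-set Venn counts ``(only_a, shared, only_b)`` over atlas regions."""
    if atlas:
        known = atlas[0].membership
        for lab in (a, b):
            if lab not in known:
                raise KeyError(f"unknown source label {lab!r}; have {list(known)}")
    only_a = shared = only_b = 0
    for reg in atlas:
        ma, mb = reg.membership[a], reg.membership[b]
        if ma and mb:
            shared += 1
        elif ma:
            only_a += 1
        elif mb:
            only_b += 1
    return only_a, shared, only_b


def overlap_fraction(
    query: IntervalSet, reference: IntervalSet, min_overlap: int = 1
) -> float:
    """Fraction of query intervals with >=1 bp overlap of any reference interval."""
    if len(query) == 0:
        raise ValueError("overlap_fraction undefined for empty query set")
    ref = reference.by_chrom()
    n_hit = 0
    for iv in query:
        ivs = ref.get(iv.chrom, [])
        for r in ivs:
            if r.start >= iv.end:
                break
            if min(r.end, iv.end) - max(r.start, iv.start) >= min_overlap:
                n_hit += 1
                break
    return n_hit / len(query)


def distance_to_nearest(
    x: GenomicInterval, points: Iterable[Tuple[str, int]]
) -> float:
    """Gap in bp between an interval and its nearest same-chromosome point.

    A point inside ``[start, end)`` is at distance 0; a point right of the
    interval measures from the last included base (``end - 1``); a point
    left of it measures from ``start``. Returns ``math.inf`` when no point
    shares the chromosome. Ties break toward the smaller coordinate (the
    minimum is unaffected; the convention matters only to callers wanting
    the arg-min).
    """
    best = math.inf
    for chrom, pos in points:
        if chrom != x.chrom:
            continue
        if x.start <= pos < x.end:
            return 0
        d = x.start - pos if pos < x.start else pos - (x.end - 1)
        if d < best:
            best = d
    return best
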