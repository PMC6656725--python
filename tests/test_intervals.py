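"""Interval algebra against brute-force O(n^2) oracles and BED round trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimem.intervals import (
    GenomicInterval,
    IntervalSet,
    build_atlas,
    distance_to_nearest,
    merge_intervals,
    overlap_fraction,
    read_bed,
    venn_counts,
    write_bed,
)
from conftest import random_interval_set


# ---------------------------------------------------------------------------
# oracles

def merge_oracle(intervals, min_overlap=1):
    """Union-find over all pairs: the transitive closure of >=min_overlap."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a.chrom == b.chrom and min(a.end, b.end) - max(a.start, b.start) >= min_overlap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(intervals[i])
    spans = sorted(
        (g[0].chrom, min(iv.start for iv in g), max(iv.end for iv in g))
        for g in groups.values()
    )
    return [GenomicInterval(c, s, e) for c, s, e in spans]


def test_interval_invariants():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 100, 100)
    with pytest.raises(ValueError):
        GenomicInterval("", 0, 10)
    iv = GenomicInterval("chr1", 5, 15)
    assert len(iv) == 10 and iv.center == 10.0


@pytest.mark.parametrize(
    "content,expected",
    [
        ("", 0),
        ("chr1\t0\t100\n", 1),
        ("# comment\ntrack name=x\nchr2\t5\t8\tpeak\t3.5\t+\n", 1),
    ],
)
def test_read_bed(tmp_path, content, expected):
    p = tmp_path / "x.bed"
    p.write_text(content)
    s = read_bed(p)
    assert len(s) == expected
    if expected and "peak" in content:
        iv = s.intervals[0]
        assert (iv.name, iv.score, iv.strand) == ("peak", 3.5, "+")


def test_read_bed_rejects_zero_length(tmp_path):
    p = tmp_path / "bad.bed"
    p.write_text("chr1\t100\t100\n")
    with pytest.raises(ValueError, match="bad.bed:1"):
        read_bed(p)


def test_bed_round_trip(tmp_path, rng):
    s = random_interval_set(rng, 50)
    p = tmp_path / "rt.bed"
    write_bed(s, p)
    back = read_bed(p)
    assert [(i.chrom, i.start, i.end) for i in back] == [
        (i.chrom, i.start, i.end) for i in s
    ]


def test_merge_examples():
    s = IntervalSet("x", [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 5, 20)])
    assert [(i.start, i.end) for i in merge_intervals(s)] == [(0, 20)]
    # book-ended intervals (0 bp overlap) never merge
    s2 = IntervalSet("x", [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 10, 20)])
    assert len(merge_intervals(s2)) == 2


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("min_overlap", [1, 25])
def test_merge_matches_union_find_oracle(seed, min_overlap):
    rng = np.random.default_rng(seed)
    s = random_interval_set(rng, 200, span=4000, max_len=120)
    got = merge_intervals(s, min_overlap=min_overlap)
    expect = merge_oracle(s.intervals, min_overlap=min_overlap)
    assert [(i.chrom, i.start, i.end) for i in got] == [
        (i.chrom, i.start, i.end) for i in expect
    ]


def test_merge_large_instance_against_oracle():
    rng = np.random.default_rng(99)
    s = random_interval_set(rng, 1000, span=50_000, max_len=200)
    got = merge_intervals(s)
    expect = merge_oracle(s.intervals)
    assert [(i.chrom, i.start, i.end) for i in got] == [
        (i.chrom, i.start, i.end) for i in expect
    ]


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 60)),
        min_size=0,
        max_size=40,
    )
)
def test_merge_idempotent_and_order_invariant(pairs):
    ivs = [GenomicInterval("chr1", s, s + l) for s, l in pairs]
    once = merge_intervals(IntervalSet("a", ivs))
    twice = merge_intervals(once)
    assert once.intervals == twice.intervals
    shuffled = merge_intervals(IntervalSet("a", ivs[::-1]))
    assert once.intervals == shuffled.intervals


def test_atlas_single_set_is_merged_set(rng):
    s = random_interval_set(rng, 60)
    atlas = build_atlas([s])
    merged = merge_intervals(s)
    assert [r.interval for r in atlas] == merged.intervals
    assert all(r.membership[s.label] for r in atlas)


def test_atlas_two_set_example():
    a = IntervalSet("A", [GenomicInterval("chr1", 0, 100)])
    b = IntervalSet("B", [GenomicInterval("chr1", 50, 150)])
    atlas = build_atlas([a, b])
    assert len(atlas) == 1
    assert (atlas[0].interval.start, atlas[0].interval.end) == (0, 150)
    assert atlas[0].membership == {"A": True, "B": True}


def test_atlas_rejects_duplicate_labels(rng):
    s = random_interval_set(rng, 5, label="A")
    with pytest.raises(ValueError, match="duplicate"):
        build_atlas([s, random_interval_set(rng, 5, label="A")])


@pytest.mark.parametrize("seed", range(6))
def test_atlas_membership_matches_bruteforce(seed):
    rng = np.random.default_rng(100 + seed)
    sets = [random_interval_set(rng, 80, label=f"S{k}") for k in range(3)]
    atlas = build_atlas(sets)
    # non-overlap + coverage conservation
    by_chrom = {}
    for r in atlas:
        by_chrom.setdefault(r.interval.chrom, []).append(r.interval)
    for ivs in by_chrom.values():
        for x, y in zip(ivs, ivs[1:]):
            assert x.end <= y.start
    covered = sum(len(r.interval) for r in atlas)
    union = merge_oracle([iv for s in sets for iv in s.intervals])
    assert covered == sum(len(iv) for iv in union)
    # memberships vs all-pairs check
    for r in atlas:
        for s in sets:
            expect = any(iv.overlap_bp(r.interval) >= 1 for iv in s.intervals)
            assert r.membership[s.label] == expect


def test_venn_counts_examples_and_oracle(rng):
    a = IntervalSet("A", [GenomicInterval("chr1", 0, 10)])
    b = IntervalSet("B", [GenomicInterval("chr1", 100, 110)])
    assert venn_counts(build_atlas([a, b]), "A", "B") == (1, 0, 1)
    same = random_interval_set(rng, 30, label="A")
    same2 = IntervalSet("B", list(same.intervals))
    atlas = build_atlas([same, same2])
    only_a, shared, only_b = venn_counts(atlas, "A", "B")
    assert (only_a, only_b) == (0, 0) and shared == len(atlas)
    # random instance: enumeration over membership flags
    sets = [random_interval_set(rng, 50, label=l) for l in ("A", "B", "C")]
    atlas = build_atlas(sets)
    oa, sh, ob = venn_counts(atlas, "A", "B")
    expect = [0, 0, 0]
    for r in atlas:
        ma, mb = r.membership["A"], r.membership["B"]
        if ma and mb:
            expect[1] += 1
        elif ma:
            expect[0] += 1
        elif mb:
            expect[2] += 1
    assert [oa, sh, ob] == expect
    assert oa + sh + ob == sum(
        1 for r in atlas if r.membership["A"] or r.membership["B"]
    )
    with pytest.raises(KeyError):
        venn_counts(atlas, "A", "nope")


def test_overlap_fraction_cases(rng):
    q = random_interval_set(rng, 40, label="q")
    assert overlap_fraction(q, q) == 1.0
    far = IntervalSet("r", [GenomicInterval("chrX", 0, 10)])
    assert overlap_fraction(q, far) == 0.0
    q4 = IntervalSet(
        "q",
        [GenomicInterval("chr1", x, x + 10) for x in (0, 100, 200, 300)],
    )
    ref = IntervalSet(
        "r", [GenomicInterval("chr1", 5, 8), GenomicInterval("chr1", 105, 106)]
    )
    assert overlap_fraction(q4, ref) == 0.5
    with pytest.raises(ValueError):
        overlap_fraction(IntervalSet("e", []), ref)


def test_overlap_fraction_monotone_in_reference(rng):
    q = random_interval_set(rng, 60, label="q")
    ref_small = random_interval_set(rng, 20, label="r")
    grown = IntervalSet(
        "r2", list(ref_small.intervals) + list(random_interval_set(rng, 30).intervals)
    )
    assert overlap_fraction(q, grown) >= overlap_fraction(q, ref_small)


def test_distance_to_nearest():
    iv = GenomicInterval("chr1", 100, 200)
    assert distance_to_nearest(iv, [("chr1", 150)]) == 0
    assert distance_to_nearest(iv, [("chr1", 250)]) == 51  # 250 - (200 - 1)
    assert distance_to_nearest(iv, [("chr1", 90)]) == 10
    assert distance_to_nearest(iv, [("chr2", 150)]) == math.inf
    assert distance_to_nearest(iv, [("chr1", 250), ("chr1", 120)]) == 0
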