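"""The Poisson differential machinery against direct-summation oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimem.diff import (
    CountMatrix,
    DiffConfig,
    bh_adjust,
    call_differential,
    count_fragments,
    log2_fold_change,
    normalize_to_lowest,
    poisson_two_sided_p,
    proportion_filter_p,
    read_counts_tsv,
)
from epimem.intervals import AtlasRegion, GenomicInterval, IntervalSet
from epimem.simulate import SimConfig, simulate_counts


# ---------------------------------------------------------------------------
# oracles

def poisson_p_oracle(n_a, n_b):
    """Direct pmf summation (no scipy) of the two-sided equal-split test."""
    lam = (n_a + n_b) / 2.0
    if lam == 0:
        return 1.0
    lo, hi = min(n_a, n_b), max(n_a, n_b)

    def pmf(k):
        return math.exp(-lam + k * math.log(lam) - math.lgamma(k + 1))

    lower = sum(pmf(k) for k in range(0, lo + 1))
    upper = 1.0 - sum(pmf(k) for k in range(0, hi))
    return min(1.0, 2.0 * min(lower, upper))


def binom_p_oracle(k_a, k_b, N_a, N_b):
    n = k_a + k_b
    if n == 0:
        return 1.0
    p0 = N_a / (N_a + N_b)

    def pmf(k):
        return math.comb(n, k) * p0**k * (1 - p0) ** (n - k)

    lower = sum(pmf(k) for k in range(0, k_a + 1))
    upper = sum(pmf(k) for k in range(k_a, n + 1))
    return min(1.0, 2.0 * min(lower, upper))


def bh_oracle(p):
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        j = n - rank_from_top  # 1-based rank of p[i]
        prev = min(prev, p[i] * n / j)
        q[i] = prev
    return np.minimum(q, 1.0)


# ---------------------------------------------------------------------------
# normalization

def test_normalize_examples():
    counts = np.array([[10], [10]]).T
    assert (normalize_to_lowest(np.array([[3, 3]]), np.array([5, 5])) == [[3, 3]]).all()
    got = normalize_to_lowest(np.array([[10, 10]]), np.array([1_000_000, 2_000_000]))
    assert got.tolist() == [[10, 5]]
    got = normalize_to_lowest(np.array([[1]]), np.array([1_000_000]) )
    assert got.tolist() == [[1]]
    # count 1 at ratio 0.4 rounds down to 0
    got = normalize_to_lowest(np.array([[1, 0]]), np.array([1_000_000, 400_000]))
    assert got[0, 0] == 0
    with pytest.raises(ValueError):
        normalize_to_lowest(np.array([[1]]), np.array([0]))


def test_normalize_rounds_half_up():
    # 5 * 0.5 = 2.5 -> 3 (half away from zero)
    got = normalize_to_lowest(np.array([[5, 0]]), np.array([1_000_000, 500_000]))
    assert got[0, 0] == 3


# ---------------------------------------------------------------------------
# p-values

def test_poisson_p_examples():
    assert poisson_two_sided_p(7, 7) == 1.0
    assert poisson_two_sided_p(0, 0) == 1.0
    p = poisson_two_sided_p(10, 0)
    assert p == pytest.approx(poisson_p_oracle(10, 0), abs=1e-12)
    assert p == pytest.approx(2 * math.exp(-5), rel=1e-6)
    with pytest.raises(ValueError):
        poisson_two_sided_p(-1, 3)


@pytest.mark.parametrize("n_a,n_b", [(0, 5), (3, 17), (25, 25), (40, 12), (1, 0)])
def test_poisson_p_matches_oracle(n_a, n_b):
    assert poisson_two_sided_p(n_a, n_b) == pytest.approx(
        poisson_p_oracle(n_a, n_b), abs=1e-12
    )
    assert poisson_two_sided_p(n_b, n_a) == poisson_two_sided_p(n_a, n_b)


def test_proportion_p_examples():
    assert proportion_filter_p(4, 4, 10, 10) == 1.0
    assert proportion_filter_p(0, 0, 10, 10) == 1.0
    assert proportion_filter_p(10, 0, 1_000, 1_000) == pytest.approx(
        2 * 0.5**10, abs=1e-12
    )


def test_proportion_p_matches_oracle(rng):
    for _ in range(200):
        k_a, k_b = int(rng.integers(0, 60)), int(rng.integers(0, 60))
        N_a, N_b = int(rng.integers(1_000, 9_000)), int(rng.integers(1_000, 9_000))
        assert proportion_filter_p(k_a, k_b, N_a, N_b) == pytest.approx(
            binom_p_oracle(k_a, k_b, N_a, N_b), abs=1e-12
        )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 200), st.integers(0, 200))
def test_poisson_p_symmetric_and_in_unit_interval(a, b):
    p = poisson_two_sided_p(a, b)
    assert 0 < p <= 1
    assert p == poisson_two_sided_p(b, a)


def test_log2_fold_change():
    assert log2_fold_change(0, 0) == 0.0
    assert log2_fold_change(15, 3, 1) == pytest.approx(2.0, abs=1e-12)
    assert log2_fold_change(7, 19) == pytest.approx(-log2_fold_change(19, 7))


def test_bh_adjust_examples_and_oracle(rng):
    assert bh_adjust([0.02]).tolist() == [0.02]
    got = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])
    for _ in range(50):
        p = rng.random(int(rng.integers(1, 40)))
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_bh_preserves_order(rng):
    p = rng.random(100)
    q = bh_adjust(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()


# ---------------------------------------------------------------------------
# fragment counting

def test_count_fragments_rules_and_oracle(rng):
    atlas = [
        AtlasRegion(GenomicInterval("chr1", 0, 100), {"s": True}),
        AtlasRegion(GenomicInterval("chr1", 150, 250), {"s": True}),
    ]
    frags = {
        "s1": IntervalSet(
            "s1",
            [
                GenomicInterval("chr1", 10, 20),    # inside first
                GenomicInterval("chr1", 90, 160),   # spans the gap: both
                GenomicInterval("chr1", 120, 140),  # in the gap: neither
            ],
        )
    }
    m = count_fragments(atlas, frags, {"s1": "a"})
    # first region: inside-fragment + spanning fragment; second: spanning only
    assert m.counts[:, 0].tolist() == [2, 1]
    assert m.library_sizes.tolist() == [3]
    # random oracle
    regions = []
    pos = 0
    for i in range(30):
        pos += int(rng.integers(10, 60))
        end = pos + int(rng.integers(20, 80))
        regions.append(AtlasRegion(GenomicInterval("chr1", pos, end), {"x": True}))
        pos = end
    frag_ivs = [
        GenomicInterval("chr1", int(s), int(s) + int(l))
        for s, l in zip(rng.integers(0, pos, 300), rng.integers(1, 120, 300))
    ]
    m = count_fragments(regions, {"s": IntervalSet("s", frag_ivs)}, {"s": "a"})
    for i, reg in enumerate(regions):
        expect = sum(1 for f in frag_ivs if f.overlap_bp(reg.interval) >= 1)
        assert m.counts[i, 0] == expect


# ---------------------------------------------------------------------------
# end-to-end calling

def _matrix(counts, libs, conds):
    counts = np.asarray(counts)
    return CountMatrix(
        [f"r{i}" for i in range(counts.shape[0])],
        [f"s{j}" for j in range(counts.shape[1])],
        counts,
        libs,
        {f"s{j}": c for j, c in enumerate(conds)},
    )


def test_call_differential_identical_counts_no_calls():
    counts = np.tile(np.arange(10, 40).reshape(-1, 1), (1, 2))
    m = _matrix(counts, [1000, 1000], ["a", "b"])
    res = call_differential(m)
    assert (res["direction"] == "ns").all()


def test_call_differential_requires_two_conditions():
    m = _matrix(np.ones((3, 3), dtype=int), [10, 10, 10], ["a", "b", "c"])
    with pytest.raises(ValueError, match="pairwise"):
        call_differential(m)


def test_call_differential_invariant_to_sample_and_region_order(rng):
    counts = rng.poisson(50, size=(50, 4))
    m = _matrix(counts, [900, 1100, 1000, 950], ["a", "a", "b", "b"])
    res = call_differential(m, conditions=("a", "b")).set_index("region_id")
    perm_s = [3, 1, 0, 2]
    m2 = CountMatrix(
        m.region_ids,
        [m.sample_ids[j] for j in perm_s],
        counts[:, perm_s],
        m.library_sizes[perm_s],
        m.condition,
    )
    res2 = call_differential(m2, conditions=("a", "b")).set_index("region_id")
    pd.testing.assert_frame_equal(res, res2)
    perm_r = rng.permutation(50)
    m3 = CountMatrix(
        [m.region_ids[i] for i in perm_r],
        m.sample_ids,
        counts[perm_r],
        m.library_sizes,
        m.condition,
    )
    res3 = call_differential(m3, conditions=("a", "b")).set_index("region_id")
    pd.testing.assert_frame_equal(res.sort_index(), res3.sort_index())


def test_call_differential_invariant_to_library_rescaling(rng):
    counts = rng.poisson(80, size=(60, 4))
    libs = np.array([800_000, 900_000, 1_000_000, 1_100_000])
    m = _matrix(counts, libs, ["a", "a", "b", "b"])
    cfg = DiffConfig(use_proportion_filter=True)
    res = call_differential(m, cfg)
    m2 = _matrix(counts, libs * 2, ["a", "a", "b", "b"])
    res2 = call_differential(m2, cfg)
    pd.testing.assert_frame_equal(res, res2)


def test_null_simulation_false_positive_rate():
    cfg = SimConfig(seed=5, effect_fraction=0.5)  # betas overridden to zero
    m, _ = simulate_counts(800, cfg, betas=np.zeros(800))
    res = call_differential(m)
    fpr = float((res["p_poisson"] < 0.05).mean())
    assert 0.0 <= fpr <= 0.09  # discrete exact test is conservative


def test_planted_effects_recovered(rng):
    cfg = SimConfig(seed=17)
    m, betas = simulate_counts(2000, cfg)
    res = call_differential(m, conditions=("memory", "naive"))
    called = res["direction"] != "ns"
    truth = betas != 0
    sens = (called & truth).sum() / truth.sum()
    fdp = (called & ~truth).sum() / max(1, called.sum())
    assert sens >= 0.9
    assert fdp <= 0.1
    # directions agree with planted signs
    up = res["direction"] == "up"
    assert (betas[up.to_numpy()] > 0).mean() > 0.95


def test_counts_tsv_round_trip(tmp_path, rng):
    counts = rng.poisson(30, size=(20, 4))
    df = pd.DataFrame(counts, columns=["s1", "s2", "s3", "s4"])
    df.insert(0, "region_id", [f"r{i}" for i in range(20)])
    df.to_csv(tmp_path / "c.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "condition": ["a", "a", "b", "b"],
            "library_size": [100, 110, 90, 95],
        }
    ).to_csv(tmp_path / "s.tsv", sep="\t", index=False)
    m = read_counts_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
    assert (m.counts == counts).all()
    assert m.conditions == ["a", "b"]
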