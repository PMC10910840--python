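"""Chromosome scale, composite r², decay curves, half-distance, pruning."""

import numpy as np
import pandas as pd
import pytest

from chipqc import (
    MISSING,
    LDCurve,
    ScaffoldOrder,
    chromosome_scale,
    half_distance,
    ld_decay_curve,
    ld_prune,
    pairwise_r2,
)
from conftest import make_dataset


def test_chromosome_scale_offsets():
    so = ScaffoldOrder(scaffolds=[("sc1", 1000, "chr1"), ("sc2", 2000, "chr1"),
                                  ("sc3", 500, "chr2")])
    scale = chromosome_scale(so)
    assert scale.map_position("sc1", 7) == ("chr1", 7)       # first: unchanged
    assert scale.map_position("sc2", 1) == ("chr1", 1001)    # cumulative sum
    assert scale.map_position("sc3", 10) == ("chr2", 10)     # chr2 unaffected
    with pytest.raises(Exception):
        scale.map_position("nope", 1)


def test_pairwise_r2_values():
    assert pairwise_r2([0, 1, 2, 1, 0], [0, 1, 2, 1, 0]) == pytest.approx(1.0)
    assert pairwise_r2([0, 0, 2, 2], [2, 2, 0, 0]) == pytest.approx(1.0)
    x, y = np.array([0, 1, 2, 0]), np.array([0, 1, 0, 2])
    hand = (np.corrcoef(x, y)[0, 1]) ** 2  # arithmetic oracle
    assert pairwise_r2(x, y) == pytest.approx(hand)
    # masking: co-called subset only
    assert pairwise_r2([0, 1, 2, MISSING], [0, 1, 2, 0]) == pytest.approx(1.0)
    assert np.isnan(pairwise_r2([1, 1, 1], [0, 1, 2]))  # zero variance


def _curve(means, bin_width=1000, counts=None):
    n = len(means)
    return LDCurve(
        bin_edges=np.arange(n + 1) * bin_width,
        mean_r2=np.asarray(means, dtype=float),
        pair_count=np.asarray(counts if counts is not None else [10] * n),
        max_dist=n * bin_width, bin_width=bin_width,
    )


def test_half_distance_exponential_closed_form():
    """r²(d) = 0.8 exp(-d/lambda) sampled per bin crosses half-maximum at
    ~lambda ln 2 past the first bin midpoint."""
    lam = 100_000.0
    bw = 1000
    mids = np.arange(500, 500_000, bw)
    curve = _curve(0.8 * np.exp(-mids / lam), bin_width=bw)
    hd = half_distance(curve)
    assert hd == pytest.approx(mids[0] + lam * np.log(2), abs=bw)


def test_half_distance_edge_cases():
    assert half_distance(_curve([0.5] * 10)) == np.inf          # constant
    assert half_distance(_curve([0.1, 0.2, 0.3, 0.4])) == np.inf  # increasing
    # (1.0, 0.5): crossing exactly at bin 2's midpoint by interpolation
    assert half_distance(_curve([1.0, 0.5])) == pytest.approx(1500.0)


def test_ld_decay_curve_perfectly_linked_pair():
    calls = np.array([[0, 0], [1, 1], [2, 2], [1, 1], [0, 0], [2, 2]],
                     dtype=np.int8)
    ds = make_dataset(calls, positions=[1000, 6000])
    curves = ld_decay_curve(ds, max_dist=10_000, bin_width=1000, min_samples=6)
    curve = curves["scaffold_1"]
    assert curve.mean_r2[5] == pytest.approx(1.0)  # 5 kb apart -> bin 5
    assert curve.pair_count.sum() == 1
    # deterministic: identical on a second run
    again = ld_decay_curve(ds, max_dist=10_000, bin_width=1000, min_samples=6)
    np.testing.assert_array_equal(curve.mean_r2, again["scaffold_1"].mean_r2)


def test_ld_decay_unlinked_baseline():
    """Independent SNPs: flat curve near the finite-sample r² floor
    E[r²] ~ 1/(n-1)."""
    rng = np.random.default_rng(60)
    n = 50
    calls = rng.binomial(2, 0.4, size=(n, 120)).astype(np.int8)
    ds = make_dataset(calls, positions=np.arange(120) * 97 + 1)
    curves = ld_decay_curve(ds, max_dist=20_000, bin_width=5000)
    curve = curves["scaffold_1"]
    grand = np.average(curve.mean_r2[curve.pair_count > 0],
                       weights=curve.pair_count[curve.pair_count > 0])
    assert grand == pytest.approx(1 / (n - 1), rel=0.35)


def _markov_panel(n_samples, pos, tau, p=0.5, seed=0):
    """Haplotype-copying panel: allele correlation decays as exp(-d/tau),
    so dosage r²(d) = exp(-2d/tau) and the decay constant is tau/2."""
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_samples
    m = len(pos)
    hap = np.empty((n_hap, m), dtype=np.int8)
    hap[:, 0] = rng.random(n_hap) < p
    for j in range(1, m):
        rho = np.exp(-(pos[j] - pos[j - 1]) / tau)
        keep = rng.random(n_hap) < rho  # copy w.p. rho -> corr rho per gap
        fresh = rng.random(n_hap) < p   # else resample to stationarity
        hap[:, j] = np.where(keep, hap[:, j - 1], fresh)
    return (hap[::2] + hap[1::2]).astype(np.int8)


def test_half_distance_recovers_decay_constant():
    """On a correlated panel with r² decay constant lambda = tau/2, the
    half-distance lands near lambda ln 2 (within 10%, 200 samples)."""
    tau = 40_000.0
    lam = tau / 2.0
    pos = np.arange(1, 250) * 800
    calls = _markov_panel(200, pos, tau, seed=61)
    ds = make_dataset(calls, positions=pos)
    curve = ld_decay_curve(ds, max_dist=100_000, bin_width=2000)["scaffold_1"]
    hd = half_distance(curve)
    assert hd == pytest.approx(lam * np.log(2), rel=0.10)


def test_half_distance_shrinks_with_sample_size():
    """Small panels inflate r² (the 1/(n-1) floor), so half-distance
    estimates decrease on average as sample size grows."""
    tau = 40_000.0
    pos = np.arange(1, 150) * 1000
    small, large = [], []
    for seed in range(4):
        c_small = _markov_panel(8, pos, tau, seed=200 + seed)
        c_large = _markov_panel(120, pos, tau, seed=300 + seed)
        hd_s = half_distance(ld_decay_curve(make_dataset(c_small, positions=pos),
                                            max_dist=120_000, bin_width=3000,
                                            )["scaffold_1"])
        hd_l = half_distance(ld_decay_curve(make_dataset(c_large, positions=pos),
                                            max_dist=120_000, bin_width=3000,
                                            )["scaffold_1"])
        small.append(hd_s)
        large.append(hd_l)
    assert np.mean(large) < np.mean(small)


def test_ld_prune_trivial_and_duplicates():
    rng = np.random.default_rng(62)
    calls = rng.binomial(2, 0.5, size=(40, 10)).astype(np.int8)
    ds = make_dataset(calls)
    # generous threshold: everything retained
    assert len(ld_prune(ds, 1.0)) == 10
    # duplicate columns: exactly one of each pair retained
    dup = np.hstack([calls, calls])
    ds2 = make_dataset(dup)
    kept = ld_prune(ds2, 0.5)
    assert len(kept) == 10


def test_ld_prune_hand_traced_window():
    """5-SNP window with a constructed correlation structure follows the
    greedy most-violations-first removal."""
    rng = np.random.default_rng(63)
    base = rng.binomial(2, 0.5, size=(60, 1)).astype(np.int8)
    noise = rng.binomial(2, 0.5, size=(60, 2)).astype(np.int8)
    # v1, v2, v3 identical; v4, v5 independent
    calls = np.hstack([base, base, base, noise])
    ds = make_dataset(calls)
    kept = set(ld_prune(ds, 0.5))
    assert len(kept & {"v1", "v2", "v3"}) == 1
    assert {"v4", "v5"} <= kept


def test_ld_prune_invariant_no_violating_pairs():
    rng = np.random.default_rng(64)
    hap = _markov_panel(50, np.arange(1, 40) * 500, 20_000.0, seed=65)
    ds = make_dataset(hap, positions=np.arange(1, 40) * 500)
    t = 0.1
    kept = ld_prune(ds, t, window=39, step=39)
    idx = [list(ds.variants["id"]).index(k) for k in kept]
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            r2 = pairwise_r2(ds.calls[:, idx[a]], ds.calls[:, idx[b]])
            assert not (r2 >= t)
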