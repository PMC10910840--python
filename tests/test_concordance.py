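"""Concordance metrics, mismatch taxonomy, aggregation and filtering."""

import numpy as np
import pandas as pd
import pytest

import chipqc
from chipqc import (
    MISSING,
    PlatformSpec,
    SimConfig,
    classify_mismatch,
    cross_platform_report,
    filter_by_metrics,
    mismatch_metric_correlation,
    pairwise_concordance,
    replicate_error_rate,
    simulate_platform_pair,
    simulate_populations,
)
from conftest import make_dataset


def test_pairwise_concordance_masking_and_symmetry():
    assert pairwise_concordance([0, 1, 2, 1], [0, 1, 2, 1]) == 100.0
    assert pairwise_concordance([0, 1, 2, 1], [0, 1, 2, 2]) == 75.0
    assert pairwise_concordance([0, MISSING, 2], [0, 1, 2]) == 100.0
    assert pairwise_concordance([0, 1], [1, 0]) == pairwise_concordance([1, 0], [0, 1])
    assert np.isnan(pairwise_concordance([MISSING], [0]))


def test_replicate_error_rate():
    assert replicate_error_rate([99.52, 99.31, 99.67]) == pytest.approx(0.50)
    assert replicate_error_rate([98.46, 99.33, 98.40]) == pytest.approx(1.27)
    assert replicate_error_rate([100.0]) == 0.0


def test_classify_mismatch_taxonomy():
    same = {"ref": "A", "alt": "G"}
    assert classify_mismatch(same, same, 1, 2) == {"zygosity"}
    assert classify_mismatch({"ref": "A", "alt": "G"}, {"ref": "T", "alt": "G"},
                             0, 0) == {"ref_allele"}
    assert classify_mismatch(same, same, 1, 1) == set()
    assert classify_mismatch(same, same, MISSING, 2) == set()  # not assessed
    assert classify_mismatch({"ref": "A", "alt": "G"}, {"ref": "C", "alt": "T"},
                             1, 0) == {"ref_allele", "alt_allele", "zygosity"}


def _pair_datasets(calls_a, calls_b, populations=None):
    a = make_dataset(calls_a, populations=populations)
    b = make_dataset(calls_b, populations=populations)
    return a, b


def test_cross_platform_identical_sets_all_zero():
    calls = np.array([[0, 1, 2], [1, 1, 0]])
    a, b = _pair_datasets(calls, calls)
    rep = cross_platform_report(a, b)
    assert (rep.per_sample["percent"] == 0).all()
    assert rep.overall_mean == 0.0
    assert (rep.recurrence["n_snps"] == 0).all()


def test_cross_platform_means_and_recurrence():
    """Unweighted means over samples; recurrence histogram counts SNPs by
    the number of samples mismatching there and conserves totals."""
    calls_a = np.array([[0, 1, 2, 1],
                        [0, 1, 2, 1],
                        [0, 1, 2, 1]])
    calls_b = np.array([[0, 2, 2, 1],    # s1: 1 zygosity mismatch of 4
                        [0, 1, 2, 0],    # s2: v4 het->hom mismatch
                        [0, 2, 2, 0]])   # s3: v2 and v4
    a, b = _pair_datasets(calls_a, calls_b, populations=["p1", "p1", "p2"])
    rep = cross_platform_report(a, b)
    np.testing.assert_allclose(rep.per_sample["percent"], [25.0, 25.0, 50.0])
    assert rep.overall_mean == pytest.approx(100 / 3)
    assert rep.population_means["p1"] == pytest.approx(25.0)
    assert rep.population_means["p2"] == pytest.approx(50.0)
    rec = rep.recurrence
    # histogram sums: number of mismatching SNPs and total sample mismatches
    for pop, zyg in [("p1", calls_a[:2]), ("p2", calls_a[2:])]:
        sub = rec[rec["population"] == pop]
        assert (sub["n_snps"] * sub["k"]).sum() == \
            rep.per_sample.loc[rep.per_sample["population"] == pop, "n_mismatch"].sum()


def test_cross_platform_polarity_harmonized():
    """A record with swapped ref/alt is dosage-flipped before comparison."""
    a = make_dataset([[0, 2]])
    b = make_dataset([[0, 0]])
    b.variants.loc[1, ["ref", "alt"]] = ["G", "A"]  # swapped vs a
    rep = cross_platform_report(a, b)
    assert rep.overall_mean == 0.0


def test_array_error_rate_recovered_against_truth():
    """Array-vs-truth mismatch converges on the configured flip rate."""
    cfg = SimConfig(seed=31, n_pops=1, n_samples_per_pop=40, n_snps=2000)
    truth = simulate_populations(cfg)
    spec = PlatformSpec(array_error_rate=0.01, low_fld_error_mult=1.0,
                        fld_low_frac=0.0)
    arr, _ = simulate_platform_pair(truth, spec, seed=32)
    both = arr.calls != MISSING
    rate = (arr.calls != truth.calls)[both].mean()
    n = both.sum()
    sd = np.sqrt(0.01 * 0.99 / n)
    assert rate == pytest.approx(0.01, abs=2 * sd)


def test_filter_by_metrics_thresholds_and_monotonicity():
    """FLD < 6 SNPs are removed (strict threshold) and the post-filter
    mismatch rate drops below the pre-filter rate on a simulated pair."""
    cfg = SimConfig(seed=33, n_pops=2, n_samples_per_pop=9, n_snps=3000)
    truth = simulate_populations(cfg)
    arr, seq = simulate_platform_pair(truth, seed=34)
    ids, before, after = filter_by_metrics(arr, seq)
    assert len(ids) > 0
    assert after < before
    kept = np.isin(arr.base.variants["id"].to_numpy(), ids)
    assert (arr.fld[kept] >= 6).all()
    assert (arr.snp_call_rate[kept] >= 0.985).all()


def test_filter_by_metrics_all_passing_keeps_universe():
    ds = make_dataset(np.array([[0, 1], [2, 1]]))
    arr = chipqc.PlatformCallSet(base=ds, platform="array",
                                 fld=np.array([10.0, 9.0]))
    seq = chipqc.PlatformCallSet(
        base=make_dataset(np.array([[0, 1], [2, 1]])), platform="sequencing",
        depth=np.full((2, 2), 30, dtype=np.int32))
    ids, before, after = filter_by_metrics(arr, seq)
    assert list(ids) == ["v1", "v2"]


def test_mismatch_metric_correlation_cases():
    rng = np.random.default_rng(40)
    metric = rng.random(4000)
    # null: mismatches independent of the metric
    mm = rng.random(4000) < 0.1
    r, _ = mismatch_metric_correlation(mm, metric)
    assert abs(r) < 0.05
    # perfectly separated: all mismatches below the median
    mm = metric < np.median(metric)
    r, binned = mismatch_metric_correlation(mm, metric)
    # median split of a uniform metric: point-biserial -> -sqrt(3)/2
    assert r == pytest.approx(-np.sqrt(3) / 2, abs=0.02)
    assert (binned["mismatch_rate"].iloc[:5] == 1.0).all()
    assert (binned["mismatch_rate"].iloc[5:] == 0.0).all()
    # constant metric undefined
    r, _ = mismatch_metric_correlation(mm, np.ones(4000))
    assert np.isnan(r)


def test_depth_mismatch_correlation_negative():
    """Simulated pairs show depth-dependent het miscalls: negative
    point-biserial correlation between mismatch and read depth."""
    cfg = SimConfig(seed=35, n_pops=1, n_samples_per_pop=25, n_snps=1500)
    truth = simulate_populations(cfg)
    arr, seq = simulate_platform_pair(truth, seed=36)
    both = (arr.calls != MISSING) & (seq.calls != MISSING)
    mm = (arr.calls == 1) != (seq.calls == 1)
    r, _ = mismatch_metric_correlation(mm[both], seq.depth[both])
    assert r < -0.02
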