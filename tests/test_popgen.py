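"""Weir–Cockerham F_ST against an independent per-allele-sum oracle,
bootstrap calibration, distances, IBD regression and the Mantel test."""

import numpy as np
import pandas as pd
import pytest

from chipqc import (
    MISSING,
    SimConfig,
    geo_distance_km,
    ibd_regression,
    mantel_test,
    pairwise_fst_matrix,
    quasi_neutral_set,
    simulate_populations,
    site_distance_matrix,
    wc_fst,
)
from conftest import make_dataset


# -- independent WC84 oracle -------------------------------------------------
# Written from the general multi-allele formulation (components summed over
# both alleles and divided by two), a different algebraic route from the
# implementation's biallelic shortcut.

def wc_oracle_locus(pop_genotype_counts):
    """theta-hat for one locus from per-population (n0, n1, n2) counts."""
    pops = [c for c in pop_genotype_counts if sum(c) >= 2]
    r = len(pops)
    n_i = np.array([sum(c) for c in pops], dtype=float)
    nbar = n_i.mean()
    nc = (n_i.sum() - (n_i ** 2).sum() / n_i.sum()) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for allele in (0, 1):  # ref / alt
        if allele == 1:
            p_i = np.array([(c[1] + 2 * c[2]) / (2 * sum(c)) for c in pops])
        else:
            p_i = np.array([(c[1] + 2 * c[0]) / (2 * sum(c)) for c in pops])
        h_i = np.array([c[1] / sum(c) for c in pops])
        pbar = (n_i * p_i).sum() / (n_i.sum())
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / n_i.sum()
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum / 2, b_sum / 2, c_sum / 2


def _dataset_from_counts(pop_counts):
    """Build a 1-locus dataset from per-population genotype counts."""
    calls, pops = [], []
    for k, (n0, n1, n2) in enumerate(pop_counts):
        g = [0] * n0 + [1] * n1 + [2] * n2
        calls.extend(g)
        pops.extend([f"p{k}"] * len(g))
    return make_dataset(np.array(calls, dtype=np.int8).reshape(-1, 1),
                        populations=pops)


def test_wc_fst_toy_counts_match_oracle():
    """pop1 9/1/0, pop2 0/1/9 at one locus: theta from the hand-derived
    component values a=0.4025, b=0, c=0.05."""
    ds = _dataset_from_counts([(9, 1, 0), (0, 1, 9)])
    res = wc_fst(ds, n_boot=0)
    a, b, c = wc_oracle_locus([(9, 1, 0), (0, 1, 9)])
    assert res.overall == pytest.approx(a / (a + b + c), abs=1e-12)
    assert res.overall == pytest.approx(0.4025 / 0.4525, abs=1e-10)


def test_wc_fst_matches_oracle_random_configs():
    """Component-level agreement with the independent oracle to 1e-10 on
    random two- and three-population count configurations."""
    rng = np.random.default_rng(70)
    for _ in range(300):
        n_pops = rng.integers(2, 4)
        counts = [tuple(rng.integers(0, 15, size=3)) for _ in range(n_pops)]
        if any(sum(c) < 2 for c in counts):
            continue
        total_alt = sum(c[1] + 2 * c[2] for c in counts)
        total = sum(2 * sum(c) for c in counts)
        if total_alt == 0 or total_alt == total:
            continue  # monomorphic: skipped by both
        ds = _dataset_from_counts(counts)
        res = wc_fst(ds, n_boot=0)
        a, b, c = wc_oracle_locus(counts)
        assert res.per_locus["a"].iloc[0] == pytest.approx(a, abs=1e-10)
        assert res.per_locus["b"].iloc[0] == pytest.approx(b, abs=1e-10)
        assert res.per_locus["c"].iloc[0] == pytest.approx(c, abs=1e-10)


def test_wc_fst_extremes():
    """Identical frequencies -> ~0; fixed opposite alleles -> exactly 1."""
    rng = np.random.default_rng(71)
    cfg = SimConfig(seed=72, n_pops=2, n_samples_per_pop=100, n_snps=5000,
                    target_fst=0.0)
    assert abs(wc_fst(simulate_populations(cfg), n_boot=0).overall) < 0.01
    fixed = np.vstack([np.zeros((10, 50)), np.full((10, 50), 2)]).astype(np.int8)
    ds = make_dataset(fixed, populations=["p1"] * 10 + ["p2"] * 10)
    assert wc_fst(ds, n_boot=0).overall == pytest.approx(1.0)


@pytest.mark.parametrize("target", [0.05, 0.10, 0.20])
def test_wc_fst_recovers_balding_nichols_target(target):
    cfg = SimConfig(seed=int(target * 1000), n_pops=2, n_samples_per_pop=100,
                    n_snps=5000, target_fst=target)
    res = wc_fst(simulate_populations(cfg), n_boot=0)
    assert res.overall == pytest.approx(target, abs=0.02)


def test_bootstrap_ci_and_coverage():
    """Percentile CI contains the point estimate; across 200 scaled-down
    replicates the nominal-95% CI covers the target in [90%, 99%]."""
    cfg = SimConfig(seed=73, n_pops=2, n_samples_per_pop=25, n_snps=300,
                    target_fst=0.10)
    res = wc_fst(simulate_populations(cfg), n_boot=100, seed=1)
    assert res.ci[0] <= res.overall <= res.ci[1]
    assert res.p_value == 0.0  # clearly differentiated
    hits = 0
    for rep in range(200):
        cfg = SimConfig(seed=1000 + rep, n_pops=2, n_samples_per_pop=25,
                        n_snps=300, target_fst=0.10)
        r = wc_fst(simulate_populations(cfg), n_boot=100, seed=rep)
        hits += r.ci[0] <= 0.10 <= r.ci[1]
    assert 0.90 * 200 <= hits <= 0.99 * 200


def test_quasi_neutral_set():
    cats = ["intergenic"] * 6 + ["intron"] * 4
    ds = make_dataset(np.zeros((2, 10), dtype=np.int8), categories=cats)
    fst = np.array([0.0, 0.1, 0.2, 0.21, 0.5, 0.05, 0.0, 0.9, 0.1, 0.0])
    kept = quasi_neutral_set(ds, fst, "intergenic", 0.2)
    # intergenic loci with theta <= 0.2: v1, v2, v3 (boundary kept), v6
    assert list(kept) == ["v1", "v2", "v3", "v6"]


def test_geo_distance():
    assert geo_distance_km(10, 20, 10, 20) == 0.0
    # one degree of longitude at the equator: 2 pi R / 360
    assert geo_distance_km(0, 0, 0, 1) == pytest.approx(111.3195, abs=0.001)
    assert geo_distance_km(12, 34, -5, 67) == geo_distance_km(-5, 67, 12, 34)
    with pytest.raises(Exception):
        geo_distance_km(95, 0, 0, 0)


def test_ibd_regression_exact_and_null():
    sites = list("abcd")
    km = pd.DataFrame(0.0, index=sites, columns=sites)
    rng = np.random.default_rng(74)
    for i in range(4):
        for j in range(i + 1, 4):
            km.iloc[i, j] = km.iloc[j, i] = rng.uniform(50, 5000)
    slope, intercept = 0.013, -0.02
    fst_lin = km.copy()
    for i in range(4):
        for j in range(4):
            if i != j:
                y = slope * np.log(km.iloc[i, j]) + intercept
                fst_lin.iloc[i, j] = y / (1 + y)  # so fst/(1-fst) = y exactly
    fit = ibd_regression(fst_lin, km)
    assert fit["r_squared"] == pytest.approx(1.0)
    assert fit["slope"] == pytest.approx(slope, abs=1e-12)
    # independence: R^2 near 0 over many pairs
    n = 12
    sites = [f"s{i}" for i in range(n)]
    km = pd.DataFrame(0.0, index=sites, columns=sites)
    fst = pd.DataFrame(0.0, index=sites, columns=sites)
    for i in range(n):
        for j in range(i + 1, n):
            km.iloc[i, j] = km.iloc[j, i] = rng.uniform(10, 5000)
            fst.iloc[i, j] = fst.iloc[j, i] = rng.uniform(0.0, 0.3)
    assert ibd_regression(fst, km)["r_squared"] < 0.1


def _random_dist(n, seed):
    rng = np.random.default_rng(seed)
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


def test_mantel_perfect_and_invariance():
    d = _random_dist(6, 75)
    r, p = mantel_test(2 * d, d, n_perm=99, seed=1)
    assert r == pytest.approx(1.0)
    assert p == pytest.approx(1 / 100, abs=0.05)
    # consistent relabeling leaves r unchanged
    perm = np.random.default_rng(2).permutation(6)
    r2, _ = mantel_test(2 * d[np.ix_(perm, perm)], d[np.ix_(perm, perm)],
                        n_perm=9, seed=3)
    assert r2 == pytest.approx(r)


def test_mantel_null_p_uniform():
    """Independent matrices: permutation p-values are uniform on the
    achievable grid (checked with a KS statistic over repeated draws)."""
    from scipy import stats

    ps = []
    for rep in range(150):
        g = _random_dist(8, 500 + rep)
        d = _random_dist(8, 9000 + rep)
        _, p = mantel_test(g, d, n_perm=99, seed=rep)
        ps.append(p)
    ks = stats.kstest(ps, "uniform")
    assert ks.pvalue > 0.01


def test_site_distance_matrix_symmetry():
    coords = pd.DataFrame({"lat": [0.0, 0.0, 10.0], "lon": [0.0, 1.0, 1.0]},
                          index=["a", "b", "c"])
    m = site_distance_matrix(coords)
    assert (m.values == m.values.T).all()
    assert (np.diag(m.values) == 0).all()
    assert m.loc["a", "b"] == pytest.approx(111.3195, abs=0.001)


def test_pairwise_fst_matrix_properties():
    cfg = SimConfig(seed=76, n_pops=3, n_samples_per_pop=20, n_snps=800,
                    target_fst=0.1)
    ds = simulate_populations(cfg)
    m = pairwise_fst_matrix(ds)
    assert (m.values == m.values.T).all()
    assert (np.diag(m.values) == 0).all()
    assert ((m.values >= -0.05) & (m.values <= 1)).all()
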