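"""Population differentiation and isolation by distance.

Weir & Cockerham's (1984) variance-component F_ST estimator with unequal
sample sizes: per biallelic locus the components a (among populations),
b (among individuals within populations) and c (within individuals) are
computed from per-population allele frequencies and heterozygote
proportions; the overall estimate is the ratio of sums theta = sum(a) /
sum(a + b + c), negative per-locus values retained.  Uncertainty comes from
bootstrapping loci (100 replicates by default): percentile CI and a
bootstrap p for theta > 0 (fraction of replicates <= 0).

Isolation by distance: great-circle distances (haversine, R = 6378.137 km),
ordinary least squares of F_ST/(1 - F_ST) on log distance, and a one-sided
Mantel permutation test (rows and columns of one matrix permuted jointly;
p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, ChipQCError, GenotypeDataset, logger

__all__ = [
    "FstResult",
    "wc_fst",
    "pairwise_fst_matrix",
    "quasi_neutral_set",
    "geo_distance_km",
    "site_distance_matrix",
    "ibd_regression",
    "mantel_test",
]

EARTH_RADIUS_KM = 6378.137  # equatorial radius used by geosphere's haversine


@dataclass
class FstResult:
    """Per-locus WC84 variance components and the overall ratio-of-sums
    estimate, with loci-bootstrap replicates, CI and p for theta > 0."""

    per_locus: pd.DataFrame  # a, b, c, theta (nan where undefined)
    overall: float
    bootstrap: np.ndarray | None = None
    ci: tuple[float, float] | None = None
    p_value: float | None = None


def _wc_components(
    calls: np.ndarray, pop_rows: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """WC84 per-locus components a, b, c for >= 2 populations.

    Loci monomorphic across all populations (or with < 2 populations
    having >= 2 called samples) get nan components.
    """
    r_all = len(pop_rows)
    nv = calls.shape[1]
    n_i = np.zeros((r_all, nv))
    p_i = np.zeros((r_all, nv))
    h_i = np.zeros((r_all, nv))
    for k, rows in enumerate(pop_rows):
        sub = calls[rows, :]
        called = sub != MISSING
        n = called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        het = ((sub == 1) & called).sum(axis=0)
        n_i[k] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
            h_i[k] = np.where(n > 0, het / np.maximum(n, 1), np.nan)

    ok_pop = n_i >= 2
    r = ok_pop.sum(axis=0).astype(float)
    n_i = np.where(ok_pop, n_i, 0.0)
    p_i = np.where(ok_pop, p_i, 0.0)
    h_i = np.where(ok_pop, h_i, 0.0)
    n_sum = n_i.sum(axis=0)
    valid = r >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_sum / r
        nc = (n_sum - (n_i ** 2).sum(axis=0) / n_sum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / n_sum
        s2 = (n_i * (p_i - pbar[None, :]) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / n_sum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
    poly = valid & (pbar > 0) & (pbar < 1)
    a = np.where(poly, a, np.nan)
    b = np.where(poly, b, np.nan)
    c = np.where(poly, c, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    return a, b, c, theta


def wc_fst(
    dataset: GenotypeDataset,
    pop_labels: pd.Series | None = None,
    n_boot: int = 100,
    seed: int | None = None,
) -> FstResult:
    """Weir–Cockerham F_ST over all populations in the dataset.

    Monomorphic loci are skipped; the overall estimate is ratio-of-sums.
    ``n_boot`` loci-bootstrap replicates (resampling loci with replacement)
    give a percentile 95% CI and a p-value for differentiation (fraction of
    replicates <= 0).  Set ``n_boot=0`` to skip the bootstrap.
    """
    if pop_labels is None:
        pop_labels = dataset.populations()
    labels = np.asarray([pop_labels[s] for s in dataset.sample_ids])
    pops = pd.unique(labels)
    if len(pops) < 2:
        raise ChipQCError("need at least 2 populations")
    pop_rows = [np.flatnonzero(labels == p) for p in pops]
    if any(rows.size < 2 for rows in pop_rows):
        raise ChipQCError("every population needs at least 2 samples")
    a, b, c, theta = _wc_components(dataset.calls, pop_rows)
    per_locus = pd.DataFrame({
        "id": dataset.variants["id"], "a": a, "b": b, "c": c, "theta": theta,
    })
    use = ~np.isnan(a)
    if not use.any():
        raise ChipQCError("no polymorphic loci")
    overall = float(a[use].sum() / (a[use] + b[use] + c[use]).sum())
    boot = ci = p_val = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        au, bu, cu = a[use], b[use], c[use]
        m = au.size
        idx = rng.integers(0, m, size=(n_boot, m))
        num = au[idx].sum(axis=1)
        den = (au[idx] + bu[idx] + cu[idx]).sum(axis=1)
        boot = num / den
        ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
        p_val = float((boot <= 0).mean())
    return FstResult(per_locus=per_locus, overall=overall, bootstrap=boot,
                     ci=ci, p_value=p_val)


def pairwise_fst_matrix(
    dataset: GenotypeDataset, pop_labels: pd.Series | None = None
) -> pd.DataFrame:
    """Overall WC84 theta for every population pair (symmetric, 0 diagonal)."""
    if pop_labels is None:
        pop_labels = dataset.populations()
    labels = np.asarray([pop_labels[s] for s in dataset.sample_ids])
    pops = list(pd.unique(labels))
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            rows = [np.flatnonzero(labels == pops[i]),
                    np.flatnonzero(labels == pops[j])]
            a, b, c, _ = _wc_components(dataset.calls, rows)
            use = ~np.isnan(a)
            theta = float(a[use].sum() / (a[use] + b[use] + c[use]).sum()) \
                if use.any() else float("nan")
            mat.iloc[i, j] = mat.iloc[j, i] = theta
    return mat


def quasi_neutral_set(
    dataset: GenotypeDataset,
    fst_per_locus: np.ndarray | pd.Series,
    category: str = "intergenic",
    fst_max: float = 0.2,
) -> np.ndarray:
    """Ids of SNPs in ``category`` whose per-locus theta is <= ``fst_max``
    (strictly greater values are excluded as putatively selected)."""
    fst = np.asarray(fst_per_locus, dtype=float)
    if fst.shape[0] != dataset.n_snps:
        raise ChipQCError("fst_per_locus must align with the dataset's SNPs")
    in_cat = (dataset.variants["category"] == category).to_numpy()
    keep = in_cat & ~(fst > fst_max)
    return dataset.variants["id"].to_numpy()[keep]


def geo_distance_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine great-circle distance in km (Earth radius 6378.137 km)."""
    for lat in (lat1, lat2):
        if not -90 <= lat <= 90:
            raise ChipQCError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180 <= lon <= 180:
            raise ChipQCError("longitude outside [-180, 180]")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def site_distance_matrix(coords: pd.DataFrame) -> pd.DataFrame:
    """Pairwise great-circle km between sites (frame with lat/lon index by
    site); symmetric with zero diagonal."""
    sites = list(coords.index)
    mat = pd.DataFrame(0.0, index=sites, columns=sites)
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            d = geo_distance_km(coords["lat"].iloc[i], coords["lon"].iloc[i],
                                coords["lat"].iloc[j], coords["lon"].iloc[j])
            mat.iloc[i, j] = mat.iloc[j, i] = d
    return mat


def _upper(mat: pd.DataFrame | np.ndarray) -> np.ndarray:
    m = np.asarray(mat, dtype=float)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def ibd_regression(
    fst_matrix: pd.DataFrame, dist_matrix: pd.DataFrame
) -> dict[str, float]:
    """OLS of F_ST/(1 - F_ST) on natural-log km over unique site pairs.

    Zero-distance pairs are dropped (log undefined, logged).  Returns slope,
    intercept and R².
    """
    fst = _upper(fst_matrix)
    km = _upper(dist_matrix)
    ok = km > 0
    if (~ok).any():
        logger.info("ibd_regression: dropped %d zero-distance pairs", int((~ok).sum()))
    fst, km = fst[ok], km[ok]
    if fst.size < 3:
        raise ChipQCError("need at least 3 site pairs")
    y = fst / (1.0 - fst)
    x = np.log(km)
    fit = stats.linregress(x, y)
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "r_squared": float(fit.rvalue ** 2), "n_pairs": int(fst.size)}


def mantel_test(
    genetic: pd.DataFrame | np.ndarray,
    geographic: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """One-sided (greater) Mantel test between two distance matrices.

    r is the Pearson correlation of the upper triangles; the null permutes
    rows and columns of one matrix jointly; p = (1 + #{r_perm >= r_obs}) /
    (n_perm + 1), so the minimum p at 999 permutations is 1/1000.
    """
    g = np.asarray(genetic, dtype=float)
    d = np.asarray(geographic, dtype=float)
    if g.shape != d.shape or g.shape[0] != g.shape[1]:
        raise ChipQCError("matrices must be square and conformable")
    n = g.shape[0]
    if n < 4:
        raise ChipQCError("need at least 4 sites")
    x = _upper(g)
    if np.ptp(x) == 0 or np.ptp(_upper(d)) == 0:
        raise ChipQCError("constant matrix: Mantel r undefined")
    xc = x - x.mean()
    xc /= np.sqrt((xc ** 2).sum())
    iu = np.triu_indices(n, k=1)

    def _r(mat: np.ndarray) -> float:
        y = mat[iu]
        yc = y - y.mean()
        return float(xc @ yc / np.sqrt((yc ** 2).sum()))

    r_obs = _r(d)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _r(d[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return r_obs, p
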