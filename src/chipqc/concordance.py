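"""Agreement between technical replicates and between array and sequencing
calls: pairwise concordance, the mismatch taxonomy (reference allele /
alternative allele / zygosity), per-population aggregation, recurrence
tables, and quality-metric filtering/stratification.

The headline metric is the zygosity mismatch percent per sample over
co-called SNPs; population and overall means are unweighted arithmetic means
of per-sample percentages.  Allele polarity is harmonized before comparison
(a swapped ref/alt pair flips dosages, and the event is logged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, ChipQCError, GenotypeDataset, PlatformCallSet, logger

__all__ = [
    "MismatchReport",
    "pairwise_concordance",
    "replicate_error_rate",
    "classify_mismatch",
    "cross_platform_report",
    "filter_by_metrics",
    "mismatch_metric_correlation",
    "summarize_mismatch_percents",
]


def summarize_mismatch_percents(
    percents, populations=None
) -> tuple[pd.Series, float]:
    """Aggregate per-sample mismatch percents into per-population means and
    an overall mean, both unweighted arithmetic means of sample values."""
    pct = pd.Series(np.asarray(percents, dtype=float))
    if populations is None:
        pops = pd.Series(["all"] * len(pct))
    else:
        pops = pd.Series(list(populations))
    return pct.groupby(pops).mean(), float(pct.mean())


def pairwise_concordance(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Percent of co-called SNPs with identical genotype codes.

    MISSING in either vector is excluded from the denominator; with zero
    co-called SNPs the value is undefined and returned as nan.
    """
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape:
        raise ChipQCError("call vectors must share one SNP universe")
    both = (a != MISSING) & (b != MISSING)
    n = int(both.sum())
    if n == 0:
        return float("nan")
    return 100.0 * float((a[both] == b[both]).mean())


def replicate_error_rate(concordances_for_replicate) -> float:
    """Mean of ``100 - concordance`` over a replicate's pairwise comparisons."""
    c = np.asarray(concordances_for_replicate, dtype=float)
    if c.size == 0:
        raise ChipQCError("need at least one pairwise concordance")
    return float(np.mean(100.0 - c))


def classify_mismatch(record_a, record_b, call_a: int, call_b: int) -> set[str]:
    """Mismatch taxonomy for one locus compared across two call sets.

    ``record_*`` expose ``ref``/``alt`` (mapping or attribute access).
    Categories are independent: ``ref_allele`` iff the reference alleles
    differ, ``alt_allele`` iff the alternative alleles differ, ``zygosity``
    iff both calls are non-missing and het/hom status differs.
    """
    def _get(rec, key):
        return rec[key] if isinstance(rec, (dict, pd.Series)) else getattr(rec, key)

    out: set[str] = set()
    if _get(record_a, "ref") != _get(record_b, "ref"):
        out.add("ref_allele")
    if _get(record_a, "alt") != _get(record_b, "alt"):
        out.add("alt_allele")
    if call_a != MISSING and call_b != MISSING:
        if (call_a == 1) != (call_b == 1):
            out.add("zygosity")
    return out


@dataclass
class MismatchReport:
    """Per-sample and per-SNP disagreement tallies between two call sets."""

    per_sample: pd.DataFrame  # sample, population, n_co_called, n_mismatch, percent
    population_means: pd.Series
    overall_mean: float
    recurrence: pd.DataFrame  # population, k, n_snps, percent (of compared SNPs)
    taxonomy: dict[str, int]  # ref_allele / alt_allele record-level totals
    n_shared_snps: int


def _as_base(cs) -> GenotypeDataset:
    return cs.base if isinstance(cs, PlatformCallSet) else cs


def _harmonized_calls(
    a: GenotypeDataset, b: GenotypeDataset, shared_samples: list[str]
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Intersect SNP universes, align samples, flip swapped-polarity records."""
    ids_a = a.variants["id"]
    ids_b = b.variants["id"]
    shared = ids_a[ids_a.isin(set(ids_b))].to_numpy()
    if shared.size == 0:
        raise ChipQCError("no shared SNPs between call sets")
    sub_a = a.subset(samples=shared_samples, snps=shared)
    sub_b = b.subset(samples=shared_samples, snps=shared)
    va, vb = sub_a.variants, sub_b.variants
    swapped = ((va["ref"].to_numpy() == vb["alt"].to_numpy())
               & (va["alt"].to_numpy() == vb["ref"].to_numpy()))
    calls_b = sub_b.calls.copy()
    if swapped.any():
        logger.info("harmonized polarity of %d swapped records", int(swapped.sum()))
        flip = calls_b[:, swapped]
        flip[flip != MISSING] = 2 - flip[flip != MISSING]
        calls_b[:, swapped] = flip
    return sub_a.calls, calls_b, va, vb, shared, swapped


def cross_platform_report(
    set_a, set_b, shared_samples: list[str] | None = None,
    populations: pd.Series | None = None,
) -> MismatchReport:
    """Zygosity-mismatch report between two call sets over shared samples.

    Per-sample mismatch percents are over co-called SNPs; population and
    overall means are unweighted means of member-sample percents.  The
    recurrence table counts SNPs mismatching in exactly ``k`` samples per
    population (percent relative to compared SNPs); record-level ref/alt
    allele disagreements are tallied separately.
    """
    base_a, base_b = _as_base(set_a), _as_base(set_b)
    if shared_samples is None:
        shared_samples = [s for s in base_a.sample_ids if s in set(base_b.sample_ids)]
    if not shared_samples:
        raise ChipQCError("need at least one shared sample")
    if populations is None:
        if base_a.sample_meta is not None and "population" in base_a.sample_meta:
            populations = base_a.sample_meta["population"]
        else:
            populations = pd.Series("all", index=shared_samples)
    calls_a, calls_b, va, vb, shared, swapped = _harmonized_calls(
        base_a, base_b, shared_samples
    )
    both = (calls_a != MISSING) & (calls_b != MISSING)
    zyg_mm = both & ((calls_a == 1) != (calls_b == 1))
    n_co = both.sum(axis=1)
    n_mm = zyg_mm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_co > 0, 100.0 * n_mm / n_co, np.nan)
    per_sample = pd.DataFrame({
        "sample": shared_samples,
        "population": [populations.get(s, "all") for s in shared_samples],
        "n_co_called": n_co,
        "n_mismatch": n_mm,
        "percent": pct,
    })
    pop_means, overall = summarize_mismatch_percents(
        per_sample["percent"], per_sample["population"])

    rec_rows = []
    pops = per_sample["population"].to_numpy()
    for pop in pd.unique(pops):
        rows = pops == pop
        k_per_snp = zyg_mm[rows, :].sum(axis=0)
        for k in range(1, rows.sum() + 1):
            n_snps_k = int((k_per_snp == k).sum())
            rec_rows.append((pop, k, n_snps_k, 100.0 * n_snps_k / shared.size))
    recurrence = pd.DataFrame(rec_rows, columns=["population", "k", "n_snps", "percent"])

    # record-level allele disagreements (positions with differing ref/alt)
    taxonomy = {
        "ref_allele": int((va["ref"].to_numpy() != vb["ref"].to_numpy())[~swapped].sum()),
        "alt_allele": int((va["alt"].to_numpy() != vb["alt"].to_numpy())[~swapped].sum()),
        "zygosity": int(zyg_mm.sum()),
    }
    return MismatchReport(
        per_sample=per_sample,
        population_means=pop_means,
        overall_mean=overall,
        recurrence=recurrence,
        taxonomy=taxonomy,
        n_shared_snps=int(shared.size),
    )


def filter_by_metrics(
    set_array: PlatformCallSet,
    set_seq: PlatformCallSet,
    fld_min: float = 6.0,
    call_rate_min: float = 0.985,
    depth_min: int = 20,
    shared_samples: list[str] | None = None,
) -> tuple[np.ndarray, float, float]:
    """Retain SNPs with FLD >= ``fld_min``, array call rate >=
    ``call_rate_min`` and per-call read depth >= ``depth_min`` in every
    compared sample.  Returns ``(retained ids, mismatch % before, after)``.
    """
    if set_array.fld is None:
        raise ChipQCError("array call set lacks FLD")
    if set_seq.depth is None:
        raise ChipQCError("sequencing call set lacks per-call depth")
    if shared_samples is None:
        shared_samples = [s for s in set_array.base.sample_ids
                          if s in set(set_seq.base.sample_ids)]
    seq_ids = set_seq.base.variants["id"]
    lookup = {v: i for i, v in enumerate(seq_ids)}
    arr_ids = set_array.base.variants["id"].to_numpy()
    in_both = np.array([v in lookup for v in arr_ids])
    seq_idx = np.array([lookup[v] for v in arr_ids[in_both]], dtype=int)
    s_rows = [set_seq.base.sample_ids.index(s) for s in shared_samples]
    depth_ok_shared = (set_seq.depth[np.ix_(s_rows, seq_idx)] >= depth_min).all(axis=0)
    keep = in_both.copy()
    keep[in_both] &= depth_ok_shared
    keep &= (set_array.fld >= fld_min) & (set_array.snp_call_rate >= call_rate_min)
    retained = arr_ids[keep]
    if retained.size == 0:
        logger.warning("filter_by_metrics: thresholds removed every SNP")
    before = cross_platform_report(set_array, set_seq, shared_samples).overall_mean
    after = float("nan")
    if retained.size:
        after = cross_platform_report(
            set_array.subset_snps(retained), set_seq.subset_snps(retained),
            shared_samples,
        ).overall_mean
    return retained, before, after


def mismatch_metric_correlation(
    mismatch, metric, n_bins: int = 10
) -> tuple[float, pd.DataFrame]:
    """Point-biserial correlation between a mismatch indicator and a quality
    metric, plus the mismatch rate per metric decile.  A constant metric
    yields nan (undefined).
    """
    y = np.asarray(mismatch, dtype=float).reshape(-1)
    x = np.asarray(metric, dtype=float).reshape(-1)
    if y.shape != x.shape:
        raise ChipQCError("mismatch and metric must align")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(x, y).statistic)
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    which = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        rows.append((edges[b], edges[b + 1], int(sel.sum()),
                     float(y[sel].mean()) if sel.any() else float("nan")))
    binned = pd.DataFrame(rows, columns=["lo", "hi", "n", "mismatch_rate"])
    return r, binned
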