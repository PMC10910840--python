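"""Wild-sample quality-control cascade.

Six steps in order: locus missingness, sample missingness, per-population
Hardy–Weinberg exact tests, MAF, heterozygosity outliers, and
relatedness-based duplicate removal via the KING-robust kinship estimator
(Manichaikul et al. 2010), whose canonical duplicate cutoff 0.354 ~ 2^(-3/2).

The HWE p-value is the standard (not mid-p) exact conditional test: all
heterozygote counts compatible with the observed allele counts are
enumerated with weight ``n! / (nAA! nAa! naa!) * 2^nAa``, and the p-value is
the summed probability of configurations no more probable than the observed
one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core_io import MISSING, ChipQCError, GenotypeDataset, logger

__all__ = [
    "QCThresholds",
    "QCReport",
    "hwe_exact_test",
    "individual_heterozygosity_outliers",
    "pairwise_kinship",
    "apply_qc",
]


@dataclass
class QCThresholds:
    """Wild-sample QC thresholds (defaults: 10% locus / 20% sample
    missingness, HWE p 1e-5 per population, MAF 10%, +-4 SD heterozygosity,
    kinship 0.354)."""

    locus_missing_max: float = 0.10
    sample_missing_max: float = 0.20
    hwe_p_min: float = 1e-5
    maf_min: float = 0.10
    het_sd: float = 4.0
    kinship_max: float = 0.354

    def __post_init__(self) -> None:
        for name in ("locus_missing_max", "sample_missing_max", "maf_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ChipQCError(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.hwe_p_min <= 1.0):
            raise ChipQCError("hwe_p_min must lie in [0, 1]")
        if self.het_sd <= 0 or self.kinship_max <= 0:
            raise ChipQCError("het_sd and kinship_max must be positive")


def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact conditional Hardy–Weinberg test p-value.

    Enumerate every heterozygote count with the parity allowed by the
    observed allele counts, weight by ``n!/(nAA! nAa! naa!) * 2^nAa``,
    normalize, and sum the probabilities of configurations whose probability
    does not exceed the observed one (small tolerance for float ties).
    A monomorphic locus returns 1.
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise ChipQCError("genotype counts must be non-negative")
    n = n_homref + n_het + n_homalt
    if n == 0:
        raise ChipQCError("need at least one genotype")
    n_a = 2 * n_homref + n_het  # ref-allele count
    n_b = 2 * n_homalt + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    het_min = n_a % 2
    het_max = min(n_a, n_b)
    hets = np.arange(het_min, het_max + 1, 2)
    homref = (n_a - hets) // 2
    homalt = (n_b - hets) // 2
    logw = (gammaln(n + 1) - gammaln(homref + 1) - gammaln(hets + 1)
            - gammaln(homalt + 1) + hets * np.log(2.0))
    logw -= logw.max()
    w = np.exp(logw)
    probs = w / w.sum()
    obs = np.searchsorted(hets, n_het)
    p_obs = probs[obs]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def individual_heterozygosity_outliers(
    dataset: GenotypeDataset, het_sd: float = 4.0
) -> np.ndarray:
    """Samples whose het-call fraction deviates more than ``het_sd`` sample
    standard deviations from the mean of all samples.  Returns sample ids."""
    if dataset.n_samples < 3:
        raise ChipQCError("need at least 3 samples")
    het = dataset.het_fraction()
    mean = np.nanmean(het)
    sd = np.nanstd(het, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.array([], dtype=object)
    flagged = np.abs(het - mean) > het_sd * sd
    return np.asarray(dataset.sample_ids, dtype=object)[flagged]


def pairwise_kinship(dataset: GenotypeDataset, kinship_max: float | None = None) -> pd.DataFrame:
    """KING-robust kinship for every sample pair.

    phi = (N_het,het - 2 * N_opposite_hom) / (N_het_i + N_het_j) over
    co-called SNPs; ~0.5 for duplicates, ~0.25 first-degree, ~0 unrelated.
    Pairs with no co-called SNPs get nan.  When ``kinship_max`` is given, a
    ``flagged`` column marks pairs above it and ``remove`` names the member
    with higher missingness.
    """
    if dataset.n_samples < 2:
        raise ChipQCError("need at least 2 samples")
    calls = dataset.calls
    called = calls != MISSING
    het = calls == 1
    miss = dataset.sample_missingness()
    ids = dataset.sample_ids
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            both = called[i] & called[j]
            n_hh = int((het[i] & het[j] & both).sum())
            opp = ((calls[i] == 0) & (calls[j] == 2)) | ((calls[i] == 2) & (calls[j] == 0))
            n_opp = int((opp & both).sum())
            n_het_i = int((het[i] & both).sum())
            n_het_j = int((het[j] & both).sum())
            denom = n_het_i + n_het_j
            phi = (n_hh - 2.0 * n_opp) / denom if denom > 0 else float("nan")
            if not both.any():
                phi = float("nan")
            rows.append((ids[i], ids[j], int(both.sum()), phi))
    out = pd.DataFrame(rows, columns=["sample_i", "sample_j", "n_co_called", "kinship"])
    if kinship_max is not None:
        out["flagged"] = out["kinship"] > kinship_max
        out["remove"] = [
            (r.sample_i if miss[ids.index(r.sample_i)] >= miss[ids.index(r.sample_j)]
             else r.sample_j) if r.flagged else None
            for r in out.itertuples()
        ]
    return out


@dataclass
class QCReport:
    """Per-stage removal counts and ids, in application order."""

    stages: pd.DataFrame  # stage, axis, removed, removed_ids

    def to_tsv(self, path: str) -> None:
        df = self.stages.copy()
        df["removed_ids"] = df["removed_ids"].map(lambda ids: ",".join(map(str, ids)))
        df.to_csv(path, sep="\t", index=False)


def _hwe_fail_any_population(ds: GenotypeDataset, p_min: float) -> np.ndarray:
    """Loci failing the exact HWE test (p < p_min) in any population."""
    pops = ds.populations()
    fail = np.zeros(ds.n_snps, dtype=bool)
    for pop in pops.unique():
        rows = (pops == pop).to_numpy()
        sub = ds.calls[rows, :]
        for j in range(ds.n_snps):
            col = sub[:, j]
            col = col[col != MISSING]
            if col.size == 0:
                continue
            p = hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()),
                               int((col == 2).sum()))
            if p < p_min:
                fail[j] = True
    return fail


def apply_qc(
    dataset: GenotypeDataset, thresholds: QCThresholds | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Run the six-step QC cascade in order; deterministic and idempotent.

    Steps: locus missingness > threshold; sample missingness; HWE exact test
    failing in any population; MAF; heterozygosity outliers; kinship-flagged
    duplicates (the higher-missingness member of each pair is removed).
    Population labels are required for the HWE step.
    """
    thr = thresholds or QCThresholds()
    ds = dataset
    rows = []

    def _record(stage, axis, removed_ids):
        rows.append((stage, axis, len(removed_ids), list(removed_ids)))

    def _check(stage):
        if ds.n_snps == 0 or ds.n_samples == 0:
            raise ChipQCError(f"QC cascade emptied the dataset at stage {stage!r}")

    # 1. locus missingness
    keep = ds.snp_missingness() <= thr.locus_missing_max
    _record("locus_missingness", "snp", ds.variants["id"].to_numpy()[~keep])
    ds = ds.subset(snps=keep)
    _check("locus_missingness")
    # 2. sample missingness
    keep_s = ds.sample_missingness() <= thr.sample_missing_max
    _record("sample_missingness", "sample",
            np.asarray(ds.sample_ids, dtype=object)[~keep_s])
    ds = ds.subset(samples=keep_s)
    _check("sample_missingness")
    # 3. HWE per population (fail in any population)
    fail = _hwe_fail_any_population(ds, thr.hwe_p_min)
    _record("hwe", "snp", ds.variants["id"].to_numpy()[fail])
    ds = ds.subset(snps=~fail)
    _check("hwe")
    # 4. MAF
    maf = ds.maf()
    keep_maf = np.nan_to_num(maf, nan=-1.0) >= thr.maf_min
    _record("maf", "snp", ds.variants["id"].to_numpy()[~keep_maf])
    ds = ds.subset(snps=keep_maf)
    _check("maf")
    # 5. heterozygosity outliers
    het_out = individual_heterozygosity_outliers(ds, thr.het_sd) \
        if ds.n_samples >= 3 else np.array([], dtype=object)
    _record("het_outliers", "sample", het_out)
    if het_out.size:
        keep_mask = ~np.isin(np.asarray(ds.sample_ids, dtype=object), het_out)
        ds = ds.subset(samples=keep_mask)
    _check("het_outliers")
    # 6. kinship duplicates
    kin = pairwise_kinship(ds, kinship_max=thr.kinship_max)
    remove = sorted({r for r in kin.loc[kin["flagged"], "remove"] if r is not None})
    _record("kinship", "sample", remove)
    if remove:
        keep_mask = ~np.isin(np.asarray(ds.sample_ids, dtype=object), remove)
        ds = ds.subset(samples=keep_mask)
    _check("kinship")

    report = QCReport(stages=pd.DataFrame(
        rows, columns=["stage", "axis", "removed", "removed_ids"]
    ))
    if report.stages["removed"].sum():
        logger.info("QC removed %d items across %d stages",
                    int(report.stages["removed"].sum()), len(rows))
    return ds, report
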