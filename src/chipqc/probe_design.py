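"""Candidate-SNP selection for probe tiling: filter, space, allocate.

The discovery set is reduced in three stages: (1) missingness/MAF filters
(samples first, then SNP missingness, then MAF — conventional plink
ordering), (2) a greedy within-scaffold spacing scan that keeps coding-region
SNPs at least ``min_gap_bp`` apart (boundary inclusive), and (3) allocation
of the tiling budget across functional categories by a numeric ranking key
(the simulator's random ``score`` stands in for a proprietary probe-
performance metric).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ChipQCError, GenotypeDataset, logger

__all__ = [
    "DesignCriteria",
    "DesignReport",
    "filter_candidates",
    "enforce_spacing",
    "allocate_by_category",
]


@dataclass
class DesignCriteria:
    """Probe-design thresholds: MAF >= 10%, missingness <= 10% for SNPs and
    samples, and a 200-bp minimum gap between coding-region SNPs."""

    maf_min: float = 0.10
    snp_missing_max: float = 0.10
    sample_missing_max: float = 0.10
    min_gap_bp: int = 200
    category_targets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_gap_bp < 0:
            raise ChipQCError("min_gap_bp must be >= 0")
        if self.category_targets:
            vals = np.array(list(self.category_targets.values()))
            if (vals < 0).any() or (vals > 1).any() or vals.sum() > 1 + 1e-9:
                raise ChipQCError("category targets must be fractions summing <= 1")


@dataclass
class DesignReport:
    """Counts removed per stage, in application order."""

    stages: pd.DataFrame  # columns: stage, removed, remaining

    def to_tsv(self, path: str) -> None:
        self.stages.to_csv(path, sep="\t", index=False)


def filter_candidates(
    dataset: GenotypeDataset, criteria: DesignCriteria | None = None
) -> tuple[GenotypeDataset, DesignReport]:
    """Remove high-missingness samples, then high-missingness SNPs, then
    low-MAF SNPs (MAF on non-missing calls).  Idempotent by construction."""
    crit = criteria or DesignCriteria()
    rows = []
    keep_samples = dataset.sample_missingness() <= crit.sample_missing_max
    rows.append(("sample_missingness", int((~keep_samples).sum())))
    ds = dataset.subset(samples=keep_samples)
    keep_snps = ds.snp_missingness() <= crit.snp_missing_max
    rows.append(("snp_missingness", int((~keep_snps).sum())))
    ds = ds.subset(snps=keep_snps)
    maf = ds.maf()
    keep_maf = np.nan_to_num(maf, nan=-1.0) >= crit.maf_min
    rows.append(("maf", int((~keep_maf).sum())))
    ds = ds.subset(snps=keep_maf)
    if ds.n_snps == 0 or ds.n_samples == 0:
        logger.warning("filter_candidates: empty result")
    report = pd.DataFrame(rows, columns=["stage", "removed"])
    report["remaining"] = [
        dataset.n_samples - report["removed"][0],
        dataset.n_snps - report["removed"][1],
        dataset.n_snps - report["removed"][1] - report["removed"][2],
    ]
    return ds, DesignReport(stages=report)


def enforce_spacing(
    variants: pd.DataFrame, min_gap_bp: int, region_mask: np.ndarray | None = None
) -> np.ndarray:
    """Greedy left-to-right spacing scan per scaffold.

    Within the mask, a SNP is kept iff its position is at least
    ``min_gap_bp`` from the last kept in-mask SNP on the same scaffold
    (gap >= min_gap_bp: the boundary is inclusive).  SNPs outside the mask
    are unaffected and do not reset the gap.  Unsorted input is sorted
    internally (stable); returns the retained SNP ids in input order.
    """
    if region_mask is None:
        region_mask = np.ones(len(variants), dtype=bool)
    region_mask = np.asarray(region_mask, dtype=bool)
    keep = np.ones(len(variants), dtype=bool)
    order = np.lexsort((np.arange(len(variants)), variants["pos"].to_numpy()))
    pos = variants["pos"].to_numpy()
    chrom = variants["chrom"].to_numpy()
    last_kept: dict[str, int] = {}
    for i in order:
        if not region_mask[i]:
            continue
        prev = last_kept.get(chrom[i])
        if prev is not None and pos[i] - prev < min_gap_bp:
            keep[i] = False
        else:
            last_kept[chrom[i]] = pos[i]
    return variants["id"].to_numpy()[keep]


def allocate_by_category(
    candidates: pd.DataFrame,
    category_targets: dict[str, float],
    ranking_key: str,
    total_n: int,
) -> np.ndarray:
    """Pick ``total_n`` SNPs split across categories by target fraction.

    Per category the top ``round(total_n * fraction)`` candidates by
    ``ranking_key`` (descending) are taken; when a category is exhausted
    the deficit is redistributed proportionally among categories that still
    have spare candidates.  Returns the selected ids.
    """
    if total_n < 0:
        raise ChipQCError("total_n must be >= 0")
    if total_n == 0:
        return np.array([], dtype=candidates["id"].dtype)
    if candidates["category"].isna().any():
        raise ChipQCError("every candidate must be categorized")
    n_avail = len(candidates)
    if total_n > n_avail:
        logger.warning("allocate_by_category: requested %d > %d candidates; "
                       "returning all", total_n, n_avail)
        return candidates["id"].to_numpy().copy()
    groups = {
        cat: grp.sort_values(ranking_key, ascending=False, kind="stable")
        for cat, grp in candidates.groupby("category", sort=False)
        if cat in category_targets
    }
    frac = {cat: category_targets[cat] for cat in groups}
    quota = {cat: int(round(total_n * f)) for cat, f in frac.items()}
    taken: dict[str, int] = {cat: 0 for cat in groups}
    # iterative redistribution of deficits from exhausted categories
    while True:
        deficit = 0
        open_cats = []
        for cat, grp in groups.items():
            want = quota[cat]
            have = len(grp)
            if want > have:
                deficit += want - have
                quota[cat] = have
            elif want < have:
                open_cats.append(cat)
        if deficit == 0 or not open_cats:
            break
        weights = np.array([frac[c] for c in open_cats], dtype=float)
        weights = weights / weights.sum()
        extra = np.floor(deficit * weights).astype(int)
        rem = deficit - extra.sum()
        # leftover seats by largest fractional share, ties by listed order
        remainders = deficit * weights - extra
        for k in np.argsort(-remainders, kind="stable")[:rem]:
            extra[k] += 1
        for c, e in zip(open_cats, extra):
            quota[c] += int(e)
    selected = [grp.head(quota[cat])["id"].to_numpy() for cat, grp in groups.items()]
    return np.concatenate(selected) if selected else np.array([], dtype=object)
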