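"""Functional-category representation bias and proportion-matched subsampling.

An array designed to over-represent coding regions does not carry the same
mix of intronic / intergenic / synonymous / non-synonymous / UTR SNPs as the
sequencing data it was designed from.  This module quantifies that bias
(chip percent minus reference percent per category) and constructs the
largest chip subsample whose category proportions match the reference
percentages, consumed at two-decimal precision:

    N_total = floor(min_c count_c / p_c)

with per-category seats ``n_c`` assigned by largest-remainder rounding so
they sum exactly to ``N_total`` (ties broken by category listing order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import ChipQCError, GenotypeDataset

__all__ = [
    "CategoryCounts",
    "percent",
    "category_percents",
    "bias_percent",
    "max_matched_subsample",
    "draw_matched_sets",
    "shared_fraction",
]

#: canonical category listing order (used for deterministic tie-breaks)
CATEGORY_ORDER = ("intron", "intergenic", "synonymous", "non_synonymous",
                  "utr5", "utr3")


def percent(count: int, total: int, decimals: int = 2) -> float:
    """Percentage at the reporting precision (2 decimals by convention)."""
    if total <= 0:
        raise ChipQCError("total must be positive")
    return round(100.0 * count / total, decimals)


@dataclass
class CategoryCounts:
    """SNP counts per functional category with derived percentages."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ChipQCError("counts must be non-negative")

    @classmethod
    def from_dataset(cls, dataset: GenotypeDataset) -> "CategoryCounts":
        vc = dataset.variants["category"].value_counts()
        return cls(counts={cat: int(vc.get(cat, 0)) for cat in CATEGORY_ORDER})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percents(self) -> dict[str, float]:
        return category_percents(self.counts)

    def fractions(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            raise ChipQCError("total is zero")
        return {c: n / t for c, n in self.counts.items()}


def category_percents(counts: dict[str, int], decimals: int = 2) -> dict[str, float]:
    """Per-category percentages, rounded to 2 decimals for reporting."""
    total = sum(counts.values())
    if total <= 0:
        raise ChipQCError("total count must be positive")
    return {c: percent(n, total, decimals) for c, n in counts.items()}


def bias_percent(chip_percent: float, wgs_percent: float) -> float:
    """Chip minus reference percentage points, 2-decimal report."""
    if not (0 <= chip_percent <= 100 and 0 <= wgs_percent <= 100):
        raise ChipQCError("percents must lie in [0, 100]")
    return round(chip_percent - wgs_percent, 2)


def max_matched_subsample(
    chip_counts: dict[str, int], target_percents_2dp: dict[str, float]
) -> tuple[dict[str, int], int]:
    """Largest chip subsample matching the target category proportions.

    ``target_percents_2dp`` are the reference percentages at two-decimal
    precision expressed as fractions (e.g. 0.3475).  The total is the floor
    of the binding ratio ``count_c / p_c``; seats are floor allocations
    topped up by largest fractional remainder (ties broken by the order
    categories are listed) so they sum exactly to the total, and never
    exceed the available count.  Categories with a zero target are excluded.
    """
    cats = [c for c in target_percents_2dp if target_percents_2dp[c] > 0]
    if not cats:
        return {}, 0
    for c in cats:
        if c not in chip_counts:
            raise ChipQCError(f"no chip count for category {c!r}")
    n_total = min(math.floor(chip_counts[c] / target_percents_2dp[c]) for c in cats)
    if n_total <= 0:
        return {c: 0 for c in cats}, 0
    exact = {c: n_total * target_percents_2dp[c] for c in cats}
    alloc = {c: math.floor(exact[c]) for c in cats}
    short = n_total - sum(alloc.values())
    remainders = sorted(
        cats, key=lambda c: (-(exact[c] - alloc[c]), cats.index(c))
    )
    for c in remainders[:short]:
        alloc[c] += 1
    for c in cats:  # guaranteed by n_total's construction; assert the contract
        if alloc[c] > chip_counts[c]:
            raise ChipQCError("allocation exceeded available count")
    return alloc, n_total


def draw_matched_sets(
    pool: dict[str, np.ndarray] | GenotypeDataset,
    allocation: dict[str, int],
    k_sets: int,
    seed: int,
) -> list[np.ndarray]:
    """Draw ``k_sets`` SNP-id sets without replacement within category."""
    if isinstance(pool, GenotypeDataset):
        ids = pool.variants["id"].to_numpy()
        cats = pool.variants["category"].to_numpy()
        pool = {c: ids[cats == c] for c in allocation}
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(k_sets):
        parts = []
        for c, n in allocation.items():
            avail = np.asarray(pool[c])
            if n > avail.size:
                raise ChipQCError(f"allocation for {c!r} exceeds pool")
            parts.append(rng.choice(avail, size=n, replace=False))
        out.append(np.concatenate(parts) if parts else np.array([], dtype=object))
    return out


def shared_fraction(sets: list[np.ndarray]) -> float:
    """Percent of ids present in every set, relative to the set size."""
    if not sets:
        raise ChipQCError("need at least one set")
    inter = set(sets[0])
    for s in sets[1:]:
        inter &= set(s)
    size = len(sets[0])
    if size == 0:
        raise ChipQCError("sets must be non-empty")
    return 100.0 * len(inter) / size
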