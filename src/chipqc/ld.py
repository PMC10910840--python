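"""Chromosome-scale coordinates, pairwise r², LD-decay curves, half-distance
and r²-threshold pruning.

r² is the composite (genotype-dosage) squared Pearson correlation, the
appropriate statistic for unphased calls.  The half-distance is defined on
the binned-mean decay curve: the smallest distance, by linear interpolation
between adjacent bin midpoints, where the curve first falls to half its
maximum binned mean and stays below for the next bin.  Scanning starts at
the maximum because the "original" r² at distance 0 is unobservable; a
curve that never crosses reports infinity (beyond the curve's reach).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MISSING, ChipQCError, GenotypeDataset, ScaffoldOrder, logger

__all__ = [
    "ChromosomeScale",
    "LDCurve",
    "chromosome_scale",
    "pairwise_r2",
    "ld_decay_curve",
    "half_distance",
    "ld_prune",
]


@dataclass
class ChromosomeScale:
    """Cumulative scaffold offsets per chromosome, in assembly order."""

    offsets: dict[str, tuple[str, int]]  # scaffold -> (chromosome, offset bp)

    def map_position(self, scaffold: str, pos: int) -> tuple[str, int]:
        """Chromosome-scale coordinate of a 1-based scaffold position."""
        if scaffold not in self.offsets:
            raise ChipQCError(f"unknown scaffold {scaffold!r}")
        chrom, off = self.offsets[scaffold]
        return chrom, off + pos

    def apply(self, dataset: GenotypeDataset) -> GenotypeDataset:
        """Return a copy with chrom/pos rewritten onto the chromosome scale."""
        mapped = [self.map_position(c, p) for c, p in
                  zip(dataset.variants["chrom"], dataset.variants["pos"])]
        variants = dataset.variants.copy()
        variants["chrom"] = [m[0] for m in mapped]
        variants["pos"] = [m[1] for m in mapped]
        return GenotypeDataset(list(dataset.sample_ids), variants,
                               dataset.calls.copy(), dataset.sample_meta)


def chromosome_scale(scaffold_order: ScaffoldOrder) -> ChromosomeScale:
    """Build per-scaffold offsets by cumulative length within chromosome."""
    offsets: dict[str, tuple[str, int]] = {}
    running: dict[str, int] = {}
    for scaffold, length, chrom in scaffold_order.scaffolds:
        offsets[scaffold] = (chrom, running.get(chrom, 0))
        running[chrom] = running.get(chrom, 0) + length
    return ChromosomeScale(offsets=offsets)


def pairwise_r2(dosages_i: np.ndarray, dosages_j: np.ndarray) -> float:
    """Squared Pearson correlation of dosage vectors over co-called samples.

    Undefined (nan) with fewer than 2 co-called samples or zero variance.
    """
    x = np.asarray(dosages_i, dtype=float)
    y = np.asarray(dosages_j, dtype=float)
    both = (x != MISSING) & (y != MISSING)
    x, y = x[both], y[both]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class LDCurve:
    """Binned mean r² against inter-SNP distance for one chromosome."""

    bin_edges: np.ndarray  # len n_bins + 1, contiguous from 0 to max_dist
    mean_r2: np.ndarray  # len n_bins, nan where no pairs
    pair_count: np.ndarray  # len n_bins
    max_dist: int
    bin_width: int

    @property
    def midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo": self.bin_edges[:-1], "bin_hi": self.bin_edges[1:],
            "mean_r2": self.mean_r2, "n_pairs": self.pair_count,
        })


def ld_decay_curve(
    dataset: GenotypeDataset,
    max_dist: int = 500_000,
    bin_width: int = 1_000,
    maf_min: float = 0.01,
    miss_max: float = 0.20,
    min_samples: int = 6,
) -> dict[str, LDCurve]:
    """Per-chromosome decay curve of mean r² by distance bin.

    SNPs pass a light screen (MAF >= ``maf_min``, missingness <=
    ``miss_max``); every within-chromosome pair at distance <= ``max_dist``
    contributes its composite r² to its bin.
    """
    if dataset.n_samples < min_samples:
        raise ChipQCError(f"need at least {min_samples} samples")
    keep = (np.nan_to_num(dataset.maf(), nan=-1) >= maf_min) \
        & (dataset.snp_missingness() <= miss_max)
    ds = dataset.subset(snps=keep)
    n_bins = int(np.ceil(max_dist / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    curves: dict[str, LDCurve] = {}
    for chrom in pd.unique(ds.variants["chrom"]):
        sel = (ds.variants["chrom"] == chrom).to_numpy()
        pos = ds.variants["pos"].to_numpy()[sel]
        calls = ds.calls[:, sel]
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        calls = calls[:, order].astype(float)
        calls[calls == MISSING] = np.nan
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, dtype=int)
        m = pos.size
        for a in range(m):
            hi = np.searchsorted(pos, pos[a] + max_dist, side="right")
            for b in range(a + 1, hi):
                d = pos[b] - pos[a]
                x, y = calls[:, a], calls[:, b]
                both = ~np.isnan(x) & ~np.isnan(y)
                xs, ys = x[both], y[both]
                if xs.size < 2 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
                    continue
                r = np.corrcoef(xs, ys)[0, 1]
                b_idx = min(int(d // bin_width), n_bins - 1)
                sums[b_idx] += r * r
                counts[b_idx] += 1
        if counts.sum() == 0:
            logger.warning("ld_decay_curve: no qualifying pairs on %s", chrom)
        with np.errstate(invalid="ignore"):
            mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        curves[chrom] = LDCurve(bin_edges=edges, mean_r2=mean,
                                pair_count=counts, max_dist=max_dist,
                                bin_width=bin_width)
    return curves


def half_distance(curve: LDCurve) -> float:
    """Distance at which the binned mean r² first falls to half its maximum.

    Linear interpolation between adjacent non-empty bin midpoints; the
    crossing must hold in the following non-empty bin too (a one-bin dip
    does not count).  Returns ``inf`` when the curve never reaches half
    (e.g. a constant or monotone-increasing curve).
    """
    filled = np.flatnonzero(curve.pair_count > 0)
    if filled.size == 0:
        raise ChipQCError("curve is empty")
    mids = curve.midpoints[filled]
    vals = curve.mean_r2[filled]
    i_max = int(np.nanargmax(vals))
    target = vals[i_max] / 2.0
    prev = i_max
    for i in range(i_max + 1, vals.size):
        if vals[i] <= target:
            stays = (i == vals.size - 1) or (vals[i + 1] <= target)
            if stays:
                v0, v1 = vals[prev], vals[i]
                d0, d1 = mids[prev], mids[i]
                if v0 == v1:
                    return float(d1)
                return float(d0 + (v0 - target) / (v0 - v1) * (d1 - d0))
        else:
            prev = i
    return float("inf")


def ld_prune(
    dataset: GenotypeDataset,
    r2_threshold: float,
    window: int = 50,
    step: int = 25,
) -> np.ndarray:
    """Sliding-window greedy pruning at an r² threshold.

    Within each ``window``-SNP window (per chromosome, position order) the
    SNP with the most pairwise r² >= threshold against other retained
    window members is removed repeatedly until none remain, then the window
    advances by ``step``.  Ties go to the lower-MAF SNP, then the later
    position.  Returns the retained SNP ids in input order.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ChipQCError("r2_threshold must lie in (0, 1]")
    if window < 2 or step < 1:
        raise ChipQCError("window must be >= 2 and step >= 1")
    removed = np.zeros(dataset.n_snps, dtype=bool)
    maf = np.nan_to_num(dataset.maf(), nan=0.0)
    for chrom in pd.unique(dataset.variants["chrom"]):
        sel = np.flatnonzero((dataset.variants["chrom"] == chrom).to_numpy())
        pos = dataset.variants["pos"].to_numpy()[sel]
        order = sel[np.argsort(pos, kind="stable")]
        for start in range(0, len(order), step):
            members = [i for i in order[start:start + window] if not removed[i]]
            while len(members) > 1:
                r2 = np.zeros((len(members), len(members)))
                for a in range(len(members)):
                    for b in range(a + 1, len(members)):
                        v = pairwise_r2(dataset.calls[:, members[a]],
                                        dataset.calls[:, members[b]])
                        r2[a, b] = r2[b, a] = 0.0 if np.isnan(v) else v
                viol = (r2 >= r2_threshold).sum(axis=1)
                if viol.max() == 0:
                    break
                cand = np.flatnonzero(viol == viol.max())
                # tie-break: lower MAF first, then later position
                key = sorted(
                    cand,
                    key=lambda k: (maf[members[k]],
                                   -dataset.variants["pos"].iloc[members[k]]),
                )
                worst = members[key[0]]
                removed[worst] = True
                members = [i for i in members if i != worst]
            if start + window >= len(order):
                break
    return dataset.variants["id"].to_numpy()[~removed]
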