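"""Synthetic genotype data with the statistical structure the analyses assume.

Three generators cover the study designs the pipeline is built for:

* :func:`simulate_populations` — multi-population genotypes under the
  Balding–Nichols model, where each population's allele frequency is a
  Beta(p(1-F)/F, (1-p)(1-F)/F) draw around an ancestral frequency ``p`` with
  ``F`` the target fixation index.
* :func:`simulate_cross` — nuclear families segregating Mendelian genotypes
  with an injectable genotyping-error rate.
* :func:`simulate_platform_pair` — paired "array" and "sequencing" call sets
  for the same truth.  Sequencing heterozygote miscalls are purely
  allele-sampling: with ``d`` reads from a het, both alleles are seen with
  probability ``1 - (1/2)^(d-1)``, so miscalls concentrate in heterozygotes
  and fall with depth.  The array error is a small per-call flip whose rate
  is elevated on low-FLD probes.

Defaults mirror the study conditions the pipeline targets: five ancestral
clusters, ~12 samples per site, differentiation around F = 0.10, 12x mean
sequencing depth, chip SNPs with MAF >= 0.10, an array error rate of 0.67%
(the mean technical-replicate error), and 23 offspring per cross.
Everything is reproducible bit-exactly under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import MISSING, ChipQCError, GenotypeDataset, PlatformCallSet
from .segregation import CrossFamily, expected_offspring_distribution

__all__ = [
    "CrossSpec",
    "PlatformSpec",
    "SimConfig",
    "simulate_populations",
    "simulate_cross",
    "simulate_platform_pair",
]

#: chip-like functional category mix (intron, intergenic, synonymous,
#: non-synonymous, 5'UTR, 3'UTR) used when placing simulated SNPs
_CATEGORY_PROBS = {
    "intron": 0.3949,
    "intergenic": 0.2228,
    "synonymous": 0.2320,
    "non_synonymous": 0.0314,
    "utr5": 0.0590,
    "utr3": 0.0599,
}


@dataclass
class CrossSpec:
    """Laboratory-cross generator settings."""

    n_offspring: int = 23
    genotyping_error_rate: float = 0.0
    parents: tuple[np.ndarray, np.ndarray] | None = None  # random if None


@dataclass
class PlatformSpec:
    """Paired platform generator settings.

    Read depth decomposes into a per-SNP site factor (lognormal with
    log-scale sd ``site_depth_sigma``, mean 1 — mappability/GC-style
    between-site variation, which is what makes a high-coverage stratum
    exist at all at a modest mean) times a negative-binomial per-call draw
    (variance ``m + m^2 * dispersion``; Poisson when the dispersion is 0).
    ``fld_low_frac`` of probes draw their FLD from the low-quality component
    below the conventional FLD >= 6 screen, and those probes flip calls at
    ``array_error_rate * low_fld_error_mult``.
    """

    mean_depth: float = 12.0
    depth_dispersion: float = 0.05
    site_depth_sigma: float = 0.8
    array_error_rate: float = 0.0067
    fld_low_frac: float = 0.05
    fld_good_mean: float = 12.0
    fld_good_sd: float = 3.0
    fld_low_mean: float = 4.0
    fld_low_sd: float = 1.0
    low_fld_error_mult: float = 10.0
    array_drop_alpha: float = 0.5  # per-SNP no-call rate ~ Beta(alpha, beta)
    array_drop_beta: float = 120.0


@dataclass
class SimConfig:
    """Top-level synthetic-study configuration; the seed is mandatory."""

    seed: int
    n_pops: int = 5
    n_samples_per_pop: int = 12
    n_snps: int = 5000
    target_fst: float = 0.10
    ancestral_maf_range: tuple[float, float] = (0.10, 0.50)
    cross: CrossSpec = field(default_factory=CrossSpec)
    platform: PlatformSpec = field(default_factory=PlatformSpec)

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_fst < 1.0):
            raise ChipQCError("target_fst must lie in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ChipQCError("ancestral_maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.cross.genotyping_error_rate <= 1.0):
            raise ChipQCError("error rates must lie in [0, 1]")
        if self.platform.mean_depth <= 0:
            raise ChipQCError("mean_depth must be positive")


def _variant_table(n_snps: int, rng: np.random.Generator) -> pd.DataFrame:
    """Random sorted positions on one scaffold, chip-like categories and a
    random probe-performance score (stand-in for a proprietary ranking)."""
    pos = np.sort(rng.choice(np.arange(1, max(10 * n_snps, 1000)), size=n_snps,
                             replace=False))
    cats = rng.choice(list(_CATEGORY_PROBS), p=list(_CATEGORY_PROBS.values()),
                      size=n_snps)
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=n_snps)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    return pd.DataFrame({
        "id": [f"snp{j}" for j in range(n_snps)],
        "chrom": "scaffold_1",
        "pos": pos.astype(int),
        "ref": ref,
        "alt": alt,
        "category": cats,
        "score": rng.random(n_snps),
    })


def simulate_populations(cfg: SimConfig) -> GenotypeDataset:
    """Draw multi-population genotypes under the Balding–Nichols model.

    Per SNP the ancestral frequency ``p`` is uniform on
    ``cfg.ancestral_maf_range``; each population's frequency is a
    Balding–Nichols Beta draw with ``F = cfg.target_fst`` (shared exactly
    when F = 0) and genotypes are binomial(2, p_pop).
    """
    rng = np.random.default_rng(cfg.seed)
    n_snps, k = cfg.n_snps, cfg.n_pops
    p_anc = rng.uniform(*cfg.ancestral_maf_range, size=n_snps)
    f = cfg.target_fst
    if f == 0.0:
        p_pop = np.tile(p_anc, (k, 1))
    else:
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        p_pop = rng.beta(a, b, size=(k, n_snps))
    calls = np.concatenate(
        [rng.binomial(2, p_pop[i], size=(cfg.n_samples_per_pop, n_snps))
         for i in range(k)], axis=0,
    ).astype(np.int8)
    sample_ids = [f"pop{i + 1}_s{j + 1}" for i in range(k)
                  for j in range(cfg.n_samples_per_pop)]
    lat = rng.uniform(-25.0, 45.0, size=k)
    lon = rng.uniform(70.0, 150.0, size=k)
    meta = pd.DataFrame({
        "population": [f"pop{i + 1}" for i in range(k)
                       for _ in range(cfg.n_samples_per_pop)],
        "lat": np.repeat(lat, cfg.n_samples_per_pop),
        "lon": np.repeat(lon, cfg.n_samples_per_pop),
    }, index=pd.Index(sample_ids, name="sample_id"))
    return GenotypeDataset(
        sample_ids=sample_ids,
        variants=_variant_table(n_snps, rng),
        calls=calls,
        sample_meta=meta,
    )


def simulate_cross(
    parent1: np.ndarray,
    parent2: np.ndarray,
    n_offspring: int,
    error_rate: float = 0.0,
    seed: int | None = None,
    family_id: str = "fam1",
    snp_ids: np.ndarray | None = None,
) -> CrossFamily:
    """Draw offspring from the Mendelian distribution implied by the parents.

    With probability ``error_rate`` each offspring call is replaced by a
    uniform draw from the other two genotype states.  A missing parental
    call makes the offspring MISSING at that SNP.
    """
    if not (0.0 <= error_rate <= 1.0):
        raise ChipQCError("error_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    g1 = np.asarray(parent1, dtype=np.int8)
    g2 = np.asarray(parent2, dtype=np.int8)
    n_snps = g1.shape[0]
    probs = np.zeros((n_snps, 3))
    valid = (g1 != MISSING) & (g2 != MISSING)
    for j in np.flatnonzero(valid):
        probs[j] = expected_offspring_distribution(int(g1[j]), int(g2[j]))[:3]
    # inverse-CDF draw, vectorized over the offspring x SNP grid
    cum = probs.cumsum(axis=1)
    u = rng.random((n_offspring, n_snps))
    off = (u[..., None] > cum[None, :, :]).sum(axis=2).astype(np.int8)
    if error_rate > 0:
        flip = rng.random((n_offspring, n_snps)) < error_rate
        shift = rng.integers(1, 3, size=(n_offspring, n_snps))
        off = np.where(flip, (off + shift) % 3, off).astype(np.int8)
    off[:, ~valid] = MISSING
    return CrossFamily(family_id=family_id, parent1=g1, parent2=g2,
                       offspring=off, snp_ids=snp_ids)


def simulate_platform_pair(
    truth: GenotypeDataset, platform_cfg: PlatformSpec | None = None,
    seed: int | None = None,
) -> tuple[PlatformCallSet, PlatformCallSet]:
    """Genotype the same truth on a simulated array and by sequencing.

    Array calls are the truth flipped independently at the per-call error
    rate (x ``low_fld_error_mult`` on low-FLD probes), with per-SNP no-call
    masking; sequencing draws a negative-binomial depth ``d`` per call and,
    at heterozygotes, ``d`` Bernoulli(1/2) allele reads — het is called iff
    both alleles are observed.  ``d = 0`` is MISSING; depth is stored.
    """
    cfg = platform_cfg or PlatformSpec()
    if cfg.mean_depth <= 0:
        raise ChipQCError("mean_depth must be positive")
    if (truth.calls == MISSING).any():
        raise ChipQCError("truth must be complete (no missing calls)")
    rng = np.random.default_rng(seed)
    calls = truth.calls
    ns, nv = calls.shape

    # -- array -------------------------------------------------------------
    low_fld = rng.random(nv) < cfg.fld_low_frac
    fld = np.where(
        low_fld,
        rng.normal(cfg.fld_low_mean, cfg.fld_low_sd, size=nv),
        rng.normal(cfg.fld_good_mean, cfg.fld_good_sd, size=nv),
    )
    fld = np.clip(fld, 0.05, None)
    err = np.where(low_fld, cfg.array_error_rate * cfg.low_fld_error_mult,
                   cfg.array_error_rate)
    flip = rng.random((ns, nv)) < err[None, :]
    shift = rng.integers(1, 3, size=(ns, nv))
    array_calls = np.where(flip, (calls + shift) % 3, calls).astype(np.int8)
    drop_rate = rng.beta(cfg.array_drop_alpha, cfg.array_drop_beta, size=nv)
    drop = rng.random((ns, nv)) < drop_rate[None, :]
    array_calls[drop] = MISSING
    array_set = PlatformCallSet(
        base=GenotypeDataset(list(truth.sample_ids), truth.variants.copy(),
                             array_calls, truth.sample_meta),
        platform="array", fld=fld,
    )

    # -- sequencing --------------------------------------------------------
    if cfg.site_depth_sigma > 0:
        site = rng.lognormal(-cfg.site_depth_sigma ** 2 / 2.0,
                             cfg.site_depth_sigma, size=nv)
    else:
        site = np.ones(nv)
    m = cfg.mean_depth * site[None, :]
    if cfg.depth_dispersion > 0:
        r = 1.0 / cfg.depth_dispersion
        depth = rng.negative_binomial(r, r / (r + m), size=(ns, nv))
    else:
        depth = rng.poisson(m, size=(ns, nv))
    seq_calls = calls.copy()
    het = calls == 1
    k_alt = rng.binomial(np.where(het, depth, 0), 0.5)
    seq_calls = np.where(het & (k_alt == 0), 0, seq_calls)
    seq_calls = np.where(het & (depth > 0) & (k_alt == depth), 2, seq_calls)
    seq_calls = np.where(depth == 0, MISSING, seq_calls).astype(np.int8)
    seq_set = PlatformCallSet(
        base=GenotypeDataset(list(truth.sample_ids), truth.variants.copy(),
                             seq_calls, truth.sample_meta),
        platform="sequencing", depth=depth.astype(np.int32),
    )
    return array_set, seq_set
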