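"""Mendelian segregation testing of chip SNPs on laboratory crosses.

For each single-pair mating, SNPs with at least one heterozygous parent are
testable: the expected offspring alt-allele frequency is ``(g1 + g2) / 4``
and the observed allele counts are compared with a 2-cell chi-square
(df = 1).  P-values for SNPs tested in more than one family are combined
with Fisher's method, the familywise error rate is controlled with the Holm
step-down correction, and SNPs with adjusted p below alpha fail.

Offspring genotypes that are impossible given the parents (e.g. hom-alt from
a 0 x 1 mating) are tallied as a separate Mendelian-inconsistency count;
their alleles still enter the allele-count test, which is about frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, ChipQCError, logger

__all__ = [
    "CrossFamily",
    "SegregationResult",
    "expected_offspring_distribution",
    "segregation_chisq",
    "genotype_chisq",
    "combine_fisher",
    "holm_adjust",
    "run_segregation",
]


@dataclass
class CrossFamily:
    """One single-pair mating: two parental genotype vectors plus an
    offspring genotype matrix, all over the same SNP axis."""

    family_id: str
    parent1: np.ndarray  # (n_snps,) dosages, MISSING allowed
    parent2: np.ndarray
    offspring: np.ndarray  # (n_offspring, n_snps)
    snp_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.parent1 = np.asarray(self.parent1, dtype=np.int8)
        self.parent2 = np.asarray(self.parent2, dtype=np.int8)
        self.offspring = np.asarray(self.offspring, dtype=np.int8)
        if self.offspring.ndim != 2:
            raise ChipQCError("offspring must be a 2-D matrix")
        n = self.parent1.shape[0]
        if self.parent2.shape[0] != n or self.offspring.shape[1] != n:
            raise ChipQCError("parental and offspring SNP dimensions disagree")
        if self.snp_ids is not None:
            self.snp_ids = np.asarray(self.snp_ids)
            if self.snp_ids.shape[0] != n:
                raise ChipQCError("snp_ids length must match SNP dimension")

    @property
    def n_snps(self) -> int:
        return self.parent1.shape[0]

    @property
    def n_offspring(self) -> int:
        return self.offspring.shape[0]


def expected_offspring_distribution(g1: int, g2: int) -> tuple[float, float, float, float]:
    """Exact Mendelian offspring distribution for parental dosages ``g1, g2``.

    Returns ``(P(hom-ref), P(het), P(hom-alt), expected_alt_freq)`` where the
    expected alt-allele frequency is ``(g1 + g2) / 4``.
    """
    if g1 not in (0, 1, 2) or g2 not in (0, 1, 2):
        raise ChipQCError("parental genotypes must be in {0, 1, 2}")
    q1, q2 = g1 / 2.0, g2 / 2.0  # P(transmit alt) per parent
    p_hom_alt = q1 * q2
    p_hom_ref = (1 - q1) * (1 - q2)
    p_het = q1 * (1 - q2) + q2 * (1 - q1)
    return p_hom_ref, p_het, p_hom_alt, (g1 + g2) / 4.0


def segregation_chisq(
    observed_alt_count: float, total_alleles: int, expected_alt_freq: float
) -> tuple[float, float]:
    """2-cell chi-square of observed allele counts against the Mendelian
    expectation, df = 1.  An expectation of exactly 0 or 1 with a discordant
    observation is an impossible-genotype signal, returned as ``(inf, 0.0)``.
    """
    if total_alleles <= 0:
        raise ChipQCError("total_alleles must be positive")
    if expected_alt_freq in (0.0, 1.0):
        concordant = (observed_alt_count == 0) if expected_alt_freq == 0.0 \
            else (observed_alt_count == total_alleles)
        return (0.0, 1.0) if concordant else (float("inf"), 0.0)
    exp_alt = total_alleles * expected_alt_freq
    exp_ref = total_alleles - exp_alt
    obs_ref = total_alleles - observed_alt_count
    statistic = (observed_alt_count - exp_alt) ** 2 / exp_alt \
        + (obs_ref - exp_ref) ** 2 / exp_ref
    return statistic, float(stats.chi2.sf(statistic, df=1))


def combine_fisher(p_values) -> float:
    """Fisher combination: ``X = -2 sum(ln p)`` against chi-square with 2k df.

    A single p-value is returned unchanged; zeros are clamped to the smallest
    positive float with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ChipQCError("need at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise ChipQCError("p-values must lie in [0, 1]")
    if (p == 0).any():
        logger.warning("combine_fisher: clamped %d zero p-values", int((p == 0).sum()))
        p = np.maximum(p, np.finfo(float).tiny)
    if p.size == 1:
        return float(p[0])
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, df=2 * p.size))


def holm_adjust(p_values) -> np.ndarray:
    """Holm (1979) step-down adjustment, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class SegregationResult:
    """Per-family tests, per-SNP combined/adjusted p-values and the overall
    failure fraction among tested SNPs."""

    per_family: pd.DataFrame
    per_snp: pd.DataFrame
    failure_fraction: float
    n_tested: int


def genotype_chisq(
    observed_counts: tuple[int, int, int], probs: tuple[float, float, float]
) -> tuple[float, float]:
    """3-cell chi-square of offspring genotype counts against the Mendelian
    distribution (cells with zero expectation excluded from the statistic;
    observations landing in them still deflate the valid cells)."""
    obs = np.asarray(observed_counts, dtype=float)
    p = np.asarray(probs, dtype=float)
    n = obs.sum()
    if n <= 0:
        raise ChipQCError("need at least one called offspring")
    valid = p > 0
    df = int(valid.sum()) - 1
    if df == 0:
        concordant = obs[valid].sum() == n
        return (0.0, 1.0) if concordant else (float("inf"), 0.0)
    e = n * p[valid]
    statistic = float((((obs[valid] - e) ** 2) / e).sum())
    return statistic, float(stats.chi2.sf(statistic, df=df))


def run_segregation(
    families: list[CrossFamily], alpha: float = 0.05, test: str = "allele"
) -> SegregationResult:
    """Run the segregation pipeline across one or more crosses.

    A SNP enters a family's test only when both parents are called and at
    least one is heterozygous; SNPs with no called offspring (or untestable
    in every family) are excluded from the multiple-testing family rather
    than failed.  ``test`` selects the allele-count 2-cell statistic
    (default, the frequency comparison) or the genotype-level 3-cell one.
    """
    if test not in ("allele", "genotype"):
        raise ChipQCError("test must be 'allele' or 'genotype'")
    if not families:
        raise ChipQCError("need at least one family")
    n_snps = families[0].n_snps
    snp_ids = families[0].snp_ids
    if snp_ids is None:
        snp_ids = np.arange(n_snps)
    fam_rows = []
    pvals_per_snp: dict[int, list[float]] = {}
    for fam in families:
        if fam.n_snps != n_snps:
            raise ChipQCError("families must share one SNP axis")
        g1, g2 = fam.parent1, fam.parent2
        testable = (g1 != MISSING) & (g2 != MISSING) & ((g1 == 1) | (g2 == 1))
        called = fam.offspring != MISSING
        n_called = called.sum(axis=0)
        obs_alt = np.where(called, fam.offspring, 0).sum(axis=0)
        # Mendelian inconsistencies: offspring states with probability zero
        p_states = np.zeros((3, n_snps))
        idx = np.flatnonzero(testable)
        for j in idx:
            p_states[:, j] = expected_offspring_distribution(int(g1[j]), int(g2[j]))[:3]
        impossible = np.zeros(n_snps, dtype=int)
        for state in (0, 1, 2):
            impossible += np.where(
                testable & (p_states[state] == 0.0),
                (called & (fam.offspring == state)).sum(axis=0),
                0,
            )
        for j in idx:
            if n_called[j] == 0:
                continue  # no data: excluded, not failed
            exp_freq = (int(g1[j]) + int(g2[j])) / 4.0
            if test == "allele":
                statistic, p = segregation_chisq(
                    int(obs_alt[j]), int(2 * n_called[j]), exp_freq)
            else:
                counts = tuple(int((called[:, j] & (fam.offspring[:, j] == s)).sum())
                               for s in (0, 1, 2))
                statistic, p = genotype_chisq(counts, tuple(p_states[:, j]))
            fam_rows.append((
                snp_ids[j], fam.family_id, True, exp_freq,
                int(obs_alt[j]), int(2 * n_called[j]),
                statistic, p, int(impossible[j]),
            ))
            pvals_per_snp.setdefault(j, []).append(p)
    per_family = pd.DataFrame(
        fam_rows,
        columns=["snp", "family", "testable", "expected_alt_freq",
                 "observed_alt_count", "total_alleles", "chisq", "p",
                 "mendel_inconsistencies"],
    )
    tested = sorted(pvals_per_snp)
    combined = np.array([combine_fisher(pvals_per_snp[j]) for j in tested])
    adjusted = holm_adjust(combined) if tested else np.empty(0)
    fail = adjusted < alpha
    per_snp = pd.DataFrame({
        "snp": [snp_ids[j] for j in tested],
        "n_families_tested": [len(pvals_per_snp[j]) for j in tested],
        "combined_p": combined,
        "adjusted_p": adjusted,
        "fail": fail,
    })
    frac = float(fail.mean()) if tested else 0.0
    return SegregationResult(
        per_family=per_family, per_snp=per_snp,
        failure_fraction=frac, n_tested=len(tested),
    )
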