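# Methods

This note records the models, conventions and calibration choices behind
`chipqc`, in the order the pipeline runs.

## Data model and conventions

Genotypes are unphased biallelic dosages of the alternative allele
(0 = hom-ref, 1 = het, 2 = hom-alt) with a dedicated `MISSING` sentinel
(−1); every statistic masks the sentinel explicitly and no module ever
reinterprets 0/2 polarity. Coordinates are 1-based and fully closed (VCF
convention) and all spacing arithmetic uses that convention. Half-called
genotypes (one allele observed) carry little information and are mapped to
`MISSING` on input. PLINK-style `.ped/.map` text does not record which
allele is the reference, so the writer emits a `.ref` sidecar
(id, ref, alt, category) that the reader consumes; without it the major
allele is taken as reference, which is the usual convention but cannot
guarantee polarity round-trips.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analyses assume,
not the biology underneath it.

* **Population structure** is Balding–Nichols: per SNP an ancestral
  frequency p is drawn uniform on the configured MAF range (default
  0.10–0.50, matching an array designed from common variants), and each
  population's frequency is Beta(p(1−F)/F, (1−p)(1−F)/F) with F the target
  fixation index; genotypes are binomial(2, p_pop). F = 0 shares
  frequencies exactly. Defaults — five populations, 12 samples each,
  F = 0.10 — mirror a multi-site field study with moderate
  differentiation. Balding–Nichols is the standard single-parameter
  differentiation model; it has no drift history, no admixture and no
  linkage, so passing parameter-recovery tests says nothing about
  model misspecification on real demographies.
* **Crosses** draw offspring i.i.d. from the exact Mendelian distribution
  implied by the parental dosages (P(transmit alt) = g/2 per parent);
  genotyping error replaces a call with a uniform draw from the other two
  states at the configured rate. Default 23 offspring per cross
  approximates a ~150-sample six-cross validation panel.
* **Paired platforms** genotype the same truth twice. The array flips each
  call with a small probability (default 0.67%, the scale of technical-
  replicate error on such arrays), masks calls per-SNP to emulate no-calls,
  and draws a per-probe Fisher linear discriminant (FLD) from a two-
  component mixture; the low-FLD component (5% of probes) flips calls at a
  10× elevated rate so that FLD genuinely predicts mismatches. The
  sequencing side draws a read depth per call and, at heterozygotes,
  samples each read Bernoulli(½) between the two alleles: het is called
  iff both alleles are seen, so P(miscall | depth d) = (1/2)^(d−1), zero
  depth is missing, and homozygotes are always called correctly — the
  model deliberately omits base-call error so the heterozygote mechanism
  stays analytically testable. Depth is mean 12× with two dispersion
  sources: a per-SNP lognormal site factor (log-sd 0.8; mappability/GC-
  style variation, which is what creates a ≥ 20× stratum at a 12× mean at
  all) times a negative-binomial per-call draw (dispersion 0.05).
* Everything is bit-reproducible under a fixed seed
  (`numpy.random.default_rng`).

Linkage-realistic haplotype structure is intentionally absent; LD tests
construct their own correlated panels (a haplotype-copying Markov chain
whose allele correlation decays exponentially with distance).

## Probe design

Filters run samples-first, then SNP missingness, then MAF (computed on
non-missing calls) — the conventional order in genotype-QC toolchains; the
cascade is idempotent. Spacing is a greedy left-to-right scan per scaffold
restricted to a region mask (coding SNPs by default): a SNP is kept iff it
lies ≥ min_gap (default 200 bp, boundary inclusive — "at least 200 bp
apart") from the last kept in-mask SNP. Category allocation takes the top
round(N·f_c) candidates per category by an arbitrary numeric ranking key
(a stand-in for proprietary probe-performance scores); deficits from
exhausted categories are redistributed proportionally among categories
with spare candidates, so the selection size is N up to rounding.

## Segregation testing

For each cross, SNPs with both parents called and at least one parent
heterozygous are testable; the expected offspring alt-allele frequency is
(g₁+g₂)/4 and the observed allele counts (missing offspring dropped from
the denominator) feed a 2-cell χ² with df = 1. The allele-count statistic
was chosen as the default because the comparison is framed in terms of
allele frequencies; a genotype-level 3-cell test is available
(`test="genotype"`) and is the only one with power against distortions
that leave the allele frequency unchanged (e.g. symmetric het-deficits at
het × het matings). Offspring genotypes that are impossible given the
parents are tallied as a separate Mendelian-inconsistency count; their
alleles still enter the frequency test. P-values for SNPs tested in
several crosses are combined with Fisher's method (−2Σln p vs χ²_{2k};
a single p passes through unchanged; zeros are clamped to the smallest
positive float), and the familywise error rate over all tested SNPs is
controlled with the Holm step-down procedure; adjusted p < α (default
0.05) fails.

Calibration (pinned in the test suite): error-free six-cross simulations
at 5000 SNPs × 25 offspring keep the failure fraction within α; a 10%
injected offspring error is detected for > 90% of SNPs on a six-cross ×
2000-offspring design. The large family size matters: the allele test's
per-cross signal at 10% error is ≈ 4σ at n = 1000, which is marginal
against a Holm threshold, and het × het crosses contribute nothing, so
power is carried by having several informative crosses per SNP.

## Concordance

The headline metric is the zygosity mismatch percent per sample over
co-called SNPs; population and overall means are unweighted arithmetic
means of per-sample percentages (this convention reproduces published
per-population and overall rows exactly from per-sample values).
Ref-allele and alt-allele disagreements are record-level and reported
separately from zygosity. Allele polarity is harmonized before comparison:
a record whose ref/alt are swapped relative to the other set has its
dosages flipped, and the event is logged. The quality screen retains SNPs
with FLD ≥ 6, array call rate ≥ 98.5% and read depth ≥ 20 in every
compared sample (the strictest of the defensible depth readings; per-call
thresholds are arguments, not constants). Metric–mismatch association is
summarized by the point-biserial correlation plus per-decile mismatch
rates; note that even a perfect median-split separation caps |r| at
√3/2 ≈ 0.87.

## Annotation-bias correction

Bias per category is chip percent minus reference percent, both at the
2-decimal reporting convention. The matched subsample consumes the target
percentages *at two-decimal precision* rather than raw count ratios —
this is deliberate: published "possible" allocations are reproducible
exactly only under the rounded targets (raw ratios shift a category by a
few SNPs). The total is N = ⌊min_c n_c/p_c⌋ (the binding category is
exhausted); seats are floor allocations topped up by largest fractional
remainder, ties broken by the category listing order for determinism, so
seats sum exactly to N and never exceed availability. Replicate sets are
drawn without replacement within category; the shared fraction of k
uniform size-m draws from a pool of size P concentrates near
100·(m/P)^(k−1) — matched (smaller-pool) sets therefore share far more
SNPs than unconstrained random sets of the same size.

## Wild-sample QC

Six steps in a fixed order: locus missingness > 10%; sample missingness
> 20%; exact Hardy–Weinberg test per population at p < 10⁻⁵ (a locus
failing in *any* population is removed — the stricter reading, exposed as
the per-population routine); MAF < 10%; heterozygosity outliers beyond
±4 sample SD of the per-sample het fraction (observed fraction, not the
inbreeding coefficient); and KING-robust kinship > 0.354 — the canonical
2^(−3/2) duplicate cutoff for that estimator — removing the
higher-missingness member of each flagged pair. The HWE p-value is the
standard (not mid-p) exact conditional test, enumerated in log-space with
a 1 + 10⁻¹² relative tolerance when summing configurations "no more
probable than observed" to keep float ties exact; it matches an
exact-rational enumeration oracle for every configuration with n ≤ 50.
The cascade is deterministic and idempotent. Note the ±4 SD step can, by
construction, flag a sample in perfectly clean data if one sample is a
genuine outlier; with fewer than 3 samples it is skipped.

## Linkage disequilibrium

Scaffolds are concatenated into chromosomes by cumulative offset in
assembly order; inter-scaffold pairs within a chromosome are included
(a documented caveat of concatenation). r² is the squared Pearson
correlation of dosage vectors over co-called samples (composite r²,
appropriate for unphased genotypes); zero-variance or < 2-sample pairs
are undefined and excluded. Decay curves bin all within-chromosome pairs
up to 500 kb (1 kb bins by default — wide enough that half-distances of
several hundred kb are measurable) after a light MAF ≥ 1% /
missingness ≤ 20% screen, with a 6-sample minimum. The half-distance is
defined on the binned curve: the first linear-interpolated crossing of
half the *maximum* binned mean (r² at distance zero being unobservable)
that also holds in the following bin; curves that never cross report
infinity. Finite samples floor r² at ≈ 1/(n−1), which inflates
half-distances at small n — the suite verifies half-distance estimates
shrink with sample size on identical populations. Pruning is
sliding-window greedy: remove the SNP with the most r² ≥ t violations,
ties to the lower-MAF then later-position SNP, advance by a step.

## Differentiation and isolation by distance

Per-locus Weir–Cockerham (1984) components a, b, c are computed from
per-population sample sizes, allele frequencies and heterozygote
proportions (populations contribute when ≥ 2 samples are called; loci
monomorphic overall are skipped); the overall estimate is the
ratio-of-sums Σa/Σ(a+b+c), with negative per-locus values retained so the
sums stay unbiased. Uncertainty bootstraps loci with replacement
(100 replicates by default): percentile 95% CI and p(θ ≤ 0). The
implementation is verified to 10⁻¹⁰ against an independent oracle coded
from the general multi-allele formulation, and recovers Balding–Nichols
targets within ±0.02 at 5000 SNPs × 100 samples/pop; nominal-95% CI
coverage on scaled-down replicates sits in the 90–99% band.

Quasi-neutral sets keep intergenic SNPs with per-locus θ ≤ 0.2 (strictly
greater excluded). Geographic distances are haversine great-circle km with
the 6378.137 km equatorial radius. Isolation by distance is OLS of
F_ST/(1−F_ST) on natural-log km over unique site pairs (zero-distance
pairs dropped); the Mantel test correlates upper triangles, permutes rows
and columns of one matrix jointly, and reports the one-sided
(greater) p = (1 + #{r* ≥ r})/(n_perm + 1), so 999 permutations bound p
below by 1/1000. The direction is one-sided because isolation by distance
is a directional hypothesis.

## Numerical and scale choices

Simulation sizes in the test suite (≤ 5000 SNPs, ≤ 200 samples, 100–200
bootstrap/calibration replicates, 99–199 Mantel permutations where many
repetitions are needed) were chosen so each statistical check retains a
comfortable margin over its tolerance while the whole suite runs in well
under a minute per module; they are the package's own calibration scale,
and all stochastic tests are seeded.

## Known limitations

* No multiallelic, indel, phased or sex-chromosome handling anywhere.
* The sequencing error model omits base-call error and mapping artefacts;
  real low-depth data will disagree with the array for more reasons than
  allele sampling.
* LD on concatenated scaffolds mixes intra- and inter-scaffold pairs;
  misordered assemblies inflate apparent long-range LD.
* The exact HWE test enumerates per locus and population; it is intended
  for array-scale (10⁴–10⁵ loci), not WGS-scale, panels.
* Pairwise kinship is O(n² m) in pure NumPy; it is comfortable for
  hundreds of samples, not thousands.
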