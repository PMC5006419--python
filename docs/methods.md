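# Methods

## Collapsing model

A *bin* is a set of selected loci attached to a biological feature. Three
feature levels are built automatically: **gene** bins (one per region in the
knowledge files containing a selected locus), **group** bins (one per
pathway/protein-family group; members are pooled over the group's transitive
region closure, so nested groups inherit their children's regions), and
**intergenic** bins (fixed-width windows, default 50 kb, catching selected
loci covered by no feature). A locus inside two overlapping regions
contributes to both bins; this double assignment is a deliberate choice —
the alternative (assigning to one arbitrary winner) silently biases gene
comparisons, and overlap is rare enough that per-bin tests remain
interpretable. All coordinates are 0-based half-open internally (BED
convention); VCF positions are shifted on ingest. Strand is ignored.

The per-sample bin score is `Σ_j w_j · g_ij` over member loci. Genotype
encodings count non-major alleles: additive (0/1/2), dominant (carrier
indicator), recessive (homozygote indicator); additive = dominant +
recessive holds call-wise at biallelic sites. The major allele is fixed
once from the full loaded cohort, so every stratum uses one coherent
risk/protective orientation. Missing genotypes contribute 0 to scores and
are excluded from every frequency denominator. At multi-allelic sites all
non-major alleles pool into the count, matching the NMAF's definition.

## Locus selection

Variants qualify when their NMAF is strictly below the threshold `T`
(default 0.05) under one of three modes: `overall` (pooled cohort),
`either` (below `T` in at least one of cases/controls — the default, which
admits variants rare on one side only and therefore both risk and
protective candidates), and `both` (below `T` in both strata — the
conservative option known to damp type I error). Strict `<` makes the
boundary case NMAF = T ineligible. Loci with no data in a required stratum
are excluded.

## Weighting

`w(q) = 1/sqrt(n·q·(1−q))` with the pseudo-counted estimate
`q = (m+1)/(2·n_pop+2)` taken from the scheme's weighting population, and
`n` the full-cohort genotyped count at the locus. Holding `n` common across
schemes means the scheme ordering is driven purely by `q`; `w` is strictly
decreasing in `q` on (0, 0.5), so rarer variants weigh more. Note one
subtlety of the pseudo-count: the pooled (`overall`) estimate is *not*
always between the stratum estimates (e.g. equal stratum counts give a
pooled `q` below both), so `minimum ≤ overall ≤ maximum` holds whenever the
pooled estimate lies between the stratum estimates — generically true away
from near-monomorphic loci — but not identically. The tests assert exactly
that conditional form.

## Burden tests

Logistic regression of status on the bin score (plus optional covariates)
with a Wald p-value on the score coefficient — chosen over the likelihood
ratio for speed across tens of thousands of simulated bins, and pinned
against a hand-coded IRLS fit in the tests. Constant scores are reported as
undefined (`degenerate`); separation or Newton failure as `nonconverged`;
undefined results never count as rejections. The Wilcoxon rank-sum test
uses the exact null distribution when the smaller group has ≤ 10 samples
and no ties, otherwise the normal approximation with midranks and tie
correction. No multiple-testing correction is applied inside the engine
(the simulation studies evaluate per-bin α = 0.05); the results table
carries a Bonferroni flag at `α / bins tested` for real-data use.

## Simulation harness

The generator replaces an external haplotype-resampling pipeline with a
documented stand-in that keeps the statistical structure the study needs:

* **Site frequency spectrum** — i.i.d. draws from density ∝ 1/q on
  [5×10⁻⁴, 0.5] (inverse CDF `a·(b/a)^u`), a rare-skewed, neutral-like
  shape; the lower bound is roughly the singleton frequency in a
  1000-chromosome cohort. A user-supplied empirical frequency list can be
  resampled instead when real spectra are available.
* **Genotypes** — Hardy-Weinberg, dosage ~ Binomial(2, q), independent
  loci, no missingness. No linkage disequilibrium is simulated; this is the
  main fidelity limit, and it means the studies quantify weighting-scheme
  behaviour, not LD-driven effects.
* **Phenotypes** — logistic liability `P(case) = expit(α + ln(OR)·burden)`
  over the summed causal dosage, with `α` solved by bisection (to 1e-8)
  against the *exact* burden distribution (a convolution of per-locus
  trinomials) so the population prevalence is matched; individuals are
  generated until the case/control quotas are filled exactly (cap 10⁷ per
  replicate). Because neutral loci are independent of status, rejection
  sampling generates only the causal columns and fills neutral columns in
  afterwards for the retained individuals — an exact shortcut. With OR = 1
  this reduces to labels independent of genotype.

Study defaults (changeable via `SimulationConfig`): 500 cases, 500
controls, 5 % prevalence, α = 0.05, NMAF threshold 0.05 with `either`
mode, additive encoding, 1000 replicates. Bin sizes per replicate:
average gene ~ round(Normal(50, 5)); XL gene ~ round(Normal(200, 5));
pathway = concatenation of UniformInt[2, 50] gene-sized sub-bins
(~100–2500 variants). The sd = 5 choice follows the textual description of
the original evaluation over a table that printed ±10. Power studies place
10 causal variants uniformly among the bin's loci (optionally restricted to
spectrum frequency < T); causal variants too common to pass selection still
influence the phenotype but are excluded from the tested bin, as in a real
pipeline. Each replicate runs the genuine engine path (select → weight →
score → test), so rates measure the implementation end to end.

Every study draws from a single `numpy` Generator seeded from the config;
identical config + seed reproduces identical p-value arrays. An OR sweep
seeds each OR's study as `seed + index`.

## Bin-size bias regression

To quantify whether significance depends on bin size under the null, the
replicate p-values are regressed on the selected-loci counts with a
quasi-binomial GLM (logit link, Pearson-χ² dispersion), appropriate for a
[0, 1]-bounded outcome. Control-only weighting yields a strongly negative
slope (large bins become spuriously significant); the bounded schemes are
flat. Constant sizes raise an error rather than returning an undefined fit.

## Problem sizes in the shipped checks

The test suite runs the null studies at 1000 (gene) / 300 (XL gene) / 200
(pathway) replicates and the power sweep at 150 replicates per OR; the
reproduction script uses 1000/600/300 and 250. These sizes put the
Monte-Carlo standard error comfortably inside each check's tolerance
(binomial SE at rate 0.05, n = 1000 is 0.007) while keeping a full run in
minutes on one core.

## Known limitations

* No LD, no realistic haplotype structure, no missing genotypes in the
  simulator — calibration results transfer to real data only insofar as
  those features do not interact with weighting.
* Sex chromosomes are treated as diploid; genotype likelihoods/dosages are
  out of scope.
* The Wald logistic p-value is slightly anticonservative for very sparse
  scores; the Wilcoxon test is the robust companion in that regime.
* Dispersion-style (variance-component) tests are not implemented; the
  engine's score matrix can be exported for external tools.
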