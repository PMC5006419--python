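"""Case-control sequence simulator and the type-I-error / power study harness.

The generative model is deliberately simple but preserves the statistical
structure a collapsing study depends on:

* allele frequencies are drawn from a rare-skewed site-frequency spectrum
  with density proportional to 1/q on [5e-4, 0.5] (the neutral-theory shape,
  truncated), or resampled from a user-supplied empirical frequency file;
* genotypes are independent Hardy-Weinberg draws, Binomial(2, q) non-major
  allele counts per individual, with no linkage disequilibrium and no
  missingness;
* disease status follows a logistic liability on the summed causal-allele
  count, P(case) = expit(alpha + ln(OR) * burden), with the intercept alpha
  solved numerically so the population prevalence matches the configured
  value; individuals are generated until the case and control quotas are
  filled exactly.

Under an odds ratio of 1 this collapses to status independent of genotype,
giving the null used for type-I-error estimation.  Each replicate simulates
one bin-sized set of loci (average gene, XL gene, or a pathway concatenating
2-50 gene-sized sub-bins), pushes it through the real selection / weighting /
scoring / testing engine, and records the p-value, so the study measures the
whole pipeline rather than a re-derived shortcut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .variant_io import (
    DiseaseModel,
    GenotypeMatrix,
    Locus,
    Phenotype,
    encode_genotypes,
)
from .binning import (
    BinDefinition,
    FilterMode,
    WeightScheme,
    compute_weights,
    score_bins,
    select_loci,
)
from .association import logistic_burden_test, wilcoxon_rank_sum_test

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "sample_maf_spectrum",
    "simulate_genotypes",
    "assign_phenotypes",
    "simulate_case_control",
    "solve_prevalence_intercept",
    "draw_bin_size",
    "run_type1_study",
    "run_power_study",
    "bin_size_bias_regression",
    "DEFAULT_ODDS_RATIOS",
]

SPECTRUM_LOW = 5e-4
SPECTRUM_HIGH = 0.5
XL_GENE_MEAN = 200
PATHWAY_GENES = (2, 50)
DEFAULT_ODDS_RATIOS = (1.25, 1.5, 1.75, 2.0, 2.5, 3.0, 4.0, 5.0)
GENERATION_CAP = 10**7  # individuals generated per replicate before giving up

ALL_SCHEMES = ("none", "control", "minimum", "maximum", "overall")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulation experiment.

    Defaults are the case-control design used throughout the evaluation:
    500 cases / 500 controls, 5 % disease prevalence, gene bins of
    Normal(50, 5) variants, NMAF selection threshold 0.05, additive
    encoding, and 1000 replicates.
    """

    n_cases: int = 500
    n_controls: int = 500
    prevalence: float = 0.05
    bin_kind: str = "gene"  # gene | xl_gene | pathway
    n_variants_mean: float = 50.0
    n_variants_sd: float = 5.0
    n_causal: int = 0
    odds_ratio: float = 1.0
    maf_low: float = SPECTRUM_LOW
    maf_high: float = SPECTRUM_HIGH
    empirical_freqs: tuple[float, ...] | None = None
    threshold: float = 0.05
    filter_mode: str = FilterMode.EITHER.value
    model: str = DiseaseModel.ADDITIVE.value
    schemes: tuple[str, ...] = ALL_SCHEMES
    tests: tuple[str, ...] = ("logistic", "wilcoxon")
    restrict_causal_to_rare: bool = False
    n_sims: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.odds_ratio < 1:
            raise ValueError("odds_ratio must be >= 1")
        if self.bin_kind not in ("gene", "xl_gene", "pathway"):
            raise ValueError(f"unknown bin_kind {self.bin_kind!r}")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        for s in self.schemes:
            WeightScheme(s)
        for t in self.tests:
            if t not in ("logistic", "wilcoxon"):
                raise ValueError(f"unknown test {t!r}")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class SimulationResult:
    """Per-replicate p-values plus the rejection-rate summaries."""

    config: SimulationConfig
    p_values: dict[tuple[str, str], np.ndarray]  # (scheme, test) -> length n_sims
    sizes: np.ndarray  # selected-loci count per replicate

    def rejection_rate(
        self, scheme: str, test: str, alpha: float = 0.05
    ) -> tuple[float, float]:
        """(rate, binomial SE) of p < alpha; undefined p-values never reject."""
        p = self.p_values[(scheme, test)]
        rate = float(np.mean(p < alpha))  # NaN compares False
        se = float(np.sqrt(rate * (1 - rate) / p.size))
        return rate, se

    def summary_grid(self, alpha: float = 0.05) -> "pd.DataFrame":  # noqa: F821
        import pandas as pd

        rows = []
        for (scheme, test), p in sorted(self.p_values.items()):
            rate, se = self.rejection_rate(scheme, test, alpha)
            rows.append(
                dict(
                    bin_kind=self.config.bin_kind,
                    odds_ratio=self.config.odds_ratio,
                    scheme=scheme,
                    test=test,
                    n_sims=p.size,
                    n_undefined=int(np.isnan(p).sum()),
                    rejection_rate=rate,
                    mc_se=se,
                )
            )
        return pd.DataFrame(rows)


def sample_maf_spectrum(
    k: int,
    rng: np.random.Generator,
    low: float = SPECTRUM_LOW,
    high: float = SPECTRUM_HIGH,
    empirical: Sequence[float] | None = None,
) -> np.ndarray:
    """Draw ``k`` allele frequencies from the configured spectrum.

    Default: i.i.d. from density proportional to 1/q on [low, high], i.e.
    inverse CDF q = low * (high/low)**u.  With ``empirical`` given, draws
    resample the listed frequencies with replacement instead.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if empirical is not None:
        freqs = np.asarray(empirical, dtype=float)
        if freqs.size == 0 or ((freqs <= 0) | (freqs >= 1)).any():
            raise ValueError("empirical frequencies must lie in (0, 1)")
        return rng.choice(freqs, size=k, replace=True)
    if not 0 < low < high < 1:
        raise ValueError(f"invalid spectrum bounds [{low}, {high}]")
    u = rng.random(k)
    return low * (high / low) ** u


def _dosage_to_matrix(dosage: np.ndarray, chrom: str = "1") -> GenotypeMatrix:
    """Biallelic matrix from a (n_samples, n_loci) non-major-dosage array.

    Allele 0 is the major/reference allele; loci sit at consecutive
    positions on one synthetic chromosome.
    """
    n, k = dosage.shape
    width = len(str(k))  # zero-pad so lexicographic id order == positional order
    loci = [
        Locus(f"{chrom}:{j + 1:0{width}d}:A:C", chrom, j, ("A", "C")) for j in range(k)
    ]
    calls = np.empty((n, k, 2), dtype=np.int16)
    calls[:, :, 0] = dosage >= 1
    calls[:, :, 1] = dosage == 2
    samples = [f"S{i:05d}" for i in range(n)]
    return GenotypeMatrix(samples, loci, calls)


def simulate_genotypes(
    freqs: np.ndarray, n: int, rng: np.random.Generator
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes: dosage ~ Binomial(2, q) per sample, per locus."""
    freqs = np.asarray(freqs, dtype=float)
    if ((freqs <= 0) | (freqs >= 1)).any():
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    dosage = rng.binomial(2, freqs, size=(n, freqs.size)).astype(np.int16)
    return _dosage_to_matrix(dosage)


def solve_prevalence_intercept(
    causal_freqs: Sequence[float], odds_ratio: float, prevalence: float, tol: float = 1e-8
) -> float:
    """Intercept alpha with E[expit(alpha + ln(OR) * burden)] = prevalence.

    The burden (summed causal non-major allele count) distribution is exact:
    a convolution of the per-locus HWE trinomials, so the expectation is a
    finite sum and bisection converges to ``tol``.
    """
    causal_freqs = np.asarray(causal_freqs, dtype=float)
    beta = np.log(odds_ratio)
    if causal_freqs.size == 0 or beta == 0.0:
        return float(logit(prevalence))
    # exact pmf of the burden sum over {0..2k}
    pmf = np.array([1.0])
    for q in causal_freqs:
        locus = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        pmf = np.convolve(pmf, locus)
    support = np.arange(pmf.size)

    def mean_risk(alpha: float) -> float:
        return float(pmf @ expit(alpha + beta * support))

    lo, hi = -60.0, 60.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mean_risk(mid) < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def assign_phenotypes(
    gm: GenotypeMatrix,
    config: SimulationConfig,
    causal_ids: Sequence[str],
    rng: np.random.Generator,
) -> Phenotype:
    """Draw disease status over a simulated pool and fill the case/control quotas.

    Each pool individual's case probability is the logistic liability on its
    causal burden.  Individuals are taken in random order until exactly
    ``n_cases`` cases and ``n_controls`` controls are collected; a pool too
    small to fill a quota raises.
    """
    cols = np.array([gm.locus_index(l) for l in causal_ids], dtype=int)
    burden = (
        encode_genotypes(gm, DiseaseModel.ADDITIVE)[:, cols].sum(axis=1)
        if cols.size
        else np.zeros(gm.n_samples)
    )
    causal_freqs = _causal_freqs_from_matrix(gm, cols)
    alpha = solve_prevalence_intercept(causal_freqs, config.odds_ratio, config.prevalence)
    risk = expit(alpha + np.log(config.odds_ratio) * burden)
    order = rng.permutation(gm.n_samples)
    is_case = rng.random(gm.n_samples) < risk
    cases = [i for i in order if is_case[i]][: config.n_cases]
    ctrls = [i for i in order if not is_case[i]][: config.n_controls]
    if len(cases) < config.n_cases or len(ctrls) < config.n_controls:
        raise RuntimeError(
            f"pool of {gm.n_samples} exhausted before filling "
            f"{config.n_cases}+{config.n_controls} quotas"
        )
    chosen = cases + ctrls
    status = np.r_[np.ones(len(cases), dtype=int), np.zeros(len(ctrls), dtype=int)]
    return Phenotype([gm.samples[i] for i in chosen], status)


def _causal_freqs_from_matrix(gm: GenotypeMatrix, cols: np.ndarray) -> np.ndarray:
    """Sample non-major allele frequencies at the causal columns."""
    if cols.size == 0:
        return np.array([])
    counts = gm.allele_counts()
    major = gm.major_alleles()
    total = counts.sum(axis=1)
    nonmajor = total - counts[np.arange(gm.n_loci), major]
    with np.errstate(invalid="ignore"):
        freq = nonmajor / total
    return np.nan_to_num(freq[cols])  # all-missing causal locus: no burden signal


def simulate_case_control(
    freqs: np.ndarray,
    causal_idx: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, Phenotype]:
    """Generate genotypes for exactly the configured case/control quotas.

    Fresh individuals are generated (in batches) and kept or discarded by
    their Bernoulli disease draw until both quotas are filled.  Because the
    non-causal loci are independent of status, only the causal columns are
    generated during rejection sampling; the neutral columns are filled in
    afterwards for the retained individuals — an exact shortcut.
    """
    freqs = np.asarray(freqs, dtype=float)
    causal_idx = np.asarray(causal_idx, dtype=int)
    k = freqs.size
    n_total = config.n_samples
    beta = np.log(config.odds_ratio)

    if causal_idx.size == 0 or beta == 0.0:
        # null: status independent of every genotype
        gm = simulate_genotypes(freqs, n_total, rng)
        status = np.r_[
            np.ones(config.n_cases, dtype=int), np.zeros(config.n_controls, dtype=int)
        ]
        return gm, Phenotype(list(gm.samples), status)

    alpha = solve_prevalence_intercept(freqs[causal_idx], config.odds_ratio, config.prevalence)
    case_rows: list[np.ndarray] = []
    ctrl_rows: list[np.ndarray] = []
    generated = 0
    batch = max(1024, 4 * config.n_controls)
    while (len(case_rows) < config.n_cases) or (len(ctrl_rows) < config.n_controls):
        if generated > GENERATION_CAP:
            raise RuntimeError(
                f"generated {generated} individuals without filling quotas "
                f"(prevalence {config.prevalence}, OR {config.odds_ratio})"
            )
        dos = rng.binomial(2, freqs[causal_idx], size=(batch, causal_idx.size)).astype(np.int16)
        is_case = rng.random(batch) < expit(alpha + beta * dos.sum(axis=1))
        generated += batch
        need_cases = config.n_cases - len(case_rows)
        need_ctrls = config.n_controls - len(ctrl_rows)
        case_rows.extend(dos[is_case][:need_cases])
        ctrl_rows.extend(dos[~is_case][:need_ctrls])

    causal_dos = np.vstack(case_rows + ctrl_rows)
    dosage = np.empty((n_total, k), dtype=np.int16)
    neutral_idx = np.setdiff1d(np.arange(k), causal_idx)
    dosage[:, neutral_idx] = rng.binomial(
        2, freqs[neutral_idx], size=(n_total, neutral_idx.size)
    )
    dosage[:, causal_idx] = causal_dos
    gm = _dosage_to_matrix(dosage)
    status = np.r_[
        np.ones(config.n_cases, dtype=int), np.zeros(config.n_controls, dtype=int)
    ]
    return gm, Phenotype(list(gm.samples), status)


def draw_bin_size(config: SimulationConfig, rng: np.random.Generator) -> int:
    """Realized variant count for one replicate's bin.

    gene: round(Normal(mean, sd)); xl_gene: round(Normal(200, sd));
    pathway: concatenation of UniformInt[2, 50] gene-sized sub-bins.
    Every draw is truncated below at n_causal + 1 (and at 2).
    """
    floor = max(2, config.n_causal + 1)

    def gene_like(mean: float) -> int:
        return max(floor, int(round(rng.normal(mean, config.n_variants_sd))))

    if config.bin_kind == "gene":
        return gene_like(config.n_variants_mean)
    if config.bin_kind == "xl_gene":
        return gene_like(XL_GENE_MEAN)
    n_genes = rng.integers(PATHWAY_GENES[0], PATHWAY_GENES[1] + 1)
    return max(floor, sum(gene_like(config.n_variants_mean) for _ in range(n_genes)))


def _test_one_bin(
    gm: GenotypeMatrix,
    phen: Phenotype,
    config: SimulationConfig,
) -> tuple[dict[tuple[str, str], float], int]:
    """Select, weight, score, and test one simulated bin; NaN = undefined p."""
    pvals: dict[tuple[str, str], float] = {}
    selected = select_loci(gm, phen, config.filter_mode, config.threshold)
    if not selected:
        for scheme in config.schemes:
            for test in config.tests:
                pvals[(scheme, test)] = np.nan
        return pvals, 0
    bin_def = BinDefinition("simbin", "custom", selected)
    for scheme in config.schemes:
        weights = compute_weights(gm, phen, selected, scheme)
        bsm = score_bins([bin_def], gm, config.model, weights)
        scores = bsm.scores[:, 0]
        for test in config.tests:
            if test == "logistic":
                res = logistic_burden_test(scores, phen, bin_id=bin_def.bin_id,
                                           n_loci=len(selected))
            else:
                res = wilcoxon_rank_sum_test(scores, phen, bin_id=bin_def.bin_id,
                                             n_loci=len(selected))
            pvals[(scheme, test)] = np.nan if res.p_value is None else res.p_value
    return pvals, len(selected)


def _run_study(config: SimulationConfig) -> SimulationResult:
    rng = np.random.default_rng(config.seed)
    collected = {(s, t): np.full(config.n_sims, np.nan) for s in config.schemes
                 for t in config.tests}
    sizes = np.zeros(config.n_sims, dtype=int)
    for rep in range(config.n_sims):
        k = draw_bin_size(config, rng)
        freqs = sample_maf_spectrum(
            k, rng, config.maf_low, config.maf_high, config.empirical_freqs
        )
        if config.n_causal:
            if config.n_causal > k:
                raise ValueError(f"n_causal {config.n_causal} exceeds bin size {k}")
            if config.restrict_causal_to_rare:
                candidates = np.nonzero(freqs < config.threshold)[0]
                if candidates.size < config.n_causal:
                    raise RuntimeError(
                        f"only {candidates.size} loci below the threshold; "
                        f"cannot place {config.n_causal} causal variants"
                    )
            else:
                candidates = np.arange(k)
            causal_idx = rng.choice(candidates, size=config.n_causal, replace=False)
        else:
            causal_idx = np.array([], dtype=int)
        gm, phen = simulate_case_control(freqs, causal_idx, config, rng)
        pvals, n_sel = _test_one_bin(gm, phen, config)
        sizes[rep] = n_sel
        for key, p in pvals.items():
            collected[key][rep] = p
    return SimulationResult(config, collected, sizes)


def run_type1_study(config: SimulationConfig) -> SimulationResult:
    """Null study: OR must be 1; rejection rates estimate the type I error."""
    if config.odds_ratio != 1.0 or config.n_causal != 0:
        raise ValueError("type-I-error study requires odds_ratio=1 and n_causal=0")
    return _run_study(config)


def run_power_study(
    config: SimulationConfig,
    odds_ratios: Sequence[float] = DEFAULT_ODDS_RATIOS,
) -> dict[float, SimulationResult]:
    """Alternative study: one result per odds ratio in the sweep.

    Causal loci (default 10) are drawn uniformly per replicate, optionally
    restricted to spectrum frequencies below the selection threshold.  The
    rejection rate estimates power; passing OR=1 recovers the type I error.
    """
    if config.n_causal < 1:
        raise ValueError("power study requires n_causal >= 1")
    results: dict[float, SimulationResult] = {}
    for i, odds in enumerate(odds_ratios):
        sub = replace(config, odds_ratio=float(odds), seed=config.seed + i)
        results[float(odds)] = _run_study(sub)
    return results


def bin_size_bias_regression(
    pvals: np.ndarray, sizes: np.ndarray
) -> tuple[float, float, float]:
    """Fractional-response regression of replicate p-values on bin size.

    Fits a quasi-binomial GLM (logit link, Pearson-X2 dispersion) of the
    p-value — bounded in [0, 1] — on the selected-loci count, and returns
    (slope, SE, two-sided p).  A flat relationship is expected for unbiased
    weighting schemes; control-only weighting shows a negative slope (big
    bins become spuriously significant).
    """
    import statsmodels.api as sm

    pvals = np.asarray(pvals, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    keep = ~np.isnan(pvals)
    pvals, sizes = pvals[keep], sizes[keep]
    if pvals.size < 10:
        raise ValueError("need at least 10 defined replicates")
    if np.ptp(sizes) == 0:
        raise ValueError("bin sizes are constant; slope is unidentifiable")
    X = sm.add_constant(sizes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(pvals, X, family=sm.families.Binomial()).fit(scale="X2")
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
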