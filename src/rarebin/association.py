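"""Burden association tests on collapsed bin scores.

Two classical burden tests are provided: logistic regression of case/control
status on the bin score (Wald test on the score coefficient) and the
two-sided Wilcoxon rank-sum test comparing case and control score
distributions.  Both act on a single per-sample score vector per bin, so any
weighting or disease-model choice is already baked into the scores.

No multiple-testing correction is applied to the per-bin p-values; the
results table carries a Bonferroni-significance flag at a user-chosen family
level instead, leaving the raw values intact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .binning import BinScoreMatrix
from .variant_io import Phenotype

__all__ = [
    "AssociationResult",
    "logistic_burden_test",
    "wilcoxon_rank_sum_test",
    "run_association",
    "write_results",
]

TESTS = ("logistic", "wilcoxon")

#: Group size at or below which the rank-sum test uses the exact null
#: distribution (when the data carry no ties).
EXACT_WILCOXON_MAX_N = 10


@dataclass
class AssociationResult:
    bin_id: str
    test: str
    statistic: float
    p_value: float | None
    n_loci: int
    n_cases: int
    n_controls: int
    reason: str = ""  # why p_value is undefined: degenerate | nonconverged

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.p_value is None and not self.reason:
            raise ValueError("undefined p-value needs a reason code")


def _split_scores(
    scores: np.ndarray, phen: Phenotype
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    status = phen.status
    if scores.shape != status.shape:
        raise ValueError(f"scores length {scores.shape} != phenotype length {status.shape}")
    if phen.n_cases == 0 or phen.n_controls == 0:
        raise ValueError("need at least one case and one control")
    return scores, scores[status == 1], scores[status == 0]


def logistic_burden_test(
    scores: np.ndarray,
    phen: Phenotype,
    covariates: np.ndarray | None = None,
    bin_id: str = "",
    n_loci: int = 0,
) -> AssociationResult:
    """Wald test on the bin-score coefficient of a logistic fit.

    Constant scores make the coefficient unidentifiable and return an
    undefined result with reason ``degenerate``; separation or a failed
    Newton fit returns reason ``nonconverged``.
    """
    scores, _, _ = _split_scores(scores, phen)
    base = dict(n_loci=n_loci, n_cases=phen.n_cases, n_controls=phen.n_controls)
    if np.ptp(scores) == 0:
        return AssociationResult(bin_id, "logistic", np.nan, None, reason="degenerate", **base)
    X = scores[:, None]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        X = np.column_stack([X, cov[:, None] if cov.ndim == 1 else cov])
    X = sm.add_constant(X, prepend=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(phen.status, X).fit(disp=0, method="newton", maxiter=50)
        if not fit.mle_retvals.get("converged", False):
            raise RuntimeError("no convergence")
        z = fit.tvalues[1]
        p = fit.pvalues[1]
        if not np.isfinite(z) or not np.isfinite(p):
            raise RuntimeError("non-finite Wald statistic")
    except Exception:
        return AssociationResult(bin_id, "logistic", np.nan, None, reason="nonconverged", **base)
    return AssociationResult(bin_id, "logistic", float(z), float(p), **base)


def wilcoxon_rank_sum_test(
    scores: np.ndarray, phen: Phenotype, bin_id: str = "", n_loci: int = 0
) -> AssociationResult:
    """Two-sided rank-sum (Mann-Whitney) test of case vs control scores.

    Uses the exact null distribution when the smaller group has at most
    :data:`EXACT_WILCOXON_MAX_N` samples and the scores carry no ties;
    otherwise the normal approximation with midranks and tie correction.
    """
    scores, case_scores, ctrl_scores = _split_scores(scores, phen)
    base = dict(n_loci=n_loci, n_cases=phen.n_cases, n_controls=phen.n_controls)
    if np.ptp(scores) == 0:  # all tied: no ordering information
        return AssociationResult(bin_id, "wilcoxon", np.nan, None,
                                 reason="degenerate", **base)
    no_ties = np.unique(scores).size == scores.size
    small = min(case_scores.size, ctrl_scores.size) <= EXACT_WILCOXON_MAX_N
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(case_scores, ctrl_scores, alternative="two-sided", method=method)
    return AssociationResult(
        bin_id, "wilcoxon", float(res.statistic), float(min(res.pvalue, 1.0)), **base
    )


def run_association(
    bsm: BinScoreMatrix,
    phen: Phenotype,
    test: str,
    covariates: np.ndarray | None = None,
) -> list[AssociationResult]:
    """One result per bin, in the bin order of the score matrix."""
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; expected one of {TESTS}")
    phen = phen.aligned_to_samples(bsm.samples)
    results = []
    for b, bin_def in enumerate(bsm.bins):
        scores = bsm.scores[:, b]
        if test == "logistic":
            res = logistic_burden_test(scores, phen, covariates, bin_def.bin_id, bin_def.n_loci)
        else:
            res = wilcoxon_rank_sum_test(scores, phen, bin_def.bin_id, bin_def.n_loci)
        results.append(res)
    return results


def write_results(
    results: Sequence[AssociationResult],
    path: str | Path,
    levels: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> Path:
    """Tab-delimited results with a Bonferroni flag at ``alpha / n_bins``."""
    path = Path(path)
    n_tested = sum(1 for r in results if r.p_value is not None)
    cutoff = alpha / n_tested if n_tested else np.nan
    with open(path, "w") as handle:
        handle.write(
            "bin_id\tlevel\tn_loci\ttest\tstatistic\tp_value\treason\tbonferroni_significant\n"
        )
        for r in results:
            level = (levels or {}).get(r.bin_id, "")
            p_str = "NA" if r.p_value is None else repr(r.p_value)
            flag = "NA" if r.p_value is None else str(int(r.p_value < cutoff))
            handle.write(
                f"{r.bin_id}\t{level}\t{r.n_loci}\t{r.test}\t{r.statistic:.6g}\t"
                f"{p_str}\t{r.reason}\t{flag}\n"
            )
    return path
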