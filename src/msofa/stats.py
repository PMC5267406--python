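"""Mortality-discrimination statistics for severity scores.

Survivor/non-survivor group comparisons (Welch/pooled t, Mann-Whitney,
Pearson chi-square), the empirical AUROC with its Mann-Whitney concordance
identity, DeLong placement-value confidence intervals and paired AUC
comparison, 2x2 odds ratios with Woolf intervals, and multivariable
logistic regression via maximum likelihood.

The AUROC here is the probability that a randomly chosen patient who died
has a higher score than a randomly chosen survivor, with ties counting
one half — identical to the normalised Mann-Whitney U statistic.  The
DeLong variance uses the structural components (placement values)
V10_i = P-hat(score of case i exceeds a random control) and
V01_j = P-hat(a random case exceeds control j); see docs/methods.md.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "GroupComparison",
    "DiscriminationResult",
    "LogisticFit",
    "group_compare_continuous",
    "group_compare_categorical",
    "contingency_odds_ratio",
    "empirical_auroc",
    "delong_ci",
    "bootstrap_auc_ci",
    "delong_paired_test",
    "fit_logistic",
]


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test: str  # "t", "mann_whitney" or "chi_square"
    statistic: float
    p_value: float
    group_summary: dict[str, dict[str, float]] = field(default_factory=dict)
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class DiscriminationResult:
    score_variant: str
    auc: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    comparison_p: Optional[float] = None
    method: str = "delong"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError(
                f"CI [{self.ci_low}, {self.ci_high}] does not contain AUC {self.auc}")


@dataclass(frozen=True)
class LogisticFit:
    params: "pd.Series"
    odds_ratios: "pd.DataFrame"  # columns: odds_ratio, ci_low, ci_high, p_value
    converged: bool
    separation: bool
    n_used: int
    covariates: tuple[str, ...]


def _split_groups(values, outcomes) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    outcomes = np.asarray(outcomes)
    if values.shape != outcomes.shape:
        raise ValueError("values and outcomes must have equal length")
    pos = values[outcomes == 1]
    neg = values[outcomes == 0]
    return pos, neg


def group_compare_continuous(
    values: Sequence[float],
    outcomes: Sequence[int],
    variable: str = "value",
    method: str = "auto",
    equal_var: bool = False,
) -> GroupComparison:
    """Compare a continuous variable between outcome groups.

    ``method``: "t" (default unequal-variance Welch form; ``equal_var=True``
    for the pooled form), "mann_whitney", or "auto", which falls back to
    Mann-Whitney when a Shapiro-Wilk normality pre-check (alpha = 0.05)
    fails in either group.  Two-sided p-values throughout.
    """
    pos, neg = _split_groups(values, outcomes)
    for name, group in (("died", pos), ("survived", neg)):
        if group.size == 0:
            raise ValueError(f"group {name!r} is empty")

    note = ""
    if method == "auto":
        method = "t"
        if min(pos.size, neg.size) >= 3:
            p_norm = min(sps.shapiro(pos).pvalue, sps.shapiro(neg).pvalue)
            if p_norm < 0.05:
                method = "mann_whitney"
            note = f"auto: shapiro min p = {p_norm:.4g} -> {method}"

    if method == "t":
        if min(pos.size, neg.size) < 2:
            raise ValueError("t-test requires >= 2 observations per group")
        res = sps.ttest_ind(pos, neg, equal_var=equal_var)
        statistic, p = float(res.statistic), float(res.pvalue)
        if pos.size == neg.size and np.array_equal(np.sort(pos), np.sort(neg)) and np.std(pos) == np.std(neg) == 0:
            statistic, p = 0.0, 1.0  # identical degenerate groups
    elif method == "mann_whitney":
        res = sps.mannwhitneyu(pos, neg, alternative="two-sided")
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")

    summary = {
        "died": {"n": pos.size, "mean": float(np.mean(pos)), "sd": float(np.std(pos, ddof=1)) if pos.size > 1 else float("nan"),
                 "median": float(np.median(pos)), "iqr_low": float(np.percentile(pos, 25)), "iqr_high": float(np.percentile(pos, 75))},
        "survived": {"n": neg.size, "mean": float(np.mean(neg)), "sd": float(np.std(neg, ddof=1)) if neg.size > 1 else float("nan"),
                     "median": float(np.median(neg)), "iqr_low": float(np.percentile(neg, 25)), "iqr_high": float(np.percentile(neg, 75))},
    }
    if math.isnan(p):  # zero-variance identical groups
        statistic, p = 0.0, 1.0
    return GroupComparison(variable, method, statistic, min(max(p, 0.0), 1.0), summary, note)


def group_compare_categorical(counts, variable: str = "category") -> GroupComparison:
    """Pearson chi-square test on a 2 x k contingency table of counts."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError(f"expected a 2 x k table, got shape {table.shape}")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if table.sum() == 0:
        raise ValueError("all-zero contingency table")
    note = ""
    empty = table.sum(axis=0) == 0
    if empty.any():
        table = table[:, ~empty]
        note = f"dropped {int(empty.sum())} empty column(s); df reduced"
    if table.shape[1] < 2:
        raise ValueError("need at least two non-empty columns")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return GroupComparison(variable, "chi_square", float(chi2), float(p), note=note)


def contingency_odds_ratio(table) -> tuple[float, float, float, bool]:
    """Odds ratio ad/bc for a 2x2 table with a Woolf (log-scale) 95% CI.

    Applies the Haldane-Anscombe 0.5 continuity correction to every cell
    when any cell is zero; returns (or, ci_low, ci_high, corrected).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    corrected = bool((t == 0).any())
    if corrected:
        t = t + 0.5
    (a, b), (c, d) = t
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.975)
    return (
        float(or_),
        float(math.exp(math.log(or_) - z * se)),
        float(math.exp(math.log(or_) + z * se)),
        corrected,
    )


def empirical_auroc(scores: Sequence[float], outcomes: Sequence[int]) -> float:
    """Empirical AUROC with deaths as the positive class.

    Computed through the Mann-Whitney identity with midranks:
    P(score_died > score_survived) + 0.5 P(tie) over all case-control
    pairs.  Requires both outcome classes to be present.
    """
    pos, neg = _split_groups(scores, outcomes)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both outcome classes must be present")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    rank_sum_pos = ranks[: pos.size].sum()
    u = rank_sum_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement values via midranks (Sun & Xu algorithm)."""
    m, n = pos.size, neg.size
    combined = np.concatenate([pos, neg])
    ranks = sps.rankdata(combined)
    ranks_pos = sps.rankdata(pos)
    ranks_neg = sps.rankdata(neg)
    v10 = (ranks[:m] - ranks_pos) / n            # per-case placements
    v01 = 1.0 - (ranks[m:] - ranks_neg) / m      # per-control placements
    auc = float(v10.mean())
    return auc, v10, v01


def delong_ci(
    scores: Sequence[float],
    outcomes: Sequence[int],
    level: float = 0.95,
    variant: str = "score",
) -> DiscriminationResult:
    """AUC with a DeLong (placement-value) normal-approximation CI.

    The variance is S10/m + S01/n with S10, S01 the sample variances of
    the case and control placement values; the CI is clipped to [0, 1].
    """
    pos, neg = _split_groups(scores, outcomes)
    if pos.size < 2 or neg.size < 2:
        raise ValueError(
            "DeLong CI needs >= 2 members per class; use bootstrap_auc_ci for degenerate cohorts")
    auc, v10, v01 = _placements(pos, neg)
    var = v10.var(ddof=1) / pos.size + v01.var(ddof=1) / neg.size
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return DiscriminationResult(
        score_variant=variant,
        auc=auc,
        ci_low=float(max(0.0, min(auc - half, auc))),
        ci_high=float(min(1.0, max(auc + half, auc))),
        level=level,
        method="delong",
    )


def bootstrap_auc_ci(
    scores: Sequence[float],
    outcomes: Sequence[int],
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
    variant: str = "score",
) -> DiscriminationResult:
    """Percentile CI for the AUC from a stratified (per-class) bootstrap."""
    pos, neg = _split_groups(scores, outcomes)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both outcome classes must be present")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        aucs[b], _, _ = _placements(bp, bn)
    alpha = 1.0 - level
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    auc, _, _ = _placements(pos, neg)
    return DiscriminationResult(
        score_variant=variant,
        auc=auc,
        ci_low=float(min(lo, auc)),
        ci_high=float(max(hi, auc)),
        level=level,
        method="bootstrap",
    )


def delong_paired_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    outcomes: Sequence[int],
) -> tuple[float, float, float]:
    """DeLong paired test for the AUC difference of two scores measured on
    the same patients.

    Returns (auc_a, auc_b, two-sided p).  The variance of the difference
    uses the paired covariance of the placement values; identical scores
    yield p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    outcomes = np.asarray(outcomes)
    pos_a, neg_a = _split_groups(scores_a, outcomes)
    pos_b, neg_b = _split_groups(scores_b, outcomes)
    if pos_a.size < 2 or neg_a.size < 2:
        raise ValueError("paired DeLong test needs >= 2 members per class")
    auc_a, v10_a, v01_a = _placements(pos_a, neg_a)
    auc_b, v10_b, v01_b = _placements(pos_b, neg_b)
    m, n = pos_a.size, neg_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var_diff <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / math.sqrt(var_diff)
        p = float(2 * sps.norm.sf(abs(z)))
    return auc_a, auc_b, min(max(p, 0.0), 1.0)


def fit_logistic(
    outcome: Sequence[int],
    covariates: "pd.DataFrame",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Multivariable logistic regression of a binary outcome by maximum
    likelihood, with Wald 95% CIs exponentiated to the odds-ratio scale.

    Constant or perfectly collinear covariates are rejected up front with
    the offenders named.  Perfect separation is detected and flagged; a
    separated fit carries no Wald intervals.
    """
    x = pd.DataFrame(covariates).astype(float)
    y = np.asarray(outcome, dtype=float)
    if len(y) != len(x):
        raise ValueError("outcome and covariates must have equal length")
    mask = ~(np.isnan(y) | x.isna().any(axis=1).to_numpy())
    x, y = x.loc[mask], y[mask]

    constant = [c for c in x.columns if x[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariate(s): {constant}")
    design = sm.add_constant(x, prepend=True)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify an offending column by leave-one-out rank
        offenders = [c for c in x.columns
                     if np.linalg.matrix_rank(design.drop(columns=[c]).to_numpy()) == rank]
        raise ValueError(f"perfectly collinear covariate(s): {offenders}")

    separation = False
    converged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            model = sm.Logit(y, design)
            result = model.fit(disp=0, maxiter=max_iter, tol=tol)
            converged = bool(result.mle_retvals.get("converged", False))
            params = result.params
            bse = result.bse
            pvalues = result.pvalues
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separation = True
            params = pd.Series(np.nan, index=design.columns)
            bse = pd.Series(np.nan, index=design.columns)
            pvalues = pd.Series(np.nan, index=design.columns)
        for w in caught:
            if issubclass(w.category, PerfectSeparationWarning):
                separation = True
    if not separation and np.max(np.abs(params.to_numpy())) > 15:
        separation = True  # quasi-separated: Wald intervals meaningless

    z = sps.norm.ppf(0.975)
    if separation:
        or_table = pd.DataFrame(
            {"odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan},
            index=design.columns,
        )
    else:
        or_table = pd.DataFrame({
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(params - z * bse),
            "ci_high": np.exp(params + z * bse),
            "p_value": pvalues,
        })
    return LogisticFit(
        params=params,
        odds_ratios=or_table,
        converged=converged and not separation,
        separation=separation,
        n_used=int(mask.sum()),
        covariates=tuple(x.columns),
    )
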