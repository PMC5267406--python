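"""Publication-style analysis tables built from the per-patient score table.

Four tables mirror the usual severity-score validation layout:

* characteristics by outcome (demographics, ventilation, vasopressor use,
  length of stay; t/Mann-Whitney for continuous, chi-square for counts);
* subscore and total comparison at T0 and T48 plus the derived family
  (mean, highest, delta, total-sum), survivors vs non-survivors;
* AUROC per score variant with confidence intervals and the paired
  mean-vs-initial DeLong comparison;
* multivariable logistic odds ratios for ICU mortality.

Every function takes the score frame produced by
:func:`msofa.pipeline.scores_to_frame` (with demographics joined) and
returns a plain DataFrame ready to write as CSV.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import stats

SCORE_VARIANTS = ("initial", "at48", "mean_score", "highest", "delta")
#: display names for the AUC table
VARIANT_LABELS = {
    "initial": "initial",
    "at48": "48h",
    "mean_score": "mean",
    "highest": "highest",
    "delta": "delta",
}

DEFAULT_COVARIATES = ("age", "sex", "mechanically_ventilated", "vasopressor_used")


def _outcome01(frame: pd.DataFrame) -> np.ndarray:
    if "outcome" not in frame.columns:
        raise ValueError("score frame lacks an 'outcome' column; join patient records first")
    outcomes = frame["outcome"].map({"died": 1, "survived": 0})
    if outcomes.isna().any():
        bad = frame.loc[outcomes.isna(), "outcome"].unique()
        raise ValueError(f"unexpected outcome values: {list(bad)}")
    values = outcomes.to_numpy()
    if len(np.unique(values)) < 2:
        raise ValueError("cohort has a single outcome class; comparisons are undefined")
    return values


def _comparison_row(frame, column, outcome, method="t") -> dict[str, object]:
    cmp = stats.group_compare_continuous(frame[column].to_numpy(float), outcome,
                                         variable=column, method=method)
    died, surv = cmp.group_summary["died"], cmp.group_summary["survived"]
    return {
        "variable": column,
        "all_mean": float(frame[column].mean()),
        "all_sd": float(frame[column].std(ddof=1)),
        "survivor_mean": surv["mean"], "survivor_sd": surv["sd"],
        "nonsurvivor_mean": died["mean"], "nonsurvivor_sd": died["sd"],
        "test": cmp.test, "statistic": cmp.statistic, "p_value": cmp.p_value,
    }


def characteristics_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Demographics and clinical characteristics by ICU outcome."""
    outcome = _outcome01(frame)
    rows = [
        _comparison_row(frame, "age", outcome),
        _comparison_row(frame, "icu_los_days", outcome, method="auto"),
    ]
    for column in ("sex", "mechanically_ventilated", "vasopressor_used"):
        values = frame[column]
        if column == "sex":
            indicator = (values == "male").astype(int)
            label = "sex_male"
        else:
            indicator = values.astype(int)
            label = column
        table = np.array([
            [int(((outcome == 0) & (indicator == 1)).sum()), int(((outcome == 0) & (indicator == 0)).sum())],
            [int(((outcome == 1) & (indicator == 1)).sum()), int(((outcome == 1) & (indicator == 0)).sum())],
        ])
        try:
            cmp = stats.group_compare_categorical(table, variable=label)
            statistic, p = cmp.statistic, cmp.p_value
        except ValueError:
            statistic, p = float("nan"), float("nan")
        rows.append({
            "variable": label,
            "all_mean": float(indicator.mean()),
            "survivor_mean": float(indicator[outcome == 0].mean()),
            "nonsurvivor_mean": float(indicator[outcome == 1].mean()),
            "test": "chi_square", "statistic": statistic, "p_value": p,
        })
    return pd.DataFrame(rows)


def score_comparison_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Survivor/non-survivor comparison of every subscore, the two totals
    and the derived family (t-test, mirroring a severity-score Table 3)."""
    outcome = _outcome01(frame)
    columns = [c for c in frame.columns if c.startswith(("t0_", "t48_"))]
    columns += ["mean_score", "highest", "delta", "total_sum"]
    return pd.DataFrame([_comparison_row(frame, c, outcome) for c in columns])


def auc_table(
    frame: pd.DataFrame,
    ci_method: str = "delong",
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """AUROC for each score variant against ICU mortality, with CIs and
    the paired DeLong comparison of the mean vs the initial score."""
    outcome = _outcome01(frame)
    rows = []
    for variant in SCORE_VARIANTS:
        scores = frame[variant].to_numpy(float)
        if ci_method == "delong":
            res = stats.delong_ci(scores, outcome, level=level, variant=VARIANT_LABELS[variant])
        elif ci_method == "bootstrap":
            res = stats.bootstrap_auc_ci(scores, outcome, level=level, seed=seed,
                                         variant=VARIANT_LABELS[variant])
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        rows.append({
            "variant": res.score_variant, "auc": res.auc,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "ci_method": res.method, "comparison": "", "comparison_p": np.nan,
        })
    _, _, p_mean_vs_initial = stats.delong_paired_test(
        frame["mean_score"].to_numpy(float), frame["initial"].to_numpy(float), outcome)
    table = pd.DataFrame(rows)
    table.loc[table["variant"] == "mean", ["comparison", "comparison_p"]] = \
        ["mean_vs_initial", p_mean_vs_initial]
    return table


def logistic_table(
    frame: pd.DataFrame,
    score_variant: str = "initial",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Adjusted odds ratios for ICU mortality from a multivariable
    logistic model of one score variant plus the configured covariates."""
    outcome = _outcome01(frame)
    design = pd.DataFrame({score_variant: frame[score_variant].to_numpy(float)})
    for cov in covariates:
        if cov == "sex":
            design["sex_male"] = (frame["sex"] == "male").astype(float)
        else:
            design[cov] = frame[cov].astype(float)
    fit = stats.fit_logistic(outcome, design)
    table = fit.odds_ratios.copy()
    table.insert(0, "term", table.index)
    table["coefficient"] = fit.params.reindex(table.index).to_numpy()
    table["converged"] = fit.converged
    table["separation"] = fit.separation
    table["n_used"] = fit.n_used
    return table.reset_index(drop=True)


def roc_coordinates(frame: pd.DataFrame, variant: str) -> pd.DataFrame:
    """Empirical ROC curve (FPR, TPR, threshold) for one score variant."""
    outcome = _outcome01(frame)
    scores = frame[variant].to_numpy(float)
    thresholds = np.unique(scores)[::-1]
    pos, neg = (outcome == 1).sum(), (outcome == 0).sum()
    rows = [{"threshold": np.inf, "fpr": 0.0, "tpr": 0.0}]
    for thr in thresholds:
        predicted = scores >= thr
        rows.append({
            "threshold": float(thr),
            "fpr": float((predicted & (outcome == 0)).sum() / neg),
            "tpr": float((predicted & (outcome == 1)).sum() / pos),
        })
    return pd.DataFrame(rows)
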