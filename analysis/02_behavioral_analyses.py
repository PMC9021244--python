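"""Behavioral analyses of the synthetic cohort.

Applies the preregistered win-switch exclusion rule, compares choice
accuracy between flagged and retained subjects, computes learning
curves, fits the multilevel logistic regression on the retained sample,
and recomputes the published contingency chi-square statistics.
"""

from pathlib import Path

import pandas as pd
from scipy import stats

from riskylearn.behavior_stats import (chi_square_independence,
                                       cohort_accuracy, exclusion_report,
                                       fit_choice_regression,
                                       learning_curves)
from riskylearn.task_engine import read_trials_csv

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    trials = read_trials_csv(OUT / "trials.csv")

    exclusions = exclusion_report(trials)
    exclusions.to_csv(OUT / "exclusions.csv", index=False)
    by_group = exclusions.groupby("age_group")["excluded"].agg(["sum", "count"])
    print("win-switch exclusions per age group:")
    print(by_group.to_string())
    table = [by_group["sum"].tolist(),
             (by_group["count"] - by_group["sum"]).tolist()]
    stat, df, p = chi_square_independence(table)
    print(f"exclusion prevalence chi2({df}) = {stat:.1f}, p = {p:.2f}")

    acc = cohort_accuracy(trials).merge(
        exclusions[["subject_id", "excluded"]], on="subject_id")
    means = acc.groupby("excluded")["accuracy"].mean()
    t, p_t = stats.ttest_ind(acc.loc[acc["excluded"], "accuracy"],
                             acc.loc[~acc["excluded"], "accuracy"],
                             equal_var=False)
    print(f"\nchoice accuracy: flagged {means.get(True, float('nan')):.2f} "
          f"vs retained {means.get(False, float('nan')):.2f} "
          f"(Welch t = {t:.1f}, p = {p_t:.2g})")

    curves = learning_curves(trials)
    curves.to_csv(OUT / "learning_curves.csv", index=False)

    retained = trials[~trials["subject_id"].isin(
        exclusions.loc[exclusions["excluded"], "subject_id"])]
    print(f"\nfitting choice regression on "
          f"{retained['subject_id'].nunique()} retained subjects ...")
    res = fit_choice_regression(retained)
    res.terms.to_csv(OUT / "regression_terms.csv", index=False)
    key_terms = ["block", "block:trial_lin", "block:trial_lin:age_lin",
                 "age_lin"]
    print(res.terms.set_index("term").loc[key_terms, ["estimate", "z", "p"]]
          .round(3).to_string())
    print(f"random-intercept sd = {res.random_intercept_sd:.3f}; "
          f"converged = {res.converged}")

    # published tables, recomputed
    stat, df, p = chi_square_independence([[21, 26, 16], [10, 13, 19]])
    print(f"\npublished exclusion table: chi2({df}) = {stat:.1f}, p = {p:.2f}")
    stat, df, p = chi_square_independence([[18, 25, 28], [13, 14, 7]])
    print(f"published learner table:   chi2({df}) = {stat:.1f}, p = {p:.2f}")


if __name__ == "__main__":
    main()
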