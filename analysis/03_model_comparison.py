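"""Hierarchical fits of all seven learning models, per age group.

Fits the RL models (single rate, asymmetric rates, nonlinear utility)
and the Bayesian ideal-observer models (single rate, asymmetric rates,
nonlinear utility, uncertainty bonus) to each age group's retained
subjects and tabulates ΔDIC relative to the worst model per group.
"""

from pathlib import Path

import pandas as pd

from riskylearn.behavior_stats import exclusion_report
from riskylearn.bayes_inference import MCMCConfig, delta_dic, fit_hierarchical
from riskylearn.task_engine import AGE_GROUPS, read_trials_csv

OUT = Path(__file__).resolve().parent.parent / "results"
LEARNING_MODELS = ["m1a", "m1b", "m1c", "m2a", "m2b", "m2c", "m2d"]
CONFIG = MCMCConfig(chains=2, warmup=1200, draws=1000, seed=17)


def main() -> None:
    trials = read_trials_csv(OUT / "trials.csv")
    exclusions = exclusion_report(trials)
    retained = trials[~trials["subject_id"].isin(
        exclusions.loc[exclusions["excluded"], "subject_id"])]

    tables = []
    for group in AGE_GROUPS:
        fits = []
        n = retained.loc[retained["age_group"] == group,
                         "subject_id"].nunique()
        print(f"\n== {group} ({n} retained subjects) ==")
        for model in LEARNING_MODELS:
            fit = fit_hierarchical(model, retained, CONFIG, group=group)
            fits.append(fit)
            print(f"  {model}: DIC {fit.dic:8.1f}  (pD {fit.p_d:5.1f}, "
                  f"converged={fit.converged})")
        table = delta_dic(fits)
        tables.append(table)
        best = table.iloc[0]
        print(f"  winner: {best['model']} "
              f"(ΔDIC {best['delta_dic']:.1f} above worst)")

    pd.concat(tables).to_csv(OUT / "dic_table.csv", index=False)
    print(f"\nwrote {OUT/'dic_table.csv'}")


if __name__ == "__main__":
    main()
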