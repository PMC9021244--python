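# riskylearn

Simulation and analysis of a two-option experience-based risk-taking
task: on every trial an agent chooses between a **sure** option that
always pays 10 cents and a **risky** option that pays 20 or 0 cents
with an unknown win probability that must be learned from feedback.
Across 10 blocks of 20 trials the risky option's expected value is
below (6 cents), equal to (10) or above (14) the sure option's, which
separates *learning to recognize advantageous risk* from overall
risk-taking tendency.

The package is aimed at computational cognitive modellers and
developmental decision scientists. It provides:

* **task_engine** — block schedules, predetermined outcome tapes
  (exactly `10·p` wins per ten risky choices), trial records, CSV I/O
  and dataset validation;
* **agent_models** — ten strategy models: Q-learning with constant
  learning rate (single rate α; asymmetric α₊/α₋; nonlinear utility
  `u(o) = 10(o/10)^κ`), beta-binomial Bayesian ideal observers whose
  effective learning rate `π/(a+b+π)` decays with accumulating
  evidence (single rate π; asymmetric π₊/π₋; utility; uncertainty
  bonus `φ·20·sd(p)`), two gambler's-fallacy models (the winning
  learners with negative rates, so wins *lower* the risky value), and
  an outcome-insensitive ε-risky chooser — all under a softmax policy
  `P(risky) = 1/(1+e^{−β(v−10)})`;
* **synthetic_cohort** — a generator for study-like cohorts (31 early
  adolescents, 39 mid-late adolescents, 35 adults) with heterogeneous
  strategy use and group-level parameter hierarchies;
* **behavior_stats** — the win-switch exclusion rule (rate > 30%
  flags gambler's-fallacy-like behavior), choice accuracy, learning
  curves, the multilevel logistic choice regression, and Pearson χ²
  prevalence tests;
* **bayes_inference** — hierarchical Bayesian fitting (probit-mapped
  Normal hierarchies, numba-compiled adaptive Metropolis-within-Gibbs),
  DIC/ΔDIC model comparison, posterior medians and 95% HDIs;
* **mixture_recovery** — a 5-component latent-mixture strategy
  classifier plus model- and parameter-recovery harnesses.

## Worked example

The numbered scripts under `analysis/` run the full pipeline on a
synthetic cohort and write their tables to `results/`:

```sh
python analysis/01_simulate_cohort.py      # trials.csv + ground truth
python analysis/02_behavioral_analyses.py  # exclusions, curves, regression
python analysis/03_model_comparison.py     # 7-model DIC table per group
python analysis/04_mixture_classification.py
python analysis/05_recovery.py
```

`01` simulates 105 subjects / 21 000 trials. `02` then prints:

```
win-switch exclusions per age group:
           sum  count
adult        8     35
early        6     31
midlate      8     39
choice accuracy: flagged 0.46 vs retained 0.62 (Welch t = -4.6, p = 2.7e-05)
                         estimate       z      p
block                       0.777  34.704  0.000
block:trial_lin             1.161  11.573  0.000
block:trial_lin:age_lin     0.219   1.685  0.092
published exclusion table: chi2(2) = 4.5, p = 0.11
published learner table:   chi2(2) = 4.0, p = 0.14
```

Subjects flagged by the win-switch rule perform at chance (0.46) while
retained subjects learn (0.62); risky choice increases strongly with
the risky option's EV (`block`, z = 34.7) and that effect grows over
trials (`block:trial_lin`, z = 11.6) — the signature of
experience-based optimization. The two `chi2` lines recompute the
published contingency statistics exactly from the printed counts.

`04` classifies every subject's strategy (no prior exclusion):

```
modal assignment matches true strategy for 81% of subjects
learner prevalence across groups: chi2(2) = 2.2, p = 0.33
RL vs ideal-observer among learners: chi2(2) = 9.9, p = 0.01
mean win-switch rate: GF-assigned 0.32 vs learner-assigned 0.06
```

The learner share does not differ across age groups, but *which*
learning family wins does: adolescent learners are mostly constant-rate
RL, adult learners mostly Bayesian observers with decaying rates —
and the mixture separates genuine gambler's-fallacy play (high
win-switch rates) from noisy learning. `03` reproduces the same
gradient at the model-comparison level: RL models take the best ΔDIC
in both adolescent groups, ideal-observer models in the adults.

A one-line simulation is also available from the shell:

```sh
riskylearn simulate --seed 11 --out trials.csv --manifest manifest.csv
riskylearn exclude trials.csv --out exclusions.csv
riskylearn fit trials.csv --model m1c --group early --out fit.json
riskylearn mixture trials.csv --out assignments.csv
```

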