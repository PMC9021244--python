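"""Preregistered behavioral analyses.

* Win-switch exclusion: a subject who switches to the sure option on
  more than 30% of the trials immediately following a risky win is
  flagged as showing gambler's-fallacy-like behavior.
* Choice accuracy: proportion of highest-EV choices over the
  advantageous and disadvantageous blocks (neutral blocks excluded).
* Learning curves: mean risky-choice proportion per trial x block type
  x age group, with the SEM over subjects.
* Multilevel logistic regression of single-trial choice on block type
  (-1/0/+1), trial (orthogonal linear + quadratic), age group (linear
  and quadratic contrasts) and their full factorial interactions, with
  a random intercept per subject.
* Pearson chi-square tests of independence (no continuity correction)
  for strategy-prevalence contingency tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task_engine import AGE_GROUPS

EXCLUSION_THRESHOLD = 0.30

_BLOCK_CODE = {"dis": -1.0, "neu": 0.0, "adv": 1.0}
_AGE_LINEAR = {"early": -1.0, "midlate": 0.0, "adult": 1.0}
_AGE_QUAD = {"early": 1.0, "midlate": -2.0, "adult": 1.0}


def win_switch_rate(records: pd.DataFrame) -> tuple[float, int]:
    """(rate, n eligible win trials) for one subject.

    Eligible pairs are consecutive trials (t, t+1) within a block where
    trial t was a risky win; the rate is the fraction of those followed
    by a sure choice. NaN (and never an exclusion) when the subject has
    no risky wins with a successor trial.
    """
    df = records.sort_values(["block", "trial"])
    numer = 0
    denom = 0
    for _, blk in df.groupby("block"):
        choice = blk["choice"].to_numpy()
        outcome = blk["outcome"].to_numpy()
        win = (choice[:-1] == "risky") & (outcome[:-1] == 20)
        denom += int(win.sum())
        numer += int((win & (choice[1:] == "sure")).sum())
    if denom == 0:
        return float("nan"), 0
    return numer / denom, denom


def exclusion_report(records: pd.DataFrame,
                     threshold: float = EXCLUSION_THRESHOLD) -> pd.DataFrame:
    """Per-subject win-switch rates and exclusion flags."""
    rows = []
    for subject, grp in records.groupby("subject_id", sort=False):
        rate, n_wins = win_switch_rate(grp)
        rows.append({
            "subject_id": subject,
            "age_group": grp["age_group"].iloc[0],
            "win_switch_rate": rate,
            "n_win_trials": n_wins,
            "excluded": bool(n_wins >= 1 and rate > threshold),
            "threshold": threshold,
        })
    return pd.DataFrame(rows)


def choice_accuracy(records: pd.DataFrame) -> float:
    """Proportion of highest-EV choices for one subject.

    Correct = sure in disadvantageous blocks, risky in advantageous
    blocks; neutral blocks (equal EVs) are excluded entirely.
    """
    df = records[records["block_type"] != "neu"]
    if df.empty:
        return float("nan")
    correct = np.where(df["block_type"] == "adv",
                       df["choice"] == "risky",
                       df["choice"] == "sure")
    return float(np.mean(correct))


def cohort_accuracy(records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject accuracy table for a whole cohort."""
    rows = [{"subject_id": s, "age_group": g["age_group"].iloc[0],
             "accuracy": choice_accuracy(g)}
            for s, g in records.groupby("subject_id", sort=False)]
    return pd.DataFrame(rows)


def learning_curves(records: pd.DataFrame) -> pd.DataFrame:
    """Mean risky proportion per trial x block type x age group.

    Each subject first contributes one proportion per (block type,
    trial) cell (averaging over their blocks of that type); the table
    reports the mean and SEM of those proportions over subjects.
    """
    df = records.copy()
    df["risky"] = (df["choice"] == "risky").astype(float)
    per_subject = (df.groupby(["age_group", "block_type", "trial",
                               "subject_id"])["risky"].mean())
    out = per_subject.groupby(["age_group", "block_type", "trial"]).agg(
        mean_risky="mean", sem="sem", n_subjects="count").reset_index()
    return out


@dataclass
class RegressionResult:
    """Fixed-effect table of the multilevel logistic regression."""

    terms: pd.DataFrame            # term, estimate, se, z, p
    random_intercept_sd: float
    converged: bool

    @property
    def random_intercept_variance(self) -> float:
        return self.random_intercept_sd ** 2

    def term(self, name: str) -> pd.Series:
        return self.terms.set_index("term").loc[name]


def orthogonal_trial_poly(trials: np.ndarray) -> np.ndarray:
    """Orthonormal linear and quadratic trend codes over trials 1..20,
    as R's poly() produces (decorrelated trend terms)."""
    levels = np.arange(1, 21, dtype=float)
    X = np.column_stack([np.ones_like(levels), levels, levels**2])
    Q, _ = np.linalg.qr(X)
    # fix sign: linear increasing, quadratic positive at the ends
    lin = Q[:, 1] * np.sign(Q[-1, 1])
    quad = Q[:, 2] * np.sign(Q[-1, 2])
    idx = trials.astype(int) - 1
    return np.column_stack([lin[idx], quad[idx]])


def regression_design(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray,
                                                      list[str], np.ndarray]:
    """(y, X, term names, subject index) for the choice regression.

    Full factorial of {1, block} x {1, trial_lin, trial_quad} x
    {1, age_lin, age_quad} — 18 columns including the intercept.
    """
    df = records
    y = (df["choice"] == "risky").to_numpy(float)
    bt = df["block_type"].map(_BLOCK_CODE).to_numpy()
    trial_codes = orthogonal_trial_poly(df["trial"].to_numpy())
    age_lin = df["age_group"].map(_AGE_LINEAR).to_numpy()
    age_quad = df["age_group"].map(_AGE_QUAD).to_numpy()

    block_parts = [("", np.ones(len(df))), ("block", bt)]
    trial_parts = [("", np.ones(len(df))), ("trial_lin", trial_codes[:, 0]),
                   ("trial_quad", trial_codes[:, 1])]
    age_parts = [("", np.ones(len(df))), ("age_lin", age_lin),
                 ("age_quad", age_quad)]

    cols, names = [], []
    for bn, bv in block_parts:
        for tn, tv in trial_parts:
            for an, av in age_parts:
                label = ":".join([p for p in (bn, tn, an) if p]) or "intercept"
                names.append(label)
                cols.append(bv * tv * av)
    X = np.column_stack(cols)
    subjects = pd.factorize(df["subject_id"])[0]
    return y, X, names, subjects


def fit_choice_regression(records: pd.DataFrame) -> RegressionResult:
    """Random-intercept logistic regression on single-trial choices.

    Fit with a variational Bayesian mixed GLM; reported z statistics
    are posterior mean / posterior sd Wald-type statistics with
    two-sided Normal p values.
    """
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    for g in AGE_GROUPS:
        n = records.loc[records["age_group"] == g, "subject_id"].nunique()
        if n < 2:
            raise ValueError(f"need >= 2 subjects per age group, {g} has {n}")

    y, X, names, subjects = regression_design(records)
    n_sub = subjects.max() + 1
    exog_vc = np.zeros((len(y), n_sub))
    exog_vc[np.arange(len(y)), subjects] = 1.0
    ident = np.zeros(n_sub, dtype=int)

    model = BinomialBayesMixedGLM(y, X, exog_vc, ident,
                                  fe_p=2.0, vcp_p=2.0)
    converged = True
    import warnings as _warnings
    try:
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            fit = model.fit_vb()
        if any("did not converge" in str(w.message) for w in caught):
            converged = False
    except Exception:
        # map estimation as a fallback surface, flagged as non-converged
        converged = False
        fit = model.fit_map()
    est = fit.fe_mean
    se = fit.fe_sd
    z = est / se
    p = 2 * stats.norm.sf(np.abs(z))
    terms = pd.DataFrame({"term": names, "estimate": est, "se": se,
                          "z": z, "p": p})
    ri_sd = float(np.exp(fit.vcp_mean[0]))
    return RegressionResult(terms=terms, random_intercept_sd=ri_sd,
                            converged=converged)


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction.

    Returns (statistic, df, p). Zero marginal rows/columns rejected.
    """
    arr = np.asarray(table, float)
    if arr.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal row or column")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
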