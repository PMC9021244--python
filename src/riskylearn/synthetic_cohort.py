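"""Synthetic cohorts with the statistical structure the analyses assume.

Three age groups — early adolescents (n=31), mid-late adolescents
(n=39) and adults (n=35) — each a mixture of strategy users: learners
(RL with nonlinear utility, or Bayesian ideal observers with two update
rates), gambler's-fallacy players, and outcome-insensitive epsilon
choosers. Subject-level parameters are drawn from group-level Normal
distributions on an unconstrained scale and mapped through a scaled
probit into each parameter's box, mirroring the hierarchy the fitting
stage assumes.

Default group settings encode the qualitative ordering reported for
this task family: early adolescents have the highest constant learning
rate and the lowest inverse temperature, adults mostly use the Bayesian
observer with a decaying effective learning rate and a higher inverse
temperature, and adolescents overvalue the 20-cent win (kappa > 1).
Learner prevalence follows the published mixture counts (18/31, 25/39,
28/35); the numeric parameter values are scenario choices, configurable
per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .agent_models import MIXTURE_COMPONENTS, MODELS, ModelSpec, ParamSet
from .task_engine import (make_block_schedule, records_to_frame,
                          session_tapes)


def map_to_box(z, lo, hi):
    """Scaled probit: unconstrained score -> value in (lo, hi)."""
    return lo + (hi - lo) * norm.cdf(z)


def unbox(value, lo, hi):
    """Inverse of :func:`map_to_box`."""
    return norm.ppf((np.asarray(value, float) - lo) / (hi - lo))


def loc_for(model: str, **natural: float) -> dict[str, float]:
    """Unconstrained locations whose probit image hits the given
    natural-scale values."""
    spec = MODELS[model]
    out = {}
    for name, value in natural.items():
        i = spec.param_names.index(name)
        out[name] = float(unbox(value, spec.lo[i], spec.hi[i]))
    return out


@dataclass
class GroupSpec:
    """One age group: size, strategy mix, and parameter hierarchy.

    ``param_locs[strategy][param]`` and ``param_sds[strategy][param]``
    are the group-level mean and sd of the unconstrained subject score
    for that parameter; missing entries fall back to loc 0, sd 0.4.
    """

    age_group: str
    n_subjects: int
    strategy_weights: dict[str, float]
    param_locs: dict[str, dict[str, float]] = field(default_factory=dict)
    param_sds: dict[str, dict[str, float]] = field(default_factory=dict)
    default_sd: float = 0.4

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        total = sum(self.strategy_weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"strategy weights sum to {total}, not 1")

    def loc_sd(self, strategy: str, param: str) -> tuple[float, float]:
        loc = self.param_locs.get(strategy, {}).get(param, 0.0)
        sd = self.param_sds.get(strategy, {}).get(param, self.default_sd)
        return loc, sd


@dataclass
class CohortSpec:
    groups: list[GroupSpec]
    master_seed: int = 0


def sample_subject_params(group: GroupSpec, strategy: ModelSpec,
                          seed: int) -> ParamSet:
    """Draw one subject's parameters from the group hierarchy."""
    rng = np.random.default_rng(seed)
    values = []
    for i, name in enumerate(strategy.param_names):
        loc, sd = group.loc_sd(strategy.name, name)
        z = loc + sd * rng.standard_normal()
        values.append(map_to_box(z, strategy.lo[i], strategy.hi[i]))
    return ParamSet.from_vector(strategy, values).with_q1_from_a1()


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every subject; returns (trials, manifest).

    The manifest records each subject's true strategy and true
    parameters — the ground truth for recovery analyses. Byte-identical
    output for identical master seeds.
    """
    records = []
    manifest_rows = []
    ss = np.random.SeedSequence(spec.master_seed)
    children = iter(ss.spawn(sum(g.n_subjects for g in spec.groups)))
    for group in spec.groups:
        names = sorted(group.strategy_weights)
        weights = np.array([group.strategy_weights[k] for k in names])
        for i in range(group.n_subjects):
            rng = np.random.default_rng(next(children))
            strategy_name = names[rng.choice(len(names), p=weights)]
            strategy = MODELS[strategy_name]
            seeds = rng.integers(2**31, size=4)
            params = sample_subject_params(group, strategy, int(seeds[0]))
            schedule = make_block_schedule(int(seeds[1]))
            tapes = session_tapes(schedule, int(seeds[2]))
            subject_id = f"{group.age_group}_{i + 1:02d}"
            from .agent_models import simulate_agent
            records.extend(simulate_agent(strategy, params, schedule, tapes,
                                          int(seeds[3]), subject_id,
                                          group.age_group))
            row = {"subject_id": subject_id, "age_group": group.age_group,
                   "strategy": strategy_name}
            for name in strategy.param_names:
                row[f"true_{name}"] = getattr(params, name)
            manifest_rows.append(row)
    manifest = pd.DataFrame(manifest_rows)
    return records_to_frame(records), manifest


# --- default study-like scenario -------------------------------------------

_COUNTS = {
    # (gf_rl, gf_bio, m1c, m2b, eps) per group; learners follow the
    # published assignment counts 18/31, 25/39, 28/35
    "early": (7, 2, 14, 4, 4),
    "midlate": (7, 3, 17, 8, 4),
    "adult": (3, 2, 8, 20, 2),
}

_GROUP_BETA = {"early": 1.0, "midlate": 1.2, "adult": 2.0}

_NATURAL = {
    "early": {
        "m1c": dict(alpha=0.35, kappa=1.4, beta=1.0, q1=12.0),
        "m2b": dict(pi_pos=1.2, pi_neg=1.2, beta=1.0, a1=1.2),
    },
    "midlate": {
        "m1c": dict(alpha=0.15, kappa=1.3, beta=1.2, q1=12.0),
        "m2b": dict(pi_pos=1.0, pi_neg=1.0, beta=1.2, a1=1.2),
    },
    "adult": {
        "m1c": dict(alpha=0.12, kappa=1.05, beta=2.0, q1=12.0),
        "m2b": dict(pi_pos=1.0, pi_neg=1.0, beta=2.0, a1=1.3),
    },
}


def default_group_spec(age_group: str, n_subjects: int | None = None,
                       default_sd: float = 0.4) -> GroupSpec:
    counts = _COUNTS[age_group]
    n = n_subjects if n_subjects is not None else sum(counts)
    weights = {name: c / sum(counts)
               for name, c in zip(MIXTURE_COMPONENTS, counts)}
    beta = _GROUP_BETA[age_group]
    locs = {
        "m1c": loc_for("m1c", **_NATURAL[age_group]["m1c"]),
        "m2b": loc_for("m2b", **_NATURAL[age_group]["m2b"]),
        "gf_rl": loc_for("gf_rl", alpha=-0.4, kappa=1.1, beta=beta, q1=12.0),
        "gf_bio": loc_for("gf_bio", pi_pos=-1.0, pi_neg=-1.0, beta=beta,
                          a1=1.2),
        "eps": loc_for("eps", epsilon=0.5),
    }
    sds = {"eps": {"epsilon": 0.8}}
    return GroupSpec(age_group=age_group, n_subjects=n,
                     strategy_weights=weights, param_locs=locs,
                     param_sds=sds, default_sd=default_sd)


def default_cohort_spec(master_seed: int = 0) -> CohortSpec:
    """The study-like scenario: 31 early, 39 mid-late, 35 adults."""
    return CohortSpec(groups=[default_group_spec(g)
                              for g in ("early", "midlate", "adult")],
                      master_seed=master_seed)


# --- config (de)serialization ----------------------------------------------

def cohort_spec_to_dict(spec: CohortSpec) -> dict:
    return {
        "master_seed": spec.master_seed,
        "groups": [
            {
                "age_group": g.age_group,
                "n_subjects": g.n_subjects,
                "strategy_weights": dict(g.strategy_weights),
                "param_locs": {k: dict(v) for k, v in g.param_locs.items()},
                "param_sds": {k: dict(v) for k, v in g.param_sds.items()},
                "default_sd": g.default_sd,
            }
            for g in spec.groups
        ],
    }


def cohort_spec_from_dict(d: dict) -> CohortSpec:
    groups = [GroupSpec(**g) for g in d["groups"]]
    return CohortSpec(groups=groups, master_seed=d.get("master_seed", 0))


def load_cohort_spec(path) -> CohortSpec:
    with open(path) as fh:
        return cohort_spec_from_dict(yaml.safe_load(fh))


def save_cohort_spec(spec: CohortSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cohort_spec_to_dict(spec), fh, sort_keys=False)
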