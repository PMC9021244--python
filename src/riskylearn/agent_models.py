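"""The ten candidate strategy models and their likelihoods.

Two learning families estimate the risky option's value from experienced
outcomes:

* Reinforcement learning (RL): a point value Q updated by a delta rule
  with constant learning rate, ``Q' = Q + alpha * (u(outcome) - Q)``.
* Bayesian ideal observer (BIO): a Beta(a, b) belief over the win
  probability; wins add ``pi_pos`` to a, no-wins add ``pi_neg`` to b, so
  the effective learning rate ``pi / (a + b + pi)`` decays as evidence
  accumulates.

Risk sensitivity enters through asymmetric rates (win vs. no-win), a
nonlinear utility ``u(o) = 10 * (o/10)**kappa`` (kappa > 1 overvalues
the 20-cent win), or — BIO only — an uncertainty bonus/penalty
``phi * 20 * sd(p)``. Two gambler's-fallacy variants are the same
machinery with sign-flipped rates: wins *lower* the risky option's
value. The epsilon-risky model ignores outcomes entirely and chooses
risky with fixed probability epsilon.

All learning models share a softmax policy on the value difference with
the 10-cent sure option: ``P(risky) = logistic(beta * (v_risky - 10))``.
Values are on the cents scale, so beta is in inverse cents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from ._kernels import BETA_FLOOR, C1
from .task_engine import (N_TRIALS, OutcomeTape, TapeReader, TrialRecord,
                          records_to_frame)

V_SURE = 10.0


@dataclass(frozen=True)
class ModelSpec:
    """Identity of one strategy model and the box of its parameters."""

    name: str
    family: str   # RL | BIO | GF_RL | GF_BIO | EPS
    variant: str  # basic | asymmetric | utility | uncertainty | none
    param_names: tuple[str, ...]
    lo: tuple[float, ...]
    hi: tuple[float, ...]
    model_id: int

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def is_learner(self) -> bool:
        return self.family in ("RL", "BIO")

    def box(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.lo, float), np.asarray(self.hi, float)


#: registry keyed by canonical model name
MODELS: dict[str, ModelSpec] = {
    "m1a": ModelSpec("m1a", "RL", "basic",
                     ("alpha", "beta", "q1"),
                     (0.0, 0.0, 0.0), (1.0, 10.0, 20.0), _kernels.M1A),
    "m1b": ModelSpec("m1b", "RL", "asymmetric",
                     ("alpha_pos", "alpha_neg", "beta", "q1"),
                     (0.0, 0.0, 0.0, 0.0), (1.0, 1.0, 10.0, 20.0),
                     _kernels.M1B),
    "m1c": ModelSpec("m1c", "RL", "utility",
                     ("alpha", "kappa", "beta", "q1"),
                     (0.0, 0.0, 0.0, 0.0), (1.0, 3.0, 10.0, 20.0),
                     _kernels.M1C),
    "m2a": ModelSpec("m2a", "BIO", "basic",
                     ("pi", "beta", "a1"),
                     (0.0, 0.0, 0.0), (5.0, 10.0, C1), _kernels.M2A),
    "m2b": ModelSpec("m2b", "BIO", "asymmetric",
                     ("pi_pos", "pi_neg", "beta", "a1"),
                     (0.0, 0.0, 0.0, 0.0), (5.0, 5.0, 10.0, C1),
                     _kernels.M2B),
    "m2c": ModelSpec("m2c", "BIO", "utility",
                     ("pi", "kappa", "beta", "a1"),
                     (0.0, 0.0, 0.0, 0.0), (5.0, 3.0, 10.0, C1),
                     _kernels.M2C),
    "m2d": ModelSpec("m2d", "BIO", "uncertainty",
                     ("pi", "phi", "beta", "a1"),
                     (0.0, -5.0, 0.0, 0.0), (5.0, 5.0, 10.0, C1),
                     _kernels.M2D),
    "gf_rl": ModelSpec("gf_rl", "GF_RL", "utility",
                       ("alpha", "kappa", "beta", "q1"),
                       (-1.0, 0.0, 0.0, 0.0), (0.0, 3.0, 10.0, 20.0),
                       _kernels.GF_RL),
    "gf_bio": ModelSpec("gf_bio", "GF_BIO", "asymmetric",
                        ("pi_pos", "pi_neg", "beta", "a1"),
                        (-5.0, -5.0, 0.0, 0.0), (0.0, 0.0, 10.0, C1),
                        _kernels.GF_BIO),
    "eps": ModelSpec("eps", "EPS", "none",
                     ("epsilon",), (0.0,), (1.0,), _kernels.EPS),
}

#: components of the latent mixture, in fixed tie-break order
MIXTURE_COMPONENTS = ("gf_rl", "gf_bio", "m1c", "m2b", "eps")


@dataclass(frozen=True)
class ParamSet:
    """Natural-scale parameter values; only the fields a ModelSpec names
    are meaningful. For BIO-family models the initial risky value is
    q1 = 20 * a1 / c1 with fixed concentration c1 = 2."""

    alpha: float | None = None
    alpha_pos: float | None = None
    alpha_neg: float | None = None
    pi: float | None = None
    pi_pos: float | None = None
    pi_neg: float | None = None
    kappa: float | None = None
    phi: float | None = None
    beta: float | None = None
    q1: float | None = None
    a1: float | None = None
    epsilon: float | None = None

    def to_vector(self, spec: ModelSpec) -> np.ndarray:
        vals = []
        for name in spec.param_names:
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"parameter {name!r} required by {spec.name}")
            vals.append(float(v))
        return np.asarray(vals)

    @staticmethod
    def from_vector(spec: ModelSpec, vec) -> "ParamSet":
        return ParamSet(**dict(zip(spec.param_names, map(float, vec))))

    def with_q1_from_a1(self) -> "ParamSet":
        if self.a1 is None:
            return self
        return replace(self, q1=20.0 * self.a1 / C1)


@dataclass
class BeliefState:
    """Current valuation of the risky option.

    RL families hold a point value ``q``; BIO families hold Beta
    pseudo-counts ``a, b`` (kept > 0 by a floor). The sure option's
    value is known and never part of the state.
    """

    q: float | None = None
    a: float | None = None
    b: float | None = None


def utility(outcome: float, kappa: float) -> float:
    """Subjective utility 10 * (outcome/10)**kappa; u(0)=0, u(10)=10."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return 10.0 * (outcome / 10.0) ** kappa


def init_belief(spec: ModelSpec, params: ParamSet) -> BeliefState:
    """Fresh belief at the start of a block (a new risky vase)."""
    if spec.family in ("RL", "GF_RL"):
        if params.q1 is None:
            raise ValueError("q1 required for RL-family models")
        return BeliefState(q=float(params.q1))
    if spec.family in ("BIO", "GF_BIO"):
        if params.a1 is None:
            raise ValueError("a1 required for BIO-family models")
        return BeliefState(a=float(params.a1), b=C1 - float(params.a1))
    return BeliefState()


def _rates(params: ParamSet, spec: ModelSpec) -> tuple[float, float]:
    if spec.variant == "asymmetric":
        if spec.family in ("RL",):
            return float(params.alpha_pos), float(params.alpha_neg)
        return float(params.pi_pos), float(params.pi_neg)
    if spec.family in ("RL", "GF_RL"):
        return float(params.alpha), float(params.alpha)
    return float(params.pi), float(params.pi)


def _kappa(params: ParamSet, spec: ModelSpec) -> float:
    return float(params.kappa) if spec.variant == "utility" else 1.0


def rl_update(state: BeliefState, outcome: int, params: ParamSet,
              spec: ModelSpec) -> BeliefState:
    """Delta-rule update after a risky outcome (sure outcomes rejected)."""
    if spec.family not in ("RL", "GF_RL"):
        raise ValueError(f"rl_update does not apply to family {spec.family}")
    if outcome not in (0, 20):
        raise ValueError("only risky outcomes (0 or 20 cents) update beliefs")
    rate_w, rate_l = _rates(params, spec)
    rate = rate_w if outcome == 20 else rate_l
    u = utility(outcome, _kappa(params, spec))
    return BeliefState(q=state.q + rate * (u - state.q))


def bio_update(state: BeliefState, outcome: int, params: ParamSet,
               spec: ModelSpec) -> BeliefState:
    """Beta pseudo-count update after a risky outcome; floored at 0.001."""
    if spec.family not in ("BIO", "GF_BIO"):
        raise ValueError(f"bio_update does not apply to family {spec.family}")
    if outcome not in (0, 20):
        raise ValueError("only risky outcomes (0 or 20 cents) update beliefs")
    rate_w, rate_l = _rates(params, spec)
    if outcome == 20:
        return BeliefState(a=max(state.a + rate_w, BETA_FLOOR), b=state.b)
    return BeliefState(a=state.a, b=max(state.b + rate_l, BETA_FLOOR))


def belief_update(state: BeliefState, outcome: int, params: ParamSet,
                  spec: ModelSpec) -> BeliefState:
    if spec.family in ("RL", "GF_RL"):
        return rl_update(state, outcome, params, spec)
    if spec.family in ("BIO", "GF_BIO"):
        return bio_update(state, outcome, params, spec)
    return state  # epsilon-risky carries no belief


def risky_value(state: BeliefState, params: ParamSet,
                spec: ModelSpec) -> float:
    """Cents-equivalent value of the risky option under the model."""
    if spec.family in ("RL", "GF_RL"):
        return float(state.q)
    kappa = _kappa(params, spec)
    mu = state.a / (state.a + state.b)
    v = utility(20.0, kappa) * mu
    if spec.variant == "uncertainty":
        n = state.a + state.b
        sd = math.sqrt(state.a * state.b / (n * n * (n + 1.0)))
        v += float(params.phi) * 20.0 * sd
    return v


def effective_learning_rate(state: BeliefState, pi: float) -> float:
    """Per-trial learning rate implied by a BIO belief: pi/(a+b+pi).

    The Beta posterior mean moves by this fraction toward the observed
    outcome (coded 0/1), so it decays as pseudo-counts accumulate.
    """
    return pi / (state.a + state.b + pi)


def choice_prob(v_risky: float, v_sure: float, beta: float) -> float:
    """Softmax (logistic) probability of the risky choice."""
    if beta < 0:
        raise ValueError("inverse temperature must be non-negative")
    x = beta * (v_risky - v_sure)
    return math.exp(_kernels._log_sigmoid(x))


def epsilon_prob(params: ParamSet) -> float:
    """History-independent risky-choice probability of the eps model."""
    if not 0 < params.epsilon < 1:
        raise ValueError("epsilon must lie strictly in (0, 1)")
    return float(params.epsilon)


def risky_choice_prob(state: BeliefState, params: ParamSet,
                      spec: ModelSpec) -> float:
    if spec.family == "EPS":
        return epsilon_prob(params)
    return choice_prob(risky_value(state, params, spec), V_SURE,
                       float(params.beta))


def simulate_agent(spec: ModelSpec, params: ParamSet, schedule: list[str],
                   tapes: list[OutcomeTape], seed: int,
                   subject_id: str = "s01",
                   age_group: str = "adult") -> list[TrialRecord]:
    """Play one full session: 10 blocks x 20 trials.

    The belief re-initializes at every block (a new risky vase); risky
    choices consume the block's outcome tape, sure choices pay 10 cents
    and leave both the tape and the belief untouched.
    """
    rng = np.random.default_rng(seed)
    records: list[TrialRecord] = []
    for b, (label, tape) in enumerate(zip(schedule, tapes), start=1):
        state = init_belief(spec, params)
        reader = TapeReader(tape)
        for t in range(1, N_TRIALS + 1):
            p = risky_choice_prob(state, params, spec)
            risky = rng.random() < p
            if risky:
                outcome = reader.draw()
                state = belief_update(state, outcome, params, spec)
            else:
                outcome = 10
            records.append(TrialRecord(subject_id, age_group, b, label, t,
                                       "risky" if risky else "sure", outcome))
    return records


def subject_arrays(records) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(choices, outcomes, resets) int8 arrays for one subject,
    ordered by block then trial; rejects incomplete blocks."""
    if isinstance(records, list):
        df = records_to_frame(records)
    else:
        df = records
    if df["subject_id"].nunique() > 1:
        raise ValueError("records must belong to a single subject")
    counts = df.groupby("block")["trial"].nunique()
    if (counts != N_TRIALS).any():
        bad = counts[counts != N_TRIALS].index.tolist()
        raise ValueError(f"incomplete blocks: {bad}")
    df = df.sort_values(["block", "trial"])
    choices = (df["choice"] == "risky").to_numpy(np.int8)
    outcomes = df["outcome"].to_numpy(np.int8)
    resets = (df["trial"] == 1).to_numpy(np.int8)
    return choices, outcomes, resets


def log_likelihood(spec: ModelSpec, params: ParamSet, records) -> float:
    """Exact log probability of a subject's observed choices.

    Sum over trials of log P(choice_t | belief before trial t), with the
    belief reset at each block boundary. Evaluated by the same kernel
    the hierarchical sampler uses.
    """
    choices, outcomes, resets = subject_arrays(records)
    theta = params.to_vector(spec)
    return float(_kernels.seq_loglik(spec.model_id, theta,
                                     choices, outcomes, resets))
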