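"""Structure of the experience-based risk-taking task.

Participants (or simulated agents) choose repeatedly between a *sure*
option that always pays 10 cents and a *risky* option that pays 20 or 0
cents with an unknown win probability. The task comprises 10 blocks of
20 trials; a fresh risky option is introduced in every block. The win
probability of the risky option is 0.3 in four blocks (risk
disadvantageous, EV 6 cents), 0.7 in four blocks (risk advantageous, EV
14 cents), and 0.5 in two blocks (risk neutral, EV 10 cents).

Outcomes are not i.i.d. draws: each block carries a predetermined
*outcome tape* in which every window of ten successive risky choices
contains exactly ``10 * win_prob`` wins, in random order. The tape is
consumed only by risky choices; sure choices do not advance it.

All block and trial indices are 1-based in data files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_BLOCKS = 10
N_TRIALS = 20

SURE_PAYOFF = 10
RISKY_WIN = 20
RISKY_LOSS = 0

#: block-type label -> (win probability, number of blocks in a session)
BLOCK_TYPES = {
    "dis": (0.3, 4),
    "neu": (0.5, 2),
    "adv": (0.7, 4),
}

AGE_GROUPS = ("early", "midlate", "adult")

CSV_COLUMNS = [
    "subject_id",
    "age_group",
    "block",
    "block_type",
    "trial",
    "choice",
    "outcome",
]


@dataclass(frozen=True)
class BlockType:
    """One of the three risky-option conditions."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in BLOCK_TYPES:
            raise ValueError(f"unknown block type {self.label!r}")

    @property
    def win_prob(self) -> float:
        return BLOCK_TYPES[self.label][0]

    @property
    def n_blocks(self) -> int:
        return BLOCK_TYPES[self.label][1]

    @property
    def expected_value(self) -> float:
        """Expected value of the risky option in cents (6, 10 or 14)."""
        return RISKY_WIN * self.win_prob


@dataclass(frozen=True)
class OutcomeTape:
    """Predetermined win/no-win sequence for one block.

    ``wins[i]`` is the outcome of the (i+1)-th *risky choice* in the
    block, not of trial i+1: sure choices do not consume the tape.
    """

    block_index: int
    block_type: str
    wins: tuple[int, ...]

    def __post_init__(self) -> None:
        k = int(round(10 * BLOCK_TYPES[self.block_type][0]))
        if len(self.wins) != N_TRIALS:
            raise ValueError("tape must hold 20 entries")
        if sum(self.wins[:10]) != k or sum(self.wins[10:]) != k:
            raise ValueError("each 10-choice window must hold exactly "
                             f"{k} wins for block type {self.block_type!r}")


@dataclass
class TapeReader:
    """Stateful view of a tape, advanced one entry per risky choice."""

    tape: OutcomeTape
    position: int = 0

    def draw(self) -> int:
        """Outcome (cents) of the next risky choice."""
        win = self.tape.wins[self.position]
        self.position += 1
        return RISKY_WIN if win else RISKY_LOSS


@dataclass(frozen=True)
class TrialRecord:
    """One choice/outcome event — the atomic unit of every analysis."""

    subject_id: str
    age_group: str
    block: int
    block_type: str
    trial: int
    choice: str
    outcome: int


def make_block_schedule(seed: int) -> list[str]:
    """Random order of the 10 block types for one session.

    Both the first five and the last five blocks contain exactly one
    neutral, two disadvantageous and two advantageous blocks; within
    each half the order is uniformly random. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    half = ["dis", "dis", "adv", "adv", "neu"]
    first = list(rng.permutation(half))
    second = list(rng.permutation(half))
    return [str(x) for x in first + second]


def make_outcome_tape(block_type: str | BlockType, seed: int,
                      block_index: int = 1) -> OutcomeTape:
    """Random tape for one block: k wins per 10-choice window.

    k = 3, 5 or 7 for disadvantageous, neutral and advantageous blocks;
    each window is an independent uniform shuffle.
    """
    label = block_type.label if isinstance(block_type, BlockType) else block_type
    if label not in BLOCK_TYPES:
        raise ValueError(f"unknown block type {label!r}")
    k = int(round(10 * BLOCK_TYPES[label][0]))
    rng = np.random.default_rng(seed)
    wins: list[int] = []
    for _ in range(2):
        window = [1] * k + [0] * (10 - k)
        wins.extend(int(x) for x in rng.permutation(window))
    return OutcomeTape(block_index=block_index, block_type=label,
                       wins=tuple(wins))


def block_seeds(master_seed: int, n: int = N_BLOCKS) -> list[int]:
    """Per-block tape seeds derived reproducibly from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def session_tapes(schedule: list[str], master_seed: int) -> list[OutcomeTape]:
    """One tape per block of a schedule, seeded block-by-block."""
    seeds = block_seeds(master_seed, len(schedule))
    return [
        make_outcome_tape(label, seed, block_index=i + 1)
        for i, (label, seed) in enumerate(zip(schedule, seeds))
    ]


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records], columns=CSV_COLUMNS)
    return df.astype({"block": int, "trial": int, "outcome": int})


def write_trials_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=CSV_COLUMNS)


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "subject_id": str, "age_group": str, "block": int,
            "block_type": str, "trial": int, "choice": str, "outcome": int,
        },
    )
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV missing columns: {missing}")
    return df[CSV_COLUMNS]


@dataclass
class ValidationReport:
    """Violations found in a trial dataset; empty means well-formed."""

    violations: list[tuple[int, str]] = field(default_factory=list)

    def add(self, row: int, message: str) -> None:
        self.violations.append((row, message))

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)


def validate_dataset(df: pd.DataFrame) -> ValidationReport:
    """Check every record and block invariant; never raises mid-scan.

    Row-level checks: known labels, choice/outcome consistency (sure
    pays 10; risky pays 0 or 20), trial and block ranges. Block-level
    checks: each subject x block holds the complete trial set 1..20
    with a single block type.
    """
    report = ValidationReport()
    for row, rec in df.iterrows():
        if rec["age_group"] not in AGE_GROUPS:
            report.add(row, f"unknown age_group {rec['age_group']!r}")
        if rec["block_type"] not in BLOCK_TYPES:
            report.add(row, f"unknown block_type {rec['block_type']!r}")
        if not 1 <= rec["block"] <= N_BLOCKS:
            report.add(row, f"block {rec['block']} out of range 1..10")
        if not 1 <= rec["trial"] <= N_TRIALS:
            report.add(row, f"trial {rec['trial']} out of range 1..20")
        if rec["choice"] == "sure":
            if rec["outcome"] != SURE_PAYOFF:
                report.add(row, f"sure choice with outcome {rec['outcome']}")
        elif rec["choice"] == "risky":
            if rec["outcome"] not in (RISKY_LOSS, RISKY_WIN):
                report.add(row, f"risky choice with outcome {rec['outcome']}")
        else:
            report.add(row, f"unknown choice {rec['choice']!r}")

    for (subj, block), grp in df.groupby(["subject_id", "block"], sort=False):
        trials = sorted(grp["trial"])
        if trials != list(range(1, N_TRIALS + 1)):
            report.add(int(grp.index[0]),
                       f"incomplete block: subject {subj} block {block} has "
                       f"{len(grp)} trials")
        if grp["block_type"].nunique() > 1:
            report.add(int(grp.index[0]),
                       f"inconsistent block_type in subject {subj} block {block}")
    return report
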