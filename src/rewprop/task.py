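"""Probabilistic selection task (PST) environment.

The PST trains participants on concurrent two-alternative discriminations
(pairs AB and CD) in which each stimulus carries a fixed probability of
"Correct" feedback (A 80% / B 20%; C 70% / D 30%).  Training comprises
``n_blocks`` blocks of ``trials_per_block`` trials (default 4 x 60 = 240),
each block containing equal numbers of AB and CD presentations in shuffled
order.  A feedback-free test phase then presents every pairing of the four
stimuli ``test_reps`` times each.

This module generates schedules and delivers probabilistic feedback; the
behaving agent lives in :mod:`rewprop.agents`.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "TrialRecord",
    "make_training_schedule",
    "make_test_schedule",
    "deliver_feedback",
    "simulate_fixed_choice",
    "trials_to_frame",
]

#: Feedback vocabulary.  Test-phase trials carry ``NO_FEEDBACK``.
CORRECT = "Correct"
INCORRECT = "Incorrect"
NO_FEEDBACK = "none"


@dataclass(frozen=True)
class TaskConfig:
    """Structure of one PST session.

    Parameters
    ----------
    pairs
        Training pairs as (optimal, suboptimal) stimulus labels.
    reward_prob
        Probability of "Correct" feedback for choosing each stimulus.
        Within each training pair the two probabilities must sum to 1.
    n_blocks, trials_per_block
        Training-phase layout; the total trial count is their product.
    test_reps
        Presentations of each distinct stimulus pairing in the test phase.
    seed
        Seed controlling schedule shuffling.
    """

    pairs: tuple[tuple[str, str], ...] = (("A", "B"), ("C", "D"))
    reward_prob: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.8, "B": 0.2, "C": 0.7, "D": 0.3}
    )
    n_blocks: int = 4
    trials_per_block: int = 60
    test_reps: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be positive")
        if self.test_reps < 0:
            raise ValueError("test_reps must be non-negative")
        for stim, p in self.reward_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"reward_prob[{stim!r}]={p} outside [0, 1]")
        for opt, sub in self.pairs:
            for stim in (opt, sub):
                if stim not in self.reward_prob:
                    raise ValueError(f"stimulus {stim!r} has no reward_prob entry")
            total = self.reward_prob[opt] + self.reward_prob[sub]
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"pair {opt}{sub}: reward probabilities must be complementary "
                    f"(got {total})"
                )
            if self.reward_prob[opt] < self.reward_prob[sub]:
                raise ValueError(f"pair {opt}{sub}: first member must be optimal")

    @property
    def stimuli(self) -> tuple[str, ...]:
        return tuple(s for pair in self.pairs for s in pair)

    @property
    def n_training_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def half_of_block(self, block: int) -> str:
        """First half = blocks 1..n_blocks/2, second half = the rest."""
        return "H1" if block <= self.n_blocks // 2 else "H2"

    def optimal_of(self, pair: tuple[str, str]) -> str:
        return max(pair, key=lambda s: self.reward_prob[s])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "pairs": [list(p) for p in self.pairs],
                    "reward_prob": dict(self.reward_prob),
                    "n_blocks": self.n_blocks,
                    "trials_per_block": self.trials_per_block,
                    "test_reps": self.test_reps,
                    "seed": self.seed,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "TaskConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["pairs"] = tuple(tuple(p) for p in d["pairs"])
        return cls(**d)

    def with_seed(self, seed: int) -> "TaskConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class TrialRecord:
    """One realized trial (training or test)."""

    phase: str  # "training" | "test"
    block: int  # 1-based; 0 for test phase
    trial_index: int  # 1-based global index within phase sequence
    pair: tuple[str, str]
    choice: str
    feedback: str  # "Correct" | "Incorrect" | "none"
    half: str  # "H1" | "H2"; test trials carry "H2"

    def __post_init__(self) -> None:
        if (self.feedback == NO_FEEDBACK) != (self.phase == "test"):
            raise ValueError("feedback is 'none' iff phase is 'test'")


def make_training_schedule(
    config: TaskConfig, rng: np.random.Generator | None = None
) -> list[tuple[str, str]]:
    """Balanced, shuffled training-phase pair sequence.

    Each block contains ``trials_per_block / n_pairs`` presentations of every
    training pair, independently shuffled.  Reproducible from ``config.seed``
    unless an explicit ``rng`` is supplied.
    """
    n_pairs = len(config.pairs)
    if config.trials_per_block % n_pairs != 0:
        raise ValueError(
            f"trials_per_block={config.trials_per_block} cannot be balanced "
            f"across {n_pairs} pairs"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    per_pair = config.trials_per_block // n_pairs
    schedule: list[tuple[str, str]] = []
    for _ in range(config.n_blocks):
        block = [pair for pair in config.pairs for _ in range(per_pair)]
        order = rng.permutation(len(block))
        schedule.extend(block[i] for i in order)
    return schedule


def make_test_schedule(
    config: TaskConfig, rng: np.random.Generator | None = None
) -> list[tuple[str, str]]:
    """Test-phase sequence: every unordered stimulus pairing, ``test_reps`` times.

    With the default four stimuli this yields the six pairings AB, CD, AC,
    AD, BC, BD, each presented four times, in shuffled order.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    combos = list(itertools.combinations(config.stimuli, 2))
    schedule = [pair for pair in combos for _ in range(config.test_reps)]
    order = rng.permutation(len(schedule))
    return [schedule[i] for i in order]


def deliver_feedback(
    choice: str, config: TaskConfig, rng: np.random.Generator
) -> str:
    """Independent Bernoulli feedback on the chosen stimulus.

    Returns "Correct" with probability ``reward_prob[choice]``.
    """
    if choice not in config.reward_prob:
        raise KeyError(f"unknown stimulus {choice!r}")
    return CORRECT if rng.random() < config.reward_prob[choice] else INCORRECT


def simulate_fixed_choice(
    choice: str, n_trials: int, config: TaskConfig, rng: np.random.Generator
) -> float:
    """Fraction of "Correct" feedback over ``n_trials`` fixed choices.

    Vectorized convenience for contingency checks (e.g. always choosing A
    over many trials should yield ~80% Correct).
    """
    if choice not in config.reward_prob:
        raise KeyError(f"unknown stimulus {choice!r}")
    draws = rng.random(n_trials) < config.reward_prob[choice]
    return float(draws.mean())


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Serialize trial records to the session CSV layout."""
    return pd.DataFrame(
        {
            "phase": [t.phase for t in trials],
            "block": [t.block for t in trials],
            "trial_index": [t.trial_index for t in trials],
            "pair": ["".join(t.pair) for t in trials],
            "choice": [t.choice for t in trials],
            "feedback": [t.feedback for t in trials],
            "half": [t.half for t in trials],
        }
    )
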