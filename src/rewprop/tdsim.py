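"""TD(0) simulation of reward-prediction-error backpropagation.

Each trial traverses a short intra-trial state chain (cue -> response ->
pre-feedback), with a Bernoulli reward delivered on the transition out of
the final state.  Every transition produces a prediction error
``delta = r + gamma*V(next) - V(current)`` (reward nonzero only at the
terminal transition) and the departed state's value is updated by
``alpha_td * delta``.  The cue-onset RPE is the prediction jump from a
zero-value pre-trial baseline into the cue state, ``gamma * V(cue)``.

Early in learning the RPE is concentrated at feedback (values are all
zero, so rewards are fully unexpected); with training, value accrues
backwards along the chain and the RPE migrates to the cue.  At the fixed
point the expected value of the cue state is
``reward_prob * gamma**(n_states - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TDConfig", "TDTrace", "run_td", "summarize_halves", "block_means"]


@dataclass(frozen=True)
class TDConfig:
    """Chain layout and learning parameters for the TD(0) simulation."""

    n_intratrial_states: int = 3  # cue, response, pre-feedback
    alpha_td: float = 0.1
    gamma: float = 0.95
    reward_prob: float = 0.8
    n_trials: int = 240
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_intratrial_states < 1:
            raise ValueError("need at least one intra-trial state")
        if not 0.0 <= self.alpha_td <= 1.0:
            raise ValueError("alpha_td must be in [0, 1]")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")
        if not 0.0 <= self.reward_prob <= 1.0:
            raise ValueError("reward_prob must be in [0, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")


@dataclass
class TDTrace:
    """Per-trial record of the TD simulation.

    ``values`` holds the state-value vector at the *start* of each trial
    (one row per trial), so ``values[t, 0]`` is V(cue) before trial t's
    updates.  ``final_values`` is the vector after the last trial.
    """

    cue_rpe: np.ndarray
    feedback_rpe: np.ndarray
    values: np.ndarray
    final_values: np.ndarray
    config: TDConfig

    @property
    def n_trials(self) -> int:
        return len(self.cue_rpe)


def run_td(config: TDConfig) -> TDTrace:
    """Run the TD(0) chain for ``config.n_trials`` trials."""
    rng = np.random.default_rng(config.seed)
    k = config.n_intratrial_states
    v = np.zeros(k)
    rewards = rng.random(config.n_trials) < config.reward_prob

    cue_rpe = np.empty(config.n_trials)
    fb_rpe = np.empty(config.n_trials)
    values = np.empty((config.n_trials, k))

    a, g = config.alpha_td, config.gamma
    for t in range(config.n_trials):
        values[t] = v
        # entry into the cue state from a fixed zero-value baseline
        cue_rpe[t] = g * v[0]
        # intra-trial transitions (no reward)
        for s in range(k - 1):
            delta = g * v[s + 1] - v[s]
            v[s] += a * delta
        # terminal transition carries the reward
        r = 1.0 if rewards[t] else 0.0
        delta = r - v[k - 1]
        fb_rpe[t] = delta
        v[k - 1] += a * delta

    return TDTrace(cue_rpe, fb_rpe, values, v.copy(), config)


def summarize_halves(trace: TDTrace) -> dict[str, float]:
    """Mean cue-onset and feedback RPE over the first and second halves."""
    n = trace.n_trials
    if n == 0:
        raise ValueError("empty trace")
    if n % 2 != 0:
        raise ValueError("trial count must be even to split into halves")
    h = n // 2
    return {
        "cue_rpe_h1": float(trace.cue_rpe[:h].mean()),
        "cue_rpe_h2": float(trace.cue_rpe[h:].mean()),
        "feedback_rpe_h1": float(trace.feedback_rpe[:h].mean()),
        "feedback_rpe_h2": float(trace.feedback_rpe[h:].mean()),
    }


def block_means(trace: TDTrace, n_blocks: int = 4) -> dict[str, np.ndarray]:
    """Block-averaged cue and feedback RPE (for migration curves)."""
    n = trace.n_trials
    if n % n_blocks != 0:
        raise ValueError("n_trials must divide evenly into blocks")
    shape = (n_blocks, n // n_blocks)
    return {
        "cue_rpe": trace.cue_rpe.reshape(shape).mean(axis=1),
        "feedback_rpe": trace.feedback_rpe.reshape(shape).mean(axis=1),
    }
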