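"""Q-learning agents with asymmetric learning rates for the PST.

The agent maintains one value Q(i) per stimulus, updated after each
reinforcer by a reward prediction error RPE = R - Q(i) with R = 1 for
"Correct" and 0 for "Incorrect" feedback.  Positive RPEs are scaled by
``alpha_gain`` and negative RPEs by ``alpha_loss``.  Choices between the two
members of the presented pair are drawn from a softmax whose determinism is
governed by ``beta``; two exponent conventions are supported:

* ``gain`` (default): P(i) ∝ exp(beta * Q(i)) — larger beta means more
  deterministic choice.
* ``temperature``: P(i) ∝ exp(Q(i) / beta) — beta acts as a temperature.

Simulated sessions carry the latent Q, RPE and choice-probability traces so
downstream ERP synthesis can couple waveform amplitudes to the model's
prediction-error signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .task import (
    CORRECT,
    NO_FEEDBACK,
    TaskConfig,
    TrialRecord,
    deliver_feedback,
    make_test_schedule,
    make_training_schedule,
    trials_to_frame,
)

__all__ = [
    "AgentParams",
    "RTConfig",
    "BehavioralSession",
    "softmax_probs",
    "compute_rpe",
    "q_update",
    "simulate_session",
    "sample_agent_params",
    "simulate_cohort",
]

_CONVENTIONS = ("gain", "temperature")


@dataclass(frozen=True)
class AgentParams:
    """Generative (or fitted) Q-learning parameters.

    Defaults follow the population means estimated from human PST cohorts
    (alpha_gain ≈ 0.34, alpha_loss ≈ 0.17, beta between 4 and 5).
    """

    alpha_gain: float = 0.34
    alpha_loss: float = 0.17
    beta: float = 4.5
    q_init: float = 0.5
    softmax_convention: str = "gain"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_gain <= 1.0:
            raise ValueError(f"alpha_gain={self.alpha_gain} outside [0, 1]")
        if not 0.0 <= self.alpha_loss <= 1.0:
            raise ValueError(f"alpha_loss={self.alpha_loss} outside [0, 1]")
        if not self.beta > 0:
            raise ValueError(f"beta={self.beta} must be positive")
        if not 0.0 <= self.q_init <= 1.0:
            raise ValueError(f"q_init={self.q_init} outside [0, 1]")
        if self.softmax_convention not in _CONVENTIONS:
            raise ValueError(
                f"softmax_convention must be one of {_CONVENTIONS}"
            )


@dataclass(frozen=True)
class RTConfig:
    """Log-normal reaction-time generator.

    log RT ~ Normal(log(base_median_ms) - conflict_gain*|dQ|
             - value_gain*(maxQ - 0.5), sigma), with a multiplicative
    slowdown on feedback-free test trials.  Decision conflict (small |dQ|)
    slows responses; high acquired pair value speeds them, which makes
    approach test trials faster than avoidance trials.
    """

    base_median_ms: float = 900.0
    conflict_gain: float = 0.3
    value_gain: float = 0.4
    sigma: float = 0.25
    test_multiplier: float = 1.45


def softmax_probs(
    q_values: np.ndarray, beta: float, convention: str = "gain"
) -> np.ndarray:
    """Softmax choice probabilities over a set of Q values.

    Shift-invariant and numerically stable; ``convention`` selects the
    exponent form (``beta*Q`` vs ``Q/beta``).
    """
    q = np.asarray(q_values, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("q_values must be finite")
    if not beta > 0:
        raise ValueError("beta must be positive")
    if convention not in _CONVENTIONS:
        raise ValueError(f"unknown softmax convention {convention!r}")
    x = beta * q if convention == "gain" else q / beta
    x = x - x.max()
    e = np.exp(x)
    return e / e.sum()


def compute_rpe(reward: float, q: float) -> float:
    """Reward prediction error: received minus expected reward."""
    return float(reward) - float(q)


def q_update(q: float, rpe: float, params: AgentParams) -> float:
    """Value update with asymmetric learning rates.

    Positive RPEs move Q up by ``alpha_gain * rpe``; negative RPEs move it
    down by ``alpha_loss * rpe``; a zero RPE leaves Q unchanged.  For rewards
    in {0, 1} and rates in [0, 1] the result stays in [0, 1].
    """
    if rpe > 0:
        return q + params.alpha_gain * rpe
    if rpe < 0:
        return q + params.alpha_loss * rpe
    return q


@dataclass
class BehavioralSession:
    """One simulated (or loaded) PST session with latent model traces.

    ``trials`` holds the realized trial table (both phases, in order);
    arrays are aligned with its rows.  ``q_opt`` / ``q_sub`` are the
    pre-update values of the presented pair's optimal and suboptimal
    members, ``rpe`` is NaN on feedback-free test trials.
    """

    trials: pd.DataFrame
    q_opt: np.ndarray
    q_sub: np.ndarray
    rpe: np.ndarray
    choice_prob: np.ndarray
    rt_ms: np.ndarray
    config: TaskConfig
    params_true: AgentParams | None = None
    final_q: dict[str, float] = field(default_factory=dict)

    @property
    def training(self) -> pd.DataFrame:
        return self.trials[self.trials["phase"] == "training"]

    @property
    def test(self) -> pd.DataFrame:
        return self.trials[self.trials["phase"] == "test"]

    @property
    def n_training_trials(self) -> int:
        return int((self.trials["phase"] == "training").sum())

    @property
    def q_init(self) -> float:
        return self.params_true.q_init if self.params_true is not None else 0.5

    def training_mask(self) -> np.ndarray:
        return (self.trials["phase"] == "training").to_numpy()

    def cue_value(self) -> np.ndarray:
        """Per-trial acquired predictive value of the presented pair.

        Defined as max(Q over the pair) - q_init, clipped at zero: a
        monotone proxy for how much reward the cue has come to predict.
        """
        best = np.maximum(self.q_opt, self.q_sub)
        return np.clip(best - self.q_init, 0.0, None)

    # -- serialization ----------------------------------------------------
    def to_csv(self, trials_path, traces_path=None) -> None:
        """Write the trial table and a companion latent-trace CSV."""
        trials_path = Path(trials_path)
        self.trials.to_csv(trials_path, index=False)
        if traces_path is None:
            traces_path = trials_path.with_name(trials_path.stem + "_traces.csv")
        pd.DataFrame(
            {
                "q_optimal": self.q_opt,
                "q_suboptimal": self.q_sub,
                "rpe": self.rpe,
                "choice_prob": self.choice_prob,
                "rt": self.rt_ms,
            }
        ).to_csv(traces_path, index=False)

    @classmethod
    def from_csv(
        cls,
        trials_path,
        traces_path=None,
        config: TaskConfig | None = None,
        params_true: AgentParams | None = None,
    ) -> "BehavioralSession":
        trials_path = Path(trials_path)
        trials = pd.read_csv(trials_path)
        if config is None:
            config = TaskConfig()
        n = len(trials)
        if traces_path is None:
            candidate = trials_path.with_name(trials_path.stem + "_traces.csv")
            traces_path = candidate if candidate.exists() else None
        if traces_path is not None:
            tr = pd.read_csv(traces_path)
            q_opt = tr["q_optimal"].to_numpy(float)
            q_sub = tr["q_suboptimal"].to_numpy(float)
            rpe = tr["rpe"].to_numpy(float)
            choice_prob = tr["choice_prob"].to_numpy(float)
            rt = tr["rt"].to_numpy(float)
        else:
            q_opt = np.full(n, np.nan)
            q_sub = np.full(n, np.nan)
            rpe = np.full(n, np.nan)
            choice_prob = np.full(n, np.nan)
            rt = np.full(n, np.nan)
        return cls(trials, q_opt, q_sub, rpe, choice_prob, rt, config, params_true)


def _draw_rt(
    rng: np.random.Generator,
    rt: RTConfig,
    q_pair: tuple[float, float],
    is_test: bool,
) -> float:
    dq = abs(q_pair[0] - q_pair[1])
    mx = max(q_pair)
    mu = (
        np.log(rt.base_median_ms)
        - rt.conflict_gain * dq
        - rt.value_gain * (mx - 0.5)
    )
    if is_test:
        mu += np.log(rt.test_multiplier)
    return float(np.exp(mu + rt.sigma * rng.standard_normal()))


def simulate_session(
    params: AgentParams,
    config: TaskConfig | None = None,
    seed: int = 0,
    rt_config: RTConfig | None = None,
) -> BehavioralSession:
    """Simulate a full PST session (training + test) for one agent.

    Training trials draw the choice from the softmax over the presented
    pair's current Q values, receive probabilistic feedback, and update the
    chosen stimulus's value.  Test trials choose by softmax over the final
    Q values with no feedback and no updating.  All randomness (schedule
    order, choices, feedback, RTs) derives from ``seed``.
    """
    if config is None:
        config = TaskConfig()
    if rt_config is None:
        rt_config = RTConfig()
    ss = np.random.SeedSequence(seed)
    rng_sched, rng_choice, rng_fb, rng_rt = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    q = {s: params.q_init for s in config.stimuli}
    records: list[TrialRecord] = []
    q_opt_l, q_sub_l, rpe_l, prob_l, rt_l = [], [], [], [], []

    train_sched = make_training_schedule(config, rng_sched)
    for i, pair in enumerate(train_sched):
        block = i // config.trials_per_block + 1
        qv = np.array([q[pair[0]], q[pair[1]]])
        probs = softmax_probs(qv, params.beta, params.softmax_convention)
        idx = int(rng_choice.random() >= probs[0])
        choice = pair[idx]
        feedback = deliver_feedback(choice, config, rng_fb)
        reward = 1.0 if feedback == CORRECT else 0.0
        rpe = compute_rpe(reward, q[choice])
        opt = config.optimal_of(pair)
        sub = pair[0] if pair[1] == opt else pair[1]
        q_opt_l.append(q[opt])
        q_sub_l.append(q[sub])
        rpe_l.append(rpe)
        prob_l.append(float(probs[idx]))
        rt_l.append(_draw_rt(rng_rt, rt_config, (qv[0], qv[1]), False))
        q[choice] = q_update(q[choice], rpe, params)
        records.append(
            TrialRecord(
                "training", block, i + 1, pair, choice, feedback,
                config.half_of_block(block),
            )
        )

    for j, pair in enumerate(make_test_schedule(config, rng_sched)):
        qv = np.array([q[pair[0]], q[pair[1]]])
        probs = softmax_probs(qv, params.beta, params.softmax_convention)
        idx = int(rng_choice.random() >= probs[0])
        choice = pair[idx]
        opt = config.optimal_of(pair)
        sub = pair[0] if pair[1] == opt else pair[1]
        q_opt_l.append(q[opt])
        q_sub_l.append(q[sub])
        rpe_l.append(np.nan)
        prob_l.append(float(probs[idx]))
        rt_l.append(_draw_rt(rng_rt, rt_config, (qv[0], qv[1]), True))
        records.append(
            TrialRecord("test", 0, j + 1, pair, choice, NO_FEEDBACK, "H2")
        )

    return BehavioralSession(
        trials=trials_to_frame(records),
        q_opt=np.asarray(q_opt_l),
        q_sub=np.asarray(q_sub_l),
        rpe=np.asarray(rpe_l),
        choice_prob=np.asarray(prob_l),
        rt_ms=np.asarray(rt_l),
        config=config,
        params_true=params,
        final_q=dict(q),
    )


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    # rejection sampling; the bounds are wide relative to sd, so this is cheap
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)


def sample_agent_params(
    n_subjects: int,
    seed: int = 0,
    alpha_gain: tuple[float, float] = (0.09, 0.08),
    alpha_loss: tuple[float, float] = (0.05, 0.035),
    beta: tuple[float, float] = (5.0, 1.5),
    softmax_convention: str = "gain",
) -> list[AgentParams]:
    """Draw a cohort of generative parameters from population distributions.

    Each (mean, sd) pair parameterizes a truncated normal; learning rates
    are truncated to [0.01, 0.95] and beta to [1, 10].  The defaults are
    calibrated so simulated cohorts reproduce the human training-accuracy
    trajectory (~75% in the first half, ~82% in the second, with a
    median-split rapid group near 90% and a slow group near 70%), which
    requires gradual value growth across the whole session.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_subjects):
        out.append(
            AgentParams(
                alpha_gain=_trunc_normal(rng, *alpha_gain, 0.01, 0.95),
                alpha_loss=_trunc_normal(rng, *alpha_loss, 0.01, 0.95),
                beta=_trunc_normal(rng, *beta, 1.0, 10.0),
                softmax_convention=softmax_convention,
            )
        )
    return out


def simulate_cohort(
    n_subjects: int,
    config: TaskConfig | None = None,
    seed: int = 0,
    params: list[AgentParams] | None = None,
    rt_config: RTConfig | None = None,
) -> list[BehavioralSession]:
    """Simulate ``n_subjects`` independent sessions with heterogeneous agents."""
    if config is None:
        config = TaskConfig()
    if n_subjects == 0:
        return []
    ss = np.random.SeedSequence(seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_subjects)]
    if params is None:
        params = sample_agent_params(n_subjects, seed=subject_seeds[0] ^ 0x5EED)
    return [
        simulate_session(p, config, seed=s, rt_config=rt_config)
        for p, s in zip(params, subject_seeds)
    ]
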