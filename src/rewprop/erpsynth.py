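"""Synthetic single-trial ERP epochs built by component superposition.

Each epoch is the sum of parametric ERP components — P200, N200, P300 and a
reward positivity (RewP) — rendered as Gaussian bumps in time, plus
band-limited noise.  The observed waveform is therefore a superposition in
which the positive-going RewP partially cancels the overlapping N200 on
trials where positive prediction errors occur, which is exactly the
measurement problem the analysis pipeline has to untangle.

Coupling to the behavioral model: the feedback-locked RewP amplitude scales
with the trial's positive reward prediction error, max(RPE, 0); the
cue-locked RewP scales with the presented pair's acquired predictive value
(max Q minus the initial value, clipped at zero).  As an agent learns, the
feedback driver shrinks and the cue driver grows, so the RewP migrates from
feedback to cue in the synthesized data.

The P300 can carry an oddball modulation, scaling with -log of the
empirical frequency of the event category (infrequent negative feedback
gets the larger P300).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .agents import BehavioralSession
from .task import CORRECT

__all__ = [
    "ComponentSpec",
    "EpochSet",
    "default_component_specs",
    "synthesize_epochs",
    "inject_artifacts",
]

COMPONENT_NAMES = ("P200", "N200", "P300", "RewP")
MODULATIONS = ("fixed", "positive_rpe", "oddball")

#: Epoch window in ms relative to the time-locking event.
EPOCH_START_MS = -200.0
EPOCH_SPAN_MS = 800.0


@dataclass(frozen=True)
class ComponentSpec:
    """One parametric ERP component template.

    The waveform is ``amplitude * exp(-(t - peak_latency)**2 / (2*width**2))``
    per channel, weighted by ``channel_weights`` (missing channels get 0).
    ``modulation`` selects how the per-trial amplitude scale is derived.
    """

    name: str
    event: str  # "cue" | "feedback"
    peak_latency: float  # ms post-event
    width: float = 25.0  # Gaussian SD, ms
    base_amplitude: float = 1.0  # signed, µV
    channel_weights: dict[str, float] = field(default_factory=lambda: {"Fz": 1.0})
    modulation: str = "fixed"

    def __post_init__(self) -> None:
        if self.name not in COMPONENT_NAMES:
            raise ValueError(f"unknown component {self.name!r}")
        if self.event not in ("cue", "feedback"):
            raise ValueError(f"unknown event {self.event!r}")
        if not self.width > 0:
            raise ValueError("width must be positive")
        if self.modulation not in MODULATIONS:
            raise ValueError(f"unknown modulation {self.modulation!r}")
        if self.name == "N200" and self.base_amplitude > 0:
            raise ValueError("N200 must have negative base_amplitude")
        if self.name != "N200" and self.base_amplitude < 0:
            raise ValueError(f"{self.name} must have non-negative base_amplitude")


def default_component_specs() -> list[ComponentSpec]:
    """Default component set for both event types.

    Peak latencies follow the grand-average peaks used for measurement
    (cue: P200 170 ms, N200 285 ms, P300 490 ms; feedback: P200 210 ms,
    N200 270 ms, P300 360 ms); the RewP shares the N200 latency, which is
    what makes the superposition ambiguous for raw waveforms.  Frontal
    components project to Fz, the P300 to Pz.  Base amplitudes are
    generator conditions in µV (RewP values are gains per unit driver).
    """
    fz = {"Fz": 1.0}
    pz = {"Pz": 1.0}
    return [
        ComponentSpec("P200", "cue", 170.0, 25.0, 3.0, fz, "fixed"),
        ComponentSpec("N200", "cue", 285.0, 25.0, -4.0, fz, "fixed"),
        ComponentSpec("RewP", "cue", 285.0, 25.0, 16.0, fz, "positive_rpe"),
        ComponentSpec("P300", "cue", 490.0, 25.0, 5.0, pz, "fixed"),
        ComponentSpec("P200", "feedback", 210.0, 25.0, 7.0, fz, "fixed"),
        ComponentSpec("N200", "feedback", 270.0, 25.0, -4.0, fz, "fixed"),
        ComponentSpec("RewP", "feedback", 270.0, 25.0, 20.0, fz, "positive_rpe"),
        ComponentSpec("P300", "feedback", 360.0, 25.0, 8.0, pz, "oddball"),
    ]


@dataclass
class EpochSet:
    """Labeled single-trial epochs: trials x channels x time, in µV.

    ``labels`` has one row per epoch with columns ``event`` (cue/feedback),
    ``valence`` (positive/negative/none), ``half`` (H1/H2), ``trial_index``
    and ``artifact`` (none, or the kind of injected corruption).
    """

    epochs: np.ndarray
    times: np.ndarray  # ms relative to the event
    channels: list[str]
    labels: pd.DataFrame
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_times)")
        if self.epochs.shape[1] != len(self.channels):
            raise ValueError("channel axis mismatch")
        if self.epochs.shape[2] != len(self.times):
            raise ValueError("time axis mismatch")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("labels must have one row per epoch")
        if "artifact" not in self.labels.columns:
            self.labels = self.labels.assign(artifact="none")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}") from None

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            self.epochs[mask], self.times, list(self.channels),
            self.labels.iloc[mask].reset_index(drop=True), self.sampling_rate,
        )

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.epochs.copy(), self.times.copy(), list(self.channels),
            self.labels.copy(), self.sampling_rate,
        )

    # -- serialization: array file + CSV sidecar + JSON header -----------
    def save(self, prefix) -> None:
        prefix = Path(prefix)
        np.save(prefix.with_suffix(".npy"), self.epochs)
        self.labels.to_csv(prefix.with_suffix(".labels.csv"), index=False)
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(
                {
                    "sampling_rate": self.sampling_rate,
                    "channels": self.channels,
                    "times_ms": self.times.tolist(),
                },
                fh,
            )

    @classmethod
    def load(cls, prefix) -> "EpochSet":
        prefix = Path(prefix)
        epochs = np.load(prefix.with_suffix(".npy"))
        labels = pd.read_csv(prefix.with_suffix(".labels.csv"))
        with open(prefix.with_suffix(".json")) as fh:
            header = json.load(fh)
        return cls(
            epochs, np.asarray(header["times_ms"], float), header["channels"],
            labels, header["sampling_rate"],
        )


def _epoch_times(sampling_rate: float) -> np.ndarray:
    n = int(round(EPOCH_SPAN_MS * sampling_rate / 1000.0))
    return EPOCH_START_MS + np.arange(n) * 1000.0 / sampling_rate


def _ar1_noise(rng, shape, sd, coef=0.95):
    """AR(1)-filtered Gaussian noise with stationary SD ``sd``."""
    white = rng.standard_normal(shape)
    innovation_sd = sd * np.sqrt(1.0 - coef**2)
    return lfilter([1.0], [1.0, -coef], innovation_sd * white, axis=-1)


def synthesize_epochs(
    session: BehavioralSession,
    specs: list[ComponentSpec] | None = None,
    noise_sd: float = 8.0,
    sampling_rate: float = 1000.0,
    seed: int = 0,
    ar_coef: float = 0.95,
    channels: tuple[str, ...] = ("Fz", "Pz"),
) -> EpochSet:
    """Render cue- and feedback-locked epochs for every training trial.

    Each epoch spans -200..600 ms around its event at ``sampling_rate``.
    The per-trial amplitude of each component is ``base_amplitude`` times
    its modulation factor (1 for ``fixed``; the positive-RPE / cue-value
    driver for ``positive_rpe``; -log empirical category frequency for
    ``oddball``).  Deterministic given ``seed``.
    """
    if specs is None:
        specs = default_component_specs()
    rng = np.random.default_rng(seed)
    times = _epoch_times(sampling_rate)
    n_ch = len(channels)

    training = session.training.reset_index(drop=True)
    tmask = session.training_mask()
    rpe = session.rpe[tmask]
    cue_value = session.cue_value()[tmask]
    n_trials = len(training)
    positive = (training["feedback"] == CORRECT).to_numpy()
    # oddball factors from the empirical feedback-category frequencies
    p_pos = positive.mean()
    odd_factor = np.where(
        positive,
        -np.log(max(p_pos, 1e-12)),
        -np.log(max(1.0 - p_pos, 1e-12)),
    )

    blocks = {"cue": [], "feedback": []}
    frames = []
    for event in ("cue", "feedback"):
        ev_specs = [s for s in specs if s.event == event]
        names = {s.name for s in ev_specs}
        missing = set(COMPONENT_NAMES) - names
        if missing:
            raise ValueError(
                f"missing component spec(s) for event {event!r}: "
                f"{sorted(missing)}"
            )
        templates = np.zeros((len(ev_specs), n_ch, len(times)))
        amps = np.zeros((n_trials, len(ev_specs)))
        for c, spec in enumerate(ev_specs):
            bump = np.exp(-((times - spec.peak_latency) ** 2)
                          / (2.0 * spec.width**2))
            for ci, ch in enumerate(channels):
                templates[c, ci] = spec.channel_weights.get(ch, 0.0) * bump
            if spec.modulation == "fixed":
                scale = np.ones(n_trials)
            elif spec.modulation == "positive_rpe":
                scale = np.clip(rpe, 0.0, None) if event == "feedback" else cue_value
            else:  # oddball
                scale = odd_factor
            amps[:, c] = spec.base_amplitude * scale
        signal = np.einsum("tc,cxn->txn", amps, templates)
        if noise_sd > 0:
            signal = signal + _ar1_noise(
                rng, (n_trials, n_ch, len(times)), noise_sd, ar_coef
            )
        blocks[event] = signal
        frames.append(
            pd.DataFrame(
                {
                    "event": event,
                    "valence": np.where(positive, "positive", "negative")
                    if event == "feedback" else "none",
                    "half": training["half"].to_numpy(),
                    "trial_index": training["trial_index"].to_numpy(),
                }
            )
        )

    epochs = np.concatenate([blocks["cue"], blocks["feedback"]], axis=0)
    labels = pd.concat(frames, ignore_index=True)
    return EpochSet(epochs, times, list(channels), labels, sampling_rate)


def inject_artifacts(
    epoch_set: EpochSet,
    fraction: float,
    kinds: tuple[str, ...] = ("amplitude_spike", "step"),
    seed: int = 0,
) -> EpochSet:
    """Corrupt an exact fraction of epochs with rejection-rule violations.

    ``amplitude_spike`` adds a 150 µV single-sample excursion (violating the
    ±100 µV amplitude limit); ``step`` adds an 80 µV offset to the second
    part of the epoch (violating the 50 µV sample-to-sample step limit).
    Corrupted epochs are marked in ``labels['artifact']`` so rejection
    tests have ground truth.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    for kind in kinds:
        if kind not in ("amplitude_spike", "step"):
            raise ValueError(f"unknown artifact kind {kind!r}")
    out = epoch_set.copy()
    n_corrupt = int(round(fraction * out.n_epochs))
    if n_corrupt == 0:
        return out
    rng = np.random.default_rng(seed)
    chosen = rng.choice(out.n_epochs, size=n_corrupt, replace=False)
    n_t = len(out.times)
    artifact = out.labels["artifact"].to_numpy(object)
    for i, idx in enumerate(chosen):
        kind = kinds[i % len(kinds)]
        ch = rng.integers(len(out.channels))
        if kind == "amplitude_spike":
            at = rng.integers(n_t)
            out.epochs[idx, ch, at] += 150.0
        else:
            at = rng.integers(n_t // 4, 3 * n_t // 4)
            out.epochs[idx, ch, at:] += 80.0
        artifact[idx] = kind
    out.labels = out.labels.assign(artifact=artifact)
    return out
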