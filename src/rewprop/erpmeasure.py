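"""ERP measurement pipeline: baseline, rejection, averaging, windows.

The pipeline mirrors standard feedback-learning ERP practice: epochs are
baseline-corrected to the -200..0 ms pre-event mean, rejected if any
channel exceeds ±100 µV anywhere or jumps more than 50 µV between adjacent
samples, averaged within condition (cue by half; feedback by valence and
half), and summarized as mean amplitudes in ±25 ms windows centered on
each component's grand-average peak latency.  Difference waves (ΔRewP)
isolate the reward positivity: positive-minus-negative feedback within a
half, and cue Half-2 minus Half-1.

Window endpoints are inclusive: a sample at time t belongs to [a, b] iff
a <= t <= b.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .erpsynth import EpochSet

__all__ = [
    "MeasureConfig",
    "Waveform",
    "ConditionAverages",
    "baseline_correct",
    "artifact_reject",
    "average_by_condition",
    "mean_amplitude",
    "difference_wave",
    "measure_table",
    "measure_epochs",
    "CONDITIONS",
]

#: Closed vocabulary of averaging conditions.
CONDITIONS = ("cue-H1", "cue-H2", "fb-pos-H1", "fb-pos-H2", "fb-neg-H1", "fb-neg-H2")


def _default_windows() -> dict:
    """±25 ms windows around the grand-average component peaks."""
    return {
        ("cue", "P200"): ("Fz", 145.0, 195.0),
        ("cue", "N200"): ("Fz", 260.0, 310.0),
        ("cue", "P300"): ("Pz", 465.0, 515.0),
        ("feedback", "P200"): ("Fz", 185.0, 235.0),
        ("feedback", "N200"): ("Fz", 245.0, 295.0),
        ("feedback", "P300"): ("Pz", 335.0, 385.0),
    }


@dataclass(frozen=True)
class MeasureConfig:
    """Measurement parameters (thresholds in µV, windows in ms)."""

    baseline_window: tuple[float, float] = (-200.0, 0.0)
    reject_abs: float = 100.0
    reject_step: float = 50.0
    windows: dict = field(default_factory=_default_windows)
    min_trials_per_condition: int = 5


@dataclass
class Waveform:
    """A channels-by-time waveform on a shared time axis."""

    data: np.ndarray  # (n_channels, n_times), µV
    times: np.ndarray  # ms
    channels: list[str]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None


def condition_of(event: str, valence: str, half: str) -> str:
    """Map epoch labels onto the closed condition vocabulary."""
    if event == "cue":
        return f"cue-{half}"
    return f"fb-{'pos' if valence == 'positive' else 'neg'}-{half}"


def _window_mask(times: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    if lo < times[0] - 1e-9 or hi > times[-1] + 1e-9:
        raise ValueError(
            f"window {window} outside the epoch time axis "
            f"[{times[0]}, {times[-1]}]"
        )
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise ValueError(f"window {window} contains no samples")
    return mask


def baseline_correct(
    epoch_set: EpochSet, window: tuple[float, float] = (-200.0, 0.0)
) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over the baseline window."""
    mask = _window_mask(epoch_set.times, window)
    out = epoch_set.copy()
    out.epochs -= out.epochs[:, :, mask].mean(axis=2, keepdims=True)
    return out


def artifact_reject(
    epoch_set: EpochSet, config: MeasureConfig | None = None
) -> tuple[EpochSet, pd.DataFrame]:
    """Drop epochs violating amplitude or step criteria, on any channel.

    Returns the retained epochs and a log with one row per rejected epoch
    (columns ``epoch``, ``reason``); amplitude violations take precedence
    over step violations in the recorded reason.
    """
    if config is None:
        config = MeasureConfig()
    x = epoch_set.epochs
    amp_bad = np.abs(x).max(axis=(1, 2)) > config.reject_abs
    step_bad = np.abs(np.diff(x, axis=2)).max(axis=(1, 2)) > config.reject_step
    bad = amp_bad | step_bad
    log = pd.DataFrame(
        {
            "epoch": np.nonzero(bad)[0],
            "reason": np.where(amp_bad[bad], "amplitude", "step"),
        }
    )
    return epoch_set.select(~bad), log


@dataclass
class ConditionAverages:
    """Per-condition average waveforms with retained-trial counts."""

    waves: dict[str, Waveform]
    counts: dict[str, int]
    insufficient: list[str]  # conditions below the minimum trial count

    def __getitem__(self, condition: str) -> Waveform:
        return self.waves[condition]


def average_by_condition(
    epoch_set: EpochSet, min_trials: int = 1
) -> ConditionAverages:
    """Arithmetic mean across epochs within each labeled condition.

    Empty or under-populated conditions are flagged in ``insufficient``
    rather than silently dropped (empty conditions get no waveform).
    """
    conds = np.array(
        [
            condition_of(e, v, h)
            for e, v, h in zip(
                epoch_set.labels["event"],
                epoch_set.labels["valence"],
                epoch_set.labels["half"],
            )
        ]
    )
    waves: dict[str, Waveform] = {}
    counts: dict[str, int] = {}
    insufficient: list[str] = []
    for cond in CONDITIONS:
        mask = conds == cond
        n = int(mask.sum())
        counts[cond] = n
        if n == 0:
            insufficient.append(cond)
            continue
        if n < min_trials:
            insufficient.append(cond)
        waves[cond] = Waveform(
            epoch_set.epochs[mask].mean(axis=0),
            epoch_set.times,
            list(epoch_set.channels),
        )
    return ConditionAverages(waves, counts, insufficient)


def mean_amplitude(
    waveform: Waveform, channel: str, window: tuple[float, float]
) -> float:
    """Mean amplitude over a closed time window at one channel (µV)."""
    mask = _window_mask(waveform.times, window)
    return float(waveform.channel(channel)[mask].mean())


def difference_wave(minuend: Waveform, subtrahend: Waveform) -> Waveform:
    """Pointwise condition difference (e.g. ΔRewP = positive - negative)."""
    if minuend.channels != subtrahend.channels or not np.array_equal(
        minuend.times, subtrahend.times
    ):
        raise ValueError("waveforms are on mismatched axes")
    return Waveform(
        minuend.data - subtrahend.data, minuend.times, list(minuend.channels)
    )


def measure_table(
    averages: ConditionAverages, config: MeasureConfig | None = None
) -> pd.DataFrame:
    """Windowed mean amplitudes for every condition × component.

    One row per (condition, component); conditions without a waveform or
    below ``min_trials_per_condition`` are flagged in ``insufficient``.
    """
    if config is None:
        config = MeasureConfig()
    rows = []
    for cond in CONDITIONS:
        event = "cue" if cond.startswith("cue") else "feedback"
        n = averages.counts.get(cond, 0)
        flagged = cond in averages.insufficient or (
            n < config.min_trials_per_condition
        )
        for (ev, comp), (channel, lo, hi) in config.windows.items():
            if ev != event:
                continue
            amp = (
                mean_amplitude(averages[cond], channel, (lo, hi))
                if cond in averages.waves
                else np.nan
            )
            rows.append(
                {
                    "condition": cond,
                    "component": comp,
                    "channel": channel,
                    "mean_amplitude": amp,
                    "n_trials_retained": n,
                    "insufficient": flagged,
                }
            )
    return pd.DataFrame(rows)


def measure_epochs(
    epoch_set: EpochSet, config: MeasureConfig | None = None
) -> tuple[pd.DataFrame, ConditionAverages, pd.DataFrame]:
    """Full pipeline: baseline -> reject -> average -> measure.

    Returns the measurement table, the condition averages, and the
    rejection log.
    """
    if config is None:
        config = MeasureConfig()
    corrected = baseline_correct(epoch_set, config.baseline_window)
    retained, log = artifact_reject(corrected, config)
    averages = average_by_condition(retained)
    return measure_table(averages, config), averages, log
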