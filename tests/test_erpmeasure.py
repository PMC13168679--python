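"""Measurement pipeline: baseline, rejection, averaging, windows, ΔRewP."""

import numpy as np
import pandas as pd
import pytest

from rewprop.erpmeasure import (
    CONDITIONS,
    MeasureConfig,
    Waveform,
    artifact_reject,
    average_by_condition,
    baseline_correct,
    difference_wave,
    mean_amplitude,
    measure_epochs,
    measure_table,
)
from rewprop.erpsynth import (
    EpochSet,
    default_component_specs,
    ComponentSpec,
    inject_artifacts,
    synthesize_epochs,
)

FS = 1000.0


def _epoch_set(data, fs=FS, labels=None):
    """Wrap a (n, ch, t) array into an EpochSet with simple labels."""
    data = np.asarray(data, dtype=float)
    n, n_ch, n_t = data.shape
    times = -200.0 + np.arange(n_t) * 1000.0 / fs
    if labels is None:
        labels = pd.DataFrame(
            {
                "event": ["feedback"] * n,
                "valence": ["positive"] * n,
                "half": ["H1"] * n,
                "trial_index": np.arange(1, n + 1),
            }
        )
    channels = ["Fz", "Pz"][:n_ch]
    return EpochSet(data, times, channels, labels, fs)


class TestBaseline:
    def test_constant_epoch_becomes_zero(self):
        es = _epoch_set(np.full((1, 1, 800), 7.3))
        out = baseline_correct(es)
        np.testing.assert_allclose(out.epochs, 0.0, atol=1e-12)

    def test_zero_baseline_epoch_unchanged(self):
        data = np.zeros((1, 1, 800))
        data[0, 0, 400:] = 5.0  # activity only after 200 ms
        es = _epoch_set(data)
        out = baseline_correct(es)
        np.testing.assert_allclose(out.epochs, data, atol=1e-12)

    def test_offset_removed_exactly(self):
        template = np.sin(np.linspace(0, 3, 800)) * 4
        template -= template[:201].mean()  # zero-mean baseline by construction
        es = _epoch_set((template + 11.0)[None, None, :])
        out = baseline_correct(es)
        np.testing.assert_allclose(out.epochs[0, 0], template, atol=1e-10)

    def test_baseline_window_mean_is_zero_after_correction(self, default_session):
        es = synthesize_epochs(default_session, seed=1, sampling_rate=250.0)
        out = baseline_correct(es)
        mask = (out.times >= -200) & (out.times <= 0)
        assert np.abs(out.epochs[:, :, mask].mean(axis=2)).max() <= 1e-9

    def test_window_outside_axis_rejected(self):
        es = _epoch_set(np.zeros((1, 1, 800)))
        with pytest.raises(ValueError):
            baseline_correct(es, window=(-500, 0))


class TestArtifactRejection:
    def test_amplitude_violation_rejected(self):
        data = np.zeros((1, 2, 800))
        data[0, 0, 300] = 150.0
        retained, log = artifact_reject(_epoch_set(data))
        assert retained.n_epochs == 0
        assert log.iloc[0]["reason"] == "amplitude"

    def test_step_violation_rejected(self):
        data = np.zeros((1, 2, 800))
        data[0, 1, 400:] = 60.0  # 60 µV jump between adjacent samples
        retained, log = artifact_reject(_epoch_set(data))
        assert retained.n_epochs == 0
        assert log.iloc[0]["reason"] == "step"

    def test_smooth_high_amplitude_epoch_retained(self):
        t = np.arange(800)
        data = (99.0 * np.exp(-((t - 400.0) ** 2) / (2 * 80.0**2)))[None, None, :]
        retained, log = artifact_reject(_epoch_set(data))
        assert retained.n_epochs == 1
        assert log.empty

    def test_threshold_is_strict_inequality(self):
        t = np.arange(800)
        data = (100.0 * np.exp(-((t - 400.0) ** 2) / (2 * 80.0**2)))[None, None, :]
        retained, _ = artifact_reject(_epoch_set(data))
        assert retained.n_epochs == 1  # exactly ±100 µV is allowed

    def test_any_channel_fails_the_epoch(self):
        data = np.zeros((2, 2, 800))
        data[1, 1, 100] = 200.0  # violation on Pz only
        retained, log = artifact_reject(_epoch_set(data))
        assert retained.n_epochs == 1
        assert list(log["epoch"]) == [1]

    def test_sensitivity_and_specificity_on_injected_artifacts(
        self, default_session
    ):
        es = synthesize_epochs(default_session, seed=6, sampling_rate=250.0)
        corrupted = inject_artifacts(es, fraction=0.2, seed=7)
        retained, log = artifact_reject(baseline_correct(corrupted))
        truth = (corrupted.labels["artifact"] != "none").to_numpy()
        rejected = np.zeros(corrupted.n_epochs, bool)
        rejected[log["epoch"]] = True
        assert (rejected == truth).all()  # perfect sensitivity + specificity


class TestAveraging:
    def test_identical_epochs_average_to_themselves(self):
        data = np.tile(np.sin(np.linspace(0, 2, 800)), (3, 1, 1)).reshape(3, 1, 800)
        avgs = average_by_condition(_epoch_set(data))
        np.testing.assert_allclose(avgs["fb-pos-H1"].data[0], data[0, 0])
        assert avgs.counts["fb-pos-H1"] == 3

    def test_opposite_epochs_cancel(self):
        wave = np.sin(np.linspace(0, 2, 800))
        data = np.stack([wave[None, :], -wave[None, :]])
        avgs = average_by_condition(_epoch_set(data))
        np.testing.assert_allclose(avgs["fb-pos-H1"].data, 0.0, atol=1e-12)

    def test_empty_conditions_flagged_not_dropped(self):
        avgs = average_by_condition(_epoch_set(np.zeros((2, 1, 800))))
        assert "cue-H1" in avgs.insufficient
        assert set(avgs.counts) == set(CONDITIONS)


class TestMeanAmplitude:
    def test_flat_waveform(self):
        w = Waveform(np.full((1, 800), 3.0), -200 + np.arange(800.0), ["Fz"])
        assert mean_amplitude(w, "Fz", (245, 295)) == pytest.approx(3.0)

    def test_single_sample_window(self):
        times = -200 + np.arange(800.0)
        data = np.zeros((1, 800))
        idx = np.nonzero(times == 270.0)[0][0]
        data[0, idx] = -5.0
        w = Waveform(data, times, ["Fz"])
        assert mean_amplitude(w, "Fz", (270, 270)) == pytest.approx(-5.0)

    def test_gaussian_bump_against_trapezoid_oracle(self):
        times = -200 + np.arange(800.0)
        bump = -5.0 * np.exp(-((times - 270.0) ** 2) / (2 * 25.0**2))
        w = Waveform(bump[None, :], times, ["Fz"])
        measured = mean_amplitude(w, "Fz", (245, 295))
        mask = (times >= 245) & (times <= 295)
        oracle = np.trapezoid(bump[mask], times[mask]) / (295 - 245)
        assert measured == pytest.approx(oracle, rel=0.02)

    def test_unknown_channel_raises(self):
        w = Waveform(np.zeros((1, 800)), -200 + np.arange(800.0), ["Fz"])
        with pytest.raises(KeyError):
            mean_amplitude(w, "Cz", (245, 295))


class TestDifferenceWave:
    def test_identical_conditions_give_zero(self):
        w = Waveform(np.random.default_rng(0).normal(size=(2, 100)),
                     np.arange(100.0), ["Fz", "Pz"])
        np.testing.assert_allclose(difference_wave(w, w).data, 0.0)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(1)
        a = Waveform(rng.normal(size=(1, 50)), np.arange(50.0), ["Fz"])
        b = Waveform(rng.normal(size=(1, 50)), np.arange(50.0), ["Fz"])
        np.testing.assert_allclose(
            difference_wave(a, b).data, -difference_wave(b, a).data
        )

    def test_mismatched_axes_rejected(self):
        a = Waveform(np.zeros((1, 50)), np.arange(50.0), ["Fz"])
        b = Waveform(np.zeros((1, 50)), np.arange(50.0) + 1, ["Fz"])
        with pytest.raises(ValueError):
            difference_wave(a, b)


class TestPipeline:
    def test_table_covers_all_conditions(self, default_session):
        es = synthesize_epochs(default_session, seed=2, sampling_rate=250.0)
        table, _, _ = measure_epochs(es)
        assert set(table["condition"]) == set(CONDITIONS)
        assert set(table["component"]) == {"P200", "N200", "P300"}
        assert table["mean_amplitude"].notna().all()

    def test_linearity_in_component_gain(self, default_session):
        def run(scale):
            specs = [
                ComponentSpec(s.name, s.event, s.peak_latency, s.width,
                              scale * s.base_amplitude, s.channel_weights,
                              s.modulation)
                for s in default_component_specs()
            ]
            es = synthesize_epochs(default_session, specs=specs,
                                   noise_sd=0.0, sampling_rate=250.0, seed=0)
            table, _, _ = measure_epochs(es)
            return table["mean_amplitude"].to_numpy()

        np.testing.assert_allclose(run(2.0), 2.0 * run(1.0), atol=1e-9)
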