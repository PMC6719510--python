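"""ERP pipeline: baseline, rereferencing, rejection, averaging, measures."""

import numpy as np
import pandas as pd
import pytest

from mmnload import erp
from mmnload.erp import (
    ERPWave,
    PipelineError,
    WindowSpec,
    baseline_correct,
    difference_wave,
    mean_amplitude,
    reject_epochs,
    rereference,
)
from mmnload.synthetic_eeg import (
    CHANNELS,
    EpochMatrix,
    NoiseSpec,
    SubjectGroundTruth,
    epoch_times_ms,
    simulate_subject,
)

from conftest import TABLE1_MEANS

FS = 128.0


def make_epochs(data, fs=FS, info=None):
    times = epoch_times_ms(fs)
    n_ep = data.shape[0]
    if info is None:
        info = pd.DataFrame({
            "block": 0, "load": "low", "tone_condition": "oddball",
            "role": "standard", "frequency": 550.0, "is_target": False,
            "is_warmup": False,
        }, index=range(n_ep))
    return EpochMatrix(CHANNELS, fs, times, data, info)


def wave(amplitudes, fs=FS, channels=CHANNELS):
    return ERPWave(tuple(channels), epoch_times_ms(fs), amplitudes)


class TestBaseline:
    def test_constant_epoch_becomes_zero(self):
        epochs = make_epochs(np.full((2, 5, len(epoch_times_ms(FS))), 5.0))
        out = baseline_correct(epochs)
        assert np.allclose(out.data, 0.0)

    def test_idempotent_when_baseline_already_zero(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(3, 5, len(epoch_times_ms(FS))))
        once = baseline_correct(make_epochs(data))
        twice = baseline_correct(once)
        assert np.allclose(once.data, twice.data)
        m = (once.times_ms >= -100) & (once.times_ms < 0)
        assert np.allclose(once.data[:, :, m].mean(axis=2), 0.0, atol=1e-12)

    def test_ramp_matches_closed_form(self):
        """Linear ramp from -1 uV at -100 ms to +5 uV at +500 ms: the value at
        0 ms after correction is the ramp value minus the baseline-sample mean."""
        times = epoch_times_ms(FS)
        ramp = -1.0 + 6.0 * (times + 100.0) / 600.0
        epochs = make_epochs(np.tile(ramp, (1, 5, 1)))
        out = baseline_correct(epochs)
        base = times[(times >= -100) & (times < 0)]
        expected_at_zero = (0.0 + 1.0 - 1.0) - np.mean(-1.0 + 6.0 * (base + 100.0) / 600.0)
        i0 = int(np.flatnonzero(times == 0.0)[0])
        assert out.data[0, 0, i0] == pytest.approx(expected_at_zero, abs=1e-12)

    def test_missing_prestimulus_errors(self):
        times = epoch_times_ms(FS)
        epochs = make_epochs(np.zeros((1, 5, len(times))))
        epochs.times_ms = times + 200.0  # shift so no pre-stimulus samples
        with pytest.raises(PipelineError):
            baseline_correct(epochs)


class TestRereference:
    def test_zero_mastoids_identity(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(2, 5, len(epoch_times_ms(FS))))
        data[:, 3:, :] = 0.0  # P9, P10
        out = rereference(make_epochs(data), "mastoid_mean")
        assert np.allclose(out.data, data)

    def test_mastoid_mean_is_zero_after(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(2, 5, len(epoch_times_ms(FS))))
        out = rereference(make_epochs(data), "mastoid_mean")
        assert np.allclose(out.data[:, 3:, :].mean(axis=1), 0.0, atol=1e-12)

    def test_common_signal_cancels_in_rereferenced_difference(self):
        """Adding any common waveform to all channels changes nothing about
        mastoid-referenced difference waves (linear-algebra identity)."""
        rng = np.random.default_rng(3)
        n_t = len(epoch_times_ms(FS))
        a, b = rng.normal(size=(2, 4, 5, n_t))
        common = rng.normal(size=n_t)
        def diff_after_reref(x, y):
            rx = rereference(make_epochs(x), "mastoid_mean").data.mean(axis=0)
            ry = rereference(make_epochs(y), "mastoid_mean").data.mean(axis=0)
            return rx - ry
        d0 = diff_after_reref(a, b)
        d1 = diff_after_reref(a + common, b + common)
        assert np.allclose(d0, d1, atol=1e-12)

    def test_round_trip_with_stored_reference(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(2, 5, len(epoch_times_ms(FS))))
        epochs = make_epochs(data)
        ref = epochs.data[:, 3:, :].mean(axis=1, keepdims=True)
        out = rereference(epochs, "mastoid_mean")
        assert np.allclose(out.data + ref, data, atol=1e-12)

    def test_unknown_scheme(self):
        with pytest.raises(PipelineError):
            rereference(make_epochs(np.zeros((1, 5, len(epoch_times_ms(FS))))), "ears")


def _mixed_info(n):
    rng = np.random.default_rng(0)
    load = rng.choice(["low", "high"], size=n)
    cond = rng.choice(["oddball", "control"], size=n)
    role = np.where(cond == "oddball",
                    rng.choice(["deviant", "standard"], size=n),
                    rng.choice(["critical", "control"], size=n))
    return pd.DataFrame({
        "block": 0, "load": load, "tone_condition": cond, "role": role,
        "frequency": 550.0, "is_target": False, "is_warmup": False,
    })


class TestRejection:
    def test_all_clean_all_retained(self):
        rng = np.random.default_rng(5)
        data = rng.uniform(-10, 10, size=(20, 5, len(epoch_times_ms(FS))))
        retained, report = reject_epochs(make_epochs(data, info=_mixed_info(20)), 100.0)
        assert retained.n_epochs == 20
        assert report.min_primary_retention == 1.0

    def test_constructed_artifacts_rejected(self):
        rng = np.random.default_rng(6)
        data = rng.uniform(-10, 10, size=(10, 5, len(epoch_times_ms(FS))))
        data[3, 1, 50] += 500.0
        data[7, 0, 10] -= 500.0
        retained, _ = reject_epochs(make_epochs(data, info=_mixed_info(10)), 200.0)
        assert retained.n_epochs == 8

    def test_condition_blind(self):
        """Permuting condition labels changes retention bookkeeping but never
        which epochs are kept."""
        rng = np.random.default_rng(7)
        data = rng.normal(0, 5, size=(50, 5, len(epoch_times_ms(FS))))
        data[rng.choice(50, 5, replace=False)] += 300.0
        info = _mixed_info(50)
        kept_a, _ = reject_epochs(make_epochs(data, info=info), 100.0)
        info_perm = info.sample(frac=1.0, random_state=1).reset_index(drop=True)
        kept_b, _ = reject_epochs(make_epochs(data, info=info_perm), 100.0)
        assert np.array_equal(kept_a.data, kept_b.data)

    def test_everything_rejected_is_an_error(self):
        data = np.random.default_rng(8).normal(0, 50, (5, 5, len(epoch_times_ms(FS))))
        with pytest.raises(PipelineError):
            reject_epochs(make_epochs(data, info=_mixed_info(5)), 1e-6)

    def test_retention_rule_with_five_percent_artifacts(
            self, session_default, table1_truth):
        """The spec'd inclusion rule: a subject with 5% artifact epochs and a
        calibrated percentile cutoff retains at least 70% in every cell."""
        noise = NoiseSpec(sd=3.0, artifact_rate=0.05, drift_sd=0.5)
        epochs = simulate_subject(session_default, table1_truth, noise, 128.0, 9)
        pre = rereference(baseline_correct(epochs), "nose")
        _, report = reject_epochs(pre, percentile=90.0)
        assert report.min_primary_retention >= 0.70


class TestAveragingAndMeasures:
    def test_opposite_epochs_average_to_zero(self):
        n_t = len(epoch_times_ms(FS))
        data = np.stack([np.ones((5, n_t)), -np.ones((5, n_t))])
        w = erp.average_erp(make_epochs(data), lambda info: np.ones(2, bool))
        assert np.allclose(w.amplitudes, 0.0)
        assert w.n_epochs == 2

    def test_single_epoch_identity(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(1, 5, len(epoch_times_ms(FS))))
        w = erp.average_erp(make_epochs(data), lambda info: np.ones(1, bool))
        assert np.array_equal(w.amplitudes, data[0])

    def test_sem_shrinks_with_root_n(self):
        rng = np.random.default_rng(10)
        n_t = len(epoch_times_ms(FS))
        signal = np.sin(np.linspace(0, 3, n_t))
        def rms_dev(n):
            data = signal + rng.normal(0, 2, size=(n, 5, n_t))
            w = erp.average_erp(make_epochs(data), lambda info: np.ones(n, bool))
            return np.sqrt(np.mean((w.amplitudes - signal) ** 2))
        r = rms_dev(64) / rms_dev(1024)
        assert r == pytest.approx(4.0, rel=0.5)  # 1/sqrt(n) scaling

    def test_empty_selection_errors(self):
        data = np.zeros((2, 5, len(epoch_times_ms(FS))))
        with pytest.raises(PipelineError, match="nothing"):
            erp.average_erp(make_epochs(data), lambda info: np.zeros(2, bool),
                            condition="nothing")

    def test_difference_wave_identities(self):
        rng = np.random.default_rng(11)
        a = wave(rng.normal(size=(5, len(epoch_times_ms(FS)))))
        zero = difference_wave(a, a)
        assert np.allclose(zero.amplitudes, 0.0)
        b = ERPWave(a.channels, a.times_ms, a.amplitudes + 2.0)
        assert np.allclose(difference_wave(b, a).amplitudes, 2.0)

    def test_difference_wave_linearity_of_mean_amplitude(self):
        rng = np.random.default_rng(12)
        spec = WindowSpec("w", ("Fz", "Cz"), (100.0, 200.0))
        a = wave(rng.normal(size=(5, len(epoch_times_ms(FS)))))
        b = wave(rng.normal(size=(5, len(epoch_times_ms(FS)))))
        lhs = mean_amplitude(difference_wave(a, b), spec)
        rhs = mean_amplitude(a, spec) - mean_amplitude(b, spec)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_axis_mismatch_errors(self):
        a = wave(np.zeros((5, len(epoch_times_ms(FS)))))
        b = wave(np.zeros((5, len(epoch_times_ms(256.0)))), fs=256.0)
        with pytest.raises(PipelineError):
            difference_wave(a, b)

    def test_mean_amplitude_constants(self):
        n_t = len(epoch_times_ms(FS))
        amps = np.zeros((5, n_t))
        amps[0] = 1.0  # Fz
        amps[1] = 3.0  # Cz
        spec = WindowSpec("w", ("Fz", "Cz"), (125.0, 175.0))
        assert mean_amplitude(wave(amps), spec) == pytest.approx(2.0)
        assert mean_amplitude(wave(np.full((5, n_t), 2.0)), spec) == pytest.approx(2.0)

    def test_mean_amplitude_ramp_closed_form(self):
        times = epoch_times_ms(FS)
        ramp = times / 100.0  # uV
        spec = WindowSpec("w", ("Fz",), (125.0, 175.0))
        m = (times >= 125.0) & (times <= 175.0)
        expected = ramp[m].mean()  # discrete mean of the analytic ramp
        got = mean_amplitude(wave(np.tile(ramp, (5, 1))), spec)
        assert got == pytest.approx(expected, abs=1e-12)
        # midpoint of the window within one sample spacing
        assert abs(got - 1.5) < (1000.0 / FS) / 100.0

    def test_window_without_samples_errors(self):
        w = wave(np.zeros((5, len(epoch_times_ms(FS)))))
        with pytest.raises(PipelineError):
            mean_amplitude(w, WindowSpec("w", ("Fz",), (100.0, 100.1)))


class TestExtractMeasures:
    def test_identical_conditions_give_zero_differences(
            self, session_small, quiet_noise):
        truth = SubjectGroundTruth("S0", {("n1", "low"): -1.0, ("n1", "high"): -1.0})
        epochs = simulate_subject(session_small, truth, quiet_noise, FS, 1)
        ms = erp.preprocess_and_measure(epochs, "S0", cutoff_uv=1e9)
        for name in ("oddball_mmn", "corrected_mmn", "p3a", "visual_p3"):
            for load in ("low", "high"):
                assert ms.value(name, load) == pytest.approx(0.0, abs=1e-10)

    def test_visual_p3_cancels_in_tone_differences(
            self, session_small, quiet_noise):
        """Injecting a visual P3 of any size leaves every tone difference
        measure unchanged, because targets are equally frequent on all tones."""
        base = {("oddball_mmn", "low"): -2.0, ("oddball_mmn", "high"): -2.0,
                ("p3a", "low"): 1.0, ("p3a", "high"): 1.0}
        with_p3 = dict(base)
        with_p3.update({("visual_p3", "low"): 9.0, ("visual_p3", "high"): 3.0})
        ms_a = erp.preprocess_and_measure(
            simulate_subject(session_small, SubjectGroundTruth("a", base),
                             quiet_noise, FS, 1), "a", cutoff_uv=1e9)
        ms_b = erp.preprocess_and_measure(
            simulate_subject(session_small, SubjectGroundTruth("b", with_p3),
                             quiet_noise, FS, 1), "b", cutoff_uv=1e9)
        for name in ("oddball_mmn", "corrected_mmn", "p3a", "n1"):
            for load in ("low", "high"):
                assert ms_a.value(name, load) == pytest.approx(
                    ms_b.value(name, load), abs=1e-10)

    def test_load_effect_identities(self, session_small, quiet_noise, table1_truth):
        epochs = simulate_subject(session_small, table1_truth, quiet_noise, FS, 1)
        ms = erp.preprocess_and_measure(epochs, "S1", cutoff_uv=1e9)
        assert ms.load_effect("n1") == pytest.approx(0.34, abs=1e-10)
        # anti-symmetry: swapping levels negates the effect
        swapped = {(c, {"low": "high", "high": "low"}[lv]): v
                   for (c, lv), v in ms.measures.items()}
        ms2 = erp.MeasureSet("S1", swapped)
        assert ms2.load_effect("n1") == pytest.approx(-ms.load_effect("n1"))

    def test_missing_cell_named_in_error(self, session_small, quiet_noise,
                                         table1_truth):
        epochs = simulate_subject(session_small, table1_truth, quiet_noise, FS, 1)
        only_low = epochs.select((epochs.info["load"] == "low").to_numpy())
        with pytest.raises(PipelineError, match="high"):
            erp.extract_measures(only_low)

    def test_p3a_deviant_only_variant(self, session_small, quiet_noise):
        truth = SubjectGroundTruth("S0", {("p3a", "low"): 2.0, ("p3a", "high"): 2.0})
        epochs = simulate_subject(session_small, truth, quiet_noise, FS, 1)
        diff = erp.preprocess_and_measure(epochs, cutoff_uv=1e9)
        dev_only = erp.preprocess_and_measure(epochs, cutoff_uv=1e9,
                                              p3a_deviant_only=True)
        # no standard-tone P3a injected, so both conventions agree here
        assert dev_only.value("p3a", "low") == pytest.approx(
            diff.value("p3a", "low"), abs=1e-10)


def test_lowpass_is_presentation_only(session_small, table1_truth, quiet_noise):
    epochs = simulate_subject(session_small, table1_truth, quiet_noise, FS, 1)
    w = erp.average_erp(epochs, lambda info: (info["role"] == "deviant").to_numpy())
    smoothed = erp.lowpass_for_plotting(w, FS)
    assert smoothed.amplitudes.shape == w.amplitudes.shape
    assert not np.array_equal(smoothed.amplitudes, w.amplitudes)
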