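"""Pupil preprocessing: interpolation, deconvolution, filtering, epochs."""

import numpy as np
import pandas as pd
import pytest

from pupilbias import pupil, synthetic
from pupilbias.io import EyeRecording

from conftest import make_trials


def _recording(pupil_signal, rate=1000.0, events=None):
    n = len(pupil_signal)
    ev = pd.DataFrame(events or [(0.0, "block_start", "")],
                      columns=["t", "kind", "label"])
    return EyeRecording(time=np.arange(n) / rate,
                        pupil=np.asarray(pupil_signal, float),
                        gaze_x=np.zeros(n), gaze_y=np.zeros(n),
                        rate=rate, events=ev)


class TestInterpolateBlinks:
    def test_smooth_signal_untouched(self):
        t = np.arange(5000) / 1000.0
        rec = _recording(100 + 5 * np.sin(2 * np.pi * 0.5 * t))
        out = pupil.interpolate_blinks(rec)
        np.testing.assert_array_equal(out.pupil, rec.pupil)
        assert not out.interp_mask.any()

    def test_dropout_padded_and_linear(self):
        sig = np.full(5000, 100.0)
        sig[2000:2200] = 0.0   # 200 ms dropout
        events = [(0.0, "block_start", ""), (2.0, "blink_start", ""),
                  (2.2, "blink_end", "")]
        rec = _recording(sig, events=events)
        out = pupil.interpolate_blinks(rec, pad=0.15)
        # interpolated span = 200 + 2*150 = 500 ms
        assert out.interp_mask.sum() == pytest.approx(500, abs=2)
        # values lie on the line joining the pad endpoints (flat here)
        np.testing.assert_allclose(out.pupil, 100.0, atol=1e-9)

    def test_velocity_step_detected(self):
        rng = np.random.default_rng(0)
        sig = 100 + rng.normal(0, 0.5, 8000).cumsum() * 0.01
        sig[4000:4100] -= 80.0   # extreme-velocity step artifact
        rec = _recording(sig)
        out = pupil.interpolate_blinks(rec)
        assert out.interp_mask[4000:4100].all()
        assert np.abs(out.pupil[4000:4100] - 100).max() < 5.0

    def test_whole_recording_artifact_rejected(self):
        sig = np.full(2000, 100.0)
        events = [(0.0, "blink_start", ""), (1.999, "blink_end", "")]
        rec = _recording(sig, events=events)
        with pytest.raises(ValueError, match="entire"):
            pupil.interpolate_blinks(rec)


@pytest.fixture(scope="module")
def constructed():
    rng = np.random.default_rng(1)
    rate, dur = 1000.0, 300.0
    n = int(rate * dur)
    t = np.arange(0, 6.0, 1 / rate)
    kernel = 4.0 * synthetic.pupil_irf(t, 0.8, 8.0)
    onsets = np.sort(rng.uniform(5, dur - 10, 40))
    train = np.zeros(n)
    train[(onsets * rate).astype(int)] = 1.0
    sig = np.convolve(train, kernel)[:n] + rng.normal(0, 0.3, n)
    events = [(0.0, "block_start", "")]
    events += [(o, "blink_end", "") for o in onsets]
    rec = _recording(sig, events=events)
    return rec, kernel, train


class TestDeconvolution:
    def test_kernel_recovered_and_variance_removed(self, constructed):
        rec, kernel, train = constructed
        out, kernels = pupil.remove_event_responses(rec, ("blink_end",))
        est = np.repeat(kernels["blink_end"], 100)   # 10 Hz taps to 1 kHz
        r = np.corrcoef(est, kernel[:len(est)])[0, 1]
        assert r >= 0.95
        # event-locked variance reduced by >= 80 %
        def locked_var(x):
            segs = []
            for o in np.flatnonzero(train):
                if o + 3000 < len(x):
                    segs.append(x[o:o + 3000])
            m = np.mean(segs, axis=0)
            return np.var(m)
        assert locked_var(out.pupil) < 0.2 * locked_var(rec.pupil)

    def test_no_events_identity(self):
        rec = _recording(np.sin(np.arange(5000) / 500))
        out, kernels = pupil.remove_event_responses(rec)
        np.testing.assert_array_equal(out.pupil, rec.pupil)
        assert kernels == {}

    def test_two_event_types_separated(self):
        rng = np.random.default_rng(2)
        rate, dur = 1000.0, 400.0
        n = int(rate * dur)
        t = np.arange(0, 6.0, 1 / rate)
        k1 = 5.0 * synthetic.pupil_irf(t, 0.6, 6.0)
        k2 = -3.0 * synthetic.pupil_irf(t, 1.5, 12.0)
        sig = rng.normal(0, 0.3, n)
        events = [(0.0, "block_start", "")]
        for kind, kern in (("blink_end", k1), ("saccade_end", k2)):
            onsets = np.sort(rng.uniform(5, dur - 10, 35))
            for o in onsets:
                i = int(o * rate)
                seg = min(len(kern), n - i)
                sig[i:i + seg] += kern[:seg]
                events.append((o, kind, ""))
        events.sort()
        rec = _recording(sig, events=events)
        _, kernels = pupil.remove_event_responses(
            rec, ("blink_end", "saccade_end"))
        for kind, kern in (("blink_end", k1), ("saccade_end", k2)):
            est = np.repeat(kernels[kind], 100)
            assert np.corrcoef(est, kern[:len(est)])[0, 1] >= 0.9

    def test_few_events_skipped_with_warning(self):
        events = [(0.0, "block_start", ""), (1.0, "blink_end", "")]
        rec = _recording(np.random.default_rng(3).normal(0, 1, 5000),
                         events=events)
        with pytest.warns(UserWarning, match="skipping"):
            out, kernels = pupil.remove_event_responses(rec, ("blink_end",))
        assert kernels == {}


class TestBandpassZscoreResample:
    def test_constant_input_zeroed(self):
        rec = _recording(np.full(60_000, 123.4))
        with pytest.warns(UserWarning, match="time constants"):
            out = pupil.bandpass_zscore_resample(rec)
        assert np.abs(out.pupil).max() < 1e-6

    def test_passband_and_stopband(self):
        # two equal-amplitude tones: their output ratio isolates the filter
        # gain from the z-scoring; oracle = analytic Butterworth magnitude
        # (squared for the forward-backward pass)
        rate, dur = 1000.0, 600.0
        t = np.arange(int(dur * rate)) / rate
        sig = np.sin(2 * np.pi * 5.0 * t) + np.sin(2 * np.pi * 20.0 * t)
        with np.errstate(all="ignore"):
            out = pupil.bandpass_zscore_resample(_recording(sig, rate))
        spec = np.abs(np.fft.rfft(out.pupil))
        freqs = np.fft.rfftfreq(len(out.pupil), 1 / out.rate)
        a5 = spec[np.argmin(np.abs(freqs - 5.0))]
        a20 = spec[np.argmin(np.abs(freqs - 20.0))]
        # input tones are equal, so a20/a5 = |H(20)|^2 / |H(5)|^2
        gain_ratio = a20 / a5
        w5, w20 = 5.0 / 10.0, 20.0 / 10.0   # normalized to the 10 Hz corner
        h = lambda w: 1.0 / np.sqrt(1 + w ** 4)     # 2nd-order low-pass
        oracle = (h(w20) / h(w5)) ** 2
        assert gain_ratio == pytest.approx(oracle, rel=0.15)
        assert h(w5) ** 2 > 0.9 and h(w20) ** 2 < 0.5

    def test_output_grid_is_100hz(self):
        rec = _recording(np.random.default_rng(4).normal(0, 1, 40_000))
        with pytest.warns(UserWarning):
            out = pupil.bandpass_zscore_resample(rec)
        assert out.rate == 100.0
        np.testing.assert_allclose(np.diff(out.time), 0.01, atol=1e-12)

    def test_zscored_per_run(self):
        rec = _recording(
            np.random.default_rng(5).normal(0, 3, 400_000) + 50)
        out = pupil.bandpass_zscore_resample(rec)
        assert abs(out.pupil.mean()) < 0.05
        assert out.pupil.std() == pytest.approx(1.0, abs=0.05)


@pytest.fixture(scope="module")
def trials():
    return make_trials(n_blocks=1, seed=6)


class TestEpochs:

    def test_constant_trace_zero_epochs(self, trials):
        n = int((trials.t_feedback.max() + 5) * 100)
        rec = EyeRecording(np.arange(n) / 100.0, np.full(n, 2.5),
                           np.zeros(n), np.zeros(n), 100.0,
                           pd.DataFrame([(0.0, "block_start", "")],
                                        columns=["t", "kind", "label"]))
        ep = pupil.epoch_and_baseline(rec, trials)
        assert np.nanmax(np.abs(ep.data_ref)) < 1e-12
        np.testing.assert_allclose(ep.baseline, 2.5)

    def test_known_offsets_recovered_as_baselines(self, trials):
        n = int((trials.t_feedback.max() + 5) * 100)
        sig = np.zeros(n)
        offsets = np.arange(len(trials)) * 0.1
        for off, t0, t1 in zip(offsets, trials.t_ref_on - 1.0,
                               trials.t_feedback):
            sig[int(t0 * 100):int(t1 * 100)] = off
        rec = EyeRecording(np.arange(n) / 100.0, sig, np.zeros(n),
                          np.zeros(n), 100.0,
                          pd.DataFrame([(0.0, "block_start", "")],
                                       columns=["t", "kind", "label"]))
        ep = pupil.epoch_and_baseline(rec, trials)
        np.testing.assert_allclose(ep.baseline, offsets, atol=1e-9)

    def test_scalar_window_arithmetic(self, trials):
        n = int((trials.t_feedback.max() + 5) * 100)
        sig = np.zeros(n)
        for tf in trials.t_feedback:
            sig[int((tf - 0.25) * 100):int(tf * 100)] = 1.0
        rec = EyeRecording(np.arange(n) / 100.0, sig, np.zeros(n),
                          np.zeros(n), 100.0,
                          pd.DataFrame([(0.0, "block_start", "")],
                                       columns=["t", "kind", "label"]))
        ep = pupil.epoch_and_baseline(rec, trials)
        scal = pupil.scalar_pupil_response(ep)
        np.testing.assert_allclose(scal, 1.0, atol=0.05)

    def test_epoch_past_recording_flagged(self, trials):
        n = int((trials.t_feedback.iloc[-2]) * 100)   # truncate recording
        rec = EyeRecording(np.arange(n) / 100.0, np.zeros(n), np.zeros(n),
                          np.zeros(n), 100.0,
                          pd.DataFrame([(0.0, "block_start", "")],
                                       columns=["t", "kind", "label"]))
        ep = pupil.epoch_and_baseline(rec, trials)
        assert not ep.valid[-1]
        assert ep.valid[:len(trials) - 2].all()


class TestResidualize:
    def test_orthogonal_unchanged(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        r = np.array([1.0, 1.0, -1.0, -1.0])
        np.testing.assert_allclose(
            pupil.residualize(y, r, zscore=False), y)

    def test_proportional_annihilated(self):
        r = np.linspace(0.5, 2.0, 20)
        np.testing.assert_allclose(pupil.residualize(3 * r, r, zscore=False),
                                   0.0, atol=1e-12)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(7)
        y, r = rng.normal(0, 1, 50), rng.normal(0, 1, 50)
        got = pupil.residualize(y, r, zscore=True)
        # oracle: OLS residual of standardized y on [1, r]
        ys = (y - y.mean()) / y.std()
        x = np.column_stack([np.ones(50), r - r.mean()])
        beta, *_ = np.linalg.lstsq(x, ys, rcond=None)
        np.testing.assert_allclose(got, ys - x @ beta, atol=1e-10)

    def test_idempotent_and_decorrelated(self):
        rng = np.random.default_rng(8)
        y = rng.normal(0, 1, 100)
        r = 0.5 * y + rng.normal(0, 1, 100)
        once = pupil.residualize(y, r)
        twice = pupil.residualize(once, r, zscore=False)
        np.testing.assert_allclose(once, twice, atol=1e-12)
        assert abs(np.corrcoef(once, r)[0, 1]) < 1e-10

    def test_zero_covariate_rejected(self):
        with pytest.raises(ValueError):
            pupil.residualize(np.ones(5), np.zeros(5), zscore=False)


class TestEndToEnd:
    def test_noiseless_recovery(self):
        trials, truth = make_trials(n_blocks=1, seed=9, return_truth=True)
        rec = synthetic.synthesize_eye_recording(
            trials, amplitudes=truth.pupil_true.to_numpy(),
            blink_rate=0.0, noise_sd=0.0, drift_sd=0.0, seed=10)
        _, up = pupil.preprocess_block(rec, trials, residualize_rt=False)
        r = np.corrcoef(up.pupil_response, truth.pupil_true)[0, 1]
        assert r >= 0.99

    def test_default_noise_recovery(self):
        trials, truth = make_trials(n_blocks=1, seed=12, return_truth=True)
        rec = synthetic.synthesize_eye_recording(
            trials, amplitudes=truth.pupil_true.to_numpy(), seed=13)
        _, up = pupil.preprocess_block(rec, trials, residualize_rt=False)
        good = ~np.isnan(up.pupil_response)
        r = np.corrcoef(up.pupil_response[good],
                        truth.pupil_true[good])[0, 1]
        assert r >= 0.95
        assert np.isfinite(up.frac_interp).all()
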