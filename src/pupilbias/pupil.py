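"""Pupillometry preprocessing: from raw traces to single-trial responses.

Pipeline (one eye-tracker run = one block between calibrations):

1. blink interpolation — tracker-flagged blink intervals plus extra
   dropouts found by velocity peak detection are padded by 150 ms and
   linearly interpolated,
2. deconvolution cleanup — FIR kernels for blink- and saccade-evoked pupil
   responses are estimated by least squares and regressed out,
3. band-pass (0.01-10 Hz, second-order Butterworth, zero-phase), z-score
   per run, resample to 100 Hz,
4. epoching locked to reference onset and to feedback, baseline =
   mean pupil in the 500 ms before reference onset,
5. scalar pupil response = mean baseline-corrected signal in the 250 ms
   before feedback,
6. residualization of the scalars against log RT (projection onto the
   unit-normalized RT vector), isolating amplitude from duration effects
   of the sluggish peripheral pupil apparatus.

Trials are never excluded for interpolation; the per-trial fraction of
interpolated samples is reported as a diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .io import EyeRecording


# ---------------------------------------------------------------------------
# Blink interpolation
# ---------------------------------------------------------------------------

def _merge_intervals(intervals):
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for a, b in intervals[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(iv) for iv in out]


def detect_velocity_artifacts(pupil: np.ndarray, rate: float,
                              nsd: float = 10.0) -> list[tuple[float, float]]:
    """Artifact intervals (s) where |pupil velocity| exceeds ``nsd`` robust
    SDs of the velocity distribution (median absolute deviation based)."""
    v = np.diff(pupil) * rate
    mad = np.median(np.abs(v - np.median(v)))
    rsd = 1.4826 * mad
    # floor: a genuine dropout jumps by a sizeable fraction of the signal
    # range within one sample, far beyond any physiological slope
    thr = max(nsd * rsd, 50.0 * np.std(pupil))
    if thr == 0:
        return []
    bad = np.abs(v - np.median(v)) > thr
    # bridge single-sample gaps so one artifact forms one interval
    idx = np.flatnonzero(bad)
    if idx.size == 0:
        return []
    intervals = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > int(0.05 * rate):
            intervals.append((start / rate, (prev + 1) / rate))
            start = i
        prev = i
    intervals.append((start / rate, (prev + 1) / rate))
    return intervals


def interpolate_blinks(rec: EyeRecording, pad: float = 0.15,
                       velocity_nsd: float = 10.0) -> EyeRecording:
    """Linearly interpolate blink intervals, padded by ``pad`` seconds.

    Intervals come from paired blink_start/blink_end events plus velocity
    peak detection. Returns a copy with the interpolation mask set; raises
    if an interval covers the entire recording.
    """
    out = rec.copy()
    t0 = rec.time[0]
    starts = rec.events_of_kind("blink_start")
    ends = rec.events_of_kind("blink_end")
    if len(starts) != len(ends):
        raise ValueError("unpaired blink_start/blink_end events")
    intervals = list(zip(starts, ends))
    intervals += [(a + t0, b + t0) for a, b in
                  detect_velocity_artifacts(rec.pupil, rec.rate, velocity_nsd)]
    if not intervals:
        return out

    dur = rec.time[-1] - rec.time[0]
    padded = _merge_intervals(
        [(max(a - pad, t0), min(b + pad, rec.time[-1])) for a, b in intervals])
    mask = np.zeros(len(rec.time), dtype=bool)
    for a, b in padded:
        if b - a >= dur:
            raise ValueError("artifact interval covers the entire recording")
        i0 = int(np.searchsorted(rec.time, a, side="left"))
        i1 = int(np.searchsorted(rec.time, b, side="right"))
        mask[i0:i1] = True
    good = ~mask
    if good.sum() < 2:
        raise ValueError("artifact intervals cover the entire recording")
    out.pupil = out.pupil.copy()
    out.pupil[mask] = np.interp(rec.time[mask], rec.time[good],
                                rec.pupil[good])
    out.interp_mask = rec.interp_mask | mask
    return out


# ---------------------------------------------------------------------------
# Event-response deconvolution
# ---------------------------------------------------------------------------

def remove_event_responses(rec: EyeRecording,
                           event_kinds: tuple[str, ...] = ("blink_end",
                                                           "saccade_end"),
                           window: float = 6.0,
                           tap_rate: float = 10.0,
                           min_events: int = 5):
    """Estimate and subtract event-evoked pupil responses by deconvolution.

    For each event type, an FIR kernel (boxcar taps at ``tap_rate`` Hz over
    ``window`` s) is estimated jointly for all types by least squares, and
    the fitted event-locked responses are subtracted. Event types with
    fewer than ``min_events`` occurrences are skipped with a warning.

    Returns (cleaned recording, dict of estimated kernels).
    """
    kinds = []
    for kind in event_kinds:
        n_ev = len(rec.events_of_kind(kind))
        if n_ev == 0:
            continue
        if n_ev < min_events:
            warnings.warn(f"only {n_ev} {kind!r} events; skipping type")
            continue
        kinds.append(kind)
    out = rec.copy()
    if not kinds:
        return out, {}

    n = len(rec.time)
    n_taps = int(round(window * tap_rate))
    tap_len = int(round(rec.rate / tap_rate))
    cols = []
    for kind in kinds:
        times = rec.events_of_kind(kind)
        onsets = np.round((times - rec.time[0]) * rec.rate).astype(int)
        block = np.zeros((n, n_taps), dtype=np.float32)
        for j in range(n_taps):
            for i0 in onsets + j * tap_len:
                i1 = min(i0 + tap_len, n)
                if i0 < n:
                    block[i0:i1, j] = 1.0
        cols.append(block)
    x = np.concatenate(cols, axis=1)
    x = np.column_stack([np.ones(n, dtype=np.float32), x])
    y = rec.pupil - rec.pupil.mean()
    # normal equations: the design is tall (minutes at 1 kHz) and skinny
    xtx = (x.T @ x).astype(float)
    xtx[np.diag_indices_from(xtx)] += 1e-8
    beta = np.linalg.solve(xtx, x.T @ y)
    fitted = x[:, 1:] @ beta[1:]
    out.pupil = rec.pupil - fitted
    kernels = {kind: beta[1 + i * n_taps: 1 + (i + 1) * n_taps]
               for i, kind in enumerate(kinds)}
    return out, kernels


# ---------------------------------------------------------------------------
# Filtering, normalization, resampling
# ---------------------------------------------------------------------------

def bandpass_zscore_resample(rec: EyeRecording, low: float = 0.01,
                             high: float = 10.0, order: int = 2,
                             out_rate: float = 100.0) -> EyeRecording:
    """Zero-phase Butterworth band-pass, z-score per run, resample.

    The recording (one run) is band-pass filtered between ``low`` and
    ``high`` Hz with a second-order Butterworth applied forward-backward,
    normalized to zero mean and unit SD, and decimated to ``out_rate``
    (safe because the pass-band already ends below the output Nyquist).
    """
    if rec.rate <= 2 * high:
        raise ValueError("sampling rate must exceed twice the upper cutoff")
    factor = rec.rate / out_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("out_rate must divide the sampling rate")
    factor = int(round(factor))
    dur = rec.time[-1] - rec.time[0]
    if dur < 3.0 / low:
        warnings.warn(
            f"run of {dur:.0f}s is shorter than 3 time constants of the "
            f"{low} Hz high-pass; slow-drift removal will be imperfect")

    sos = signal.butter(order, [low, high], btype="bandpass",
                        fs=rec.rate, output="sos")
    # remove the DC level first: the 0.01 Hz high-pass corner is far
    # slower than a run, so its DC edge transient would never decay
    filt = signal.sosfiltfilt(sos, rec.pupil - rec.pupil.mean())
    sd = filt.std()
    # guard: a (near-)constant run leaves only numerical ripple after the
    # band-pass, which must not be amplified to unit variance
    scale = max(np.abs(rec.pupil).max(), 1.0)
    z = (filt - filt.mean()) / (sd if sd > 1e-10 * scale else 1.0)

    n_out = len(z) // factor
    sl = slice(0, n_out * factor)
    out = EyeRecording(
        time=rec.time[sl][::factor],
        pupil=z[sl][::factor],
        gaze_x=rec.gaze_x[sl][::factor],
        gaze_y=rec.gaze_y[sl][::factor],
        rate=out_rate,
        events=rec.events.copy(),
        interp_mask=rec.interp_mask[sl].reshape(n_out, factor).any(axis=1),
    )
    return out


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

@dataclass
class Epochs:
    """Per-trial pupil segments on a common grid, baseline corrected.

    ``data_ref``/``data_fb`` are (n_trials, n_samples) arrays locked to
    reference onset and to feedback; NaN where the epoch extends past the
    recording. ``valid`` flags trials fully inside the recording.
    """

    time_ref: np.ndarray
    data_ref: np.ndarray
    time_fb: np.ndarray
    data_fb: np.ndarray
    mask_fb: np.ndarray          # interpolated-sample mask, feedback-locked
    baseline: np.ndarray
    frac_interp: np.ndarray
    valid: np.ndarray
    trial_index: np.ndarray
    rate: float


def _extract(rec, t_events, lo, hi):
    n_t = int(round((hi - lo) * rec.rate))
    offsets = np.arange(n_t)
    data = np.full((len(t_events), n_t), np.nan)
    mask = np.zeros((len(t_events), n_t), dtype=bool)
    ok = np.zeros(len(t_events), dtype=bool)
    for i, te in enumerate(t_events):
        i0 = int(round((te + lo - rec.time[0]) * rec.rate))
        idx = i0 + offsets
        inside = (idx >= 0) & (idx < len(rec.time))
        data[i, inside] = rec.pupil[idx[inside]]
        mask[i, inside] = rec.interp_mask[idx[inside]]
        ok[i] = inside.all()
    times = lo + offsets / rec.rate
    return times, data, mask, ok


def epoch_and_baseline(rec: EyeRecording, trials: pd.DataFrame,
                       baseline_window: float = 0.5,
                       ref_window: tuple[float, float] = (-0.5, 7.5),
                       fb_window: tuple[float, float] = (-3.0, 2.0)) -> Epochs:
    """Epoch a preprocessed recording around reference onset and feedback.

    Baseline is the mean pupil in the ``baseline_window`` seconds before
    reference onset and is subtracted from both epoch sets. Trials whose
    epochs extend past the recording are flagged in ``valid``, not dropped.
    """
    t_ref = trials["t_ref_on"].to_numpy(float)
    t_fb = trials["t_feedback"].to_numpy(float)

    time_ref, data_ref, mask_ref, ok_ref = _extract(rec, t_ref, *ref_window)
    time_fb, data_fb, mask_fb, ok_fb = _extract(rec, t_fb, *fb_window)

    base_cols = time_ref >= -baseline_window
    base_cols &= time_ref < 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        baseline = np.nanmean(data_ref[:, base_cols], axis=1)

    data_ref = data_ref - baseline[:, None]
    data_fb = data_fb - baseline[:, None]

    frac = np.zeros(len(trials))
    for i, (a, b) in enumerate(zip(t_ref, t_fb)):
        i0 = int(round((a - baseline_window - rec.time[0]) * rec.rate))
        i1 = int(round((b - rec.time[0]) * rec.rate))
        i0, i1 = max(i0, 0), min(i1, len(rec.time))
        frac[i] = rec.interp_mask[i0:i1].mean() if i1 > i0 else np.nan

    return Epochs(time_ref=time_ref, data_ref=data_ref,
                  time_fb=time_fb, data_fb=data_fb, mask_fb=mask_fb,
                  baseline=baseline, frac_interp=frac,
                  valid=ok_ref & ok_fb,
                  trial_index=trials.index.to_numpy(), rate=rec.rate)


def scalar_pupil_response(epochs: Epochs, window: float = 0.25) -> np.ndarray:
    """Mean baseline-corrected pupil in the ``window`` s before feedback.

    NaN where the window is entirely interpolated or missing.
    """
    cols = (epochs.time_fb >= -window) & (epochs.time_fb < 0)
    seg = epochs.data_fb[:, cols].copy()
    seg[epochs.mask_fb[:, cols]] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(seg, axis=1)


# ---------------------------------------------------------------------------
# Residualization
# ---------------------------------------------------------------------------

def residualize(y: np.ndarray, r: np.ndarray, log_transform: bool = False,
                zscore: bool = True) -> np.ndarray:
    """Project the covariate r out of y:  y' = y - r_u (r_u^T y).

    ``r`` is optionally log-transformed, optionally centred/scaled together
    with ``y`` (default), and normalized to a unit vector before the
    projection; with centring the residual has exactly zero correlation
    with the covariate. The projection is idempotent.
    """
    y = np.asarray(y, float).copy()
    r = np.asarray(r, float).copy()
    if y.shape != r.shape or y.ndim != 1:
        raise ValueError("y and r must be equal-length vectors")
    if np.isnan(y).any() or np.isnan(r).any():
        raise ValueError("NaN values not allowed; mask them first")
    if log_transform:
        if np.any(r <= 0):
            raise ValueError("log transform requires positive covariate")
        r = np.log(r)
    if zscore:
        y = y - y.mean()
        r = r - r.mean()
        sd = y.std()
        if sd > 0:
            y = y / sd
    nrm = np.linalg.norm(r)
    if nrm == 0:
        raise ValueError("covariate is identically zero")
    r_u = r / nrm
    return y - r_u * (r_u @ y)


# ---------------------------------------------------------------------------
# Full pipeline for one block
# ---------------------------------------------------------------------------

def preprocess_block(rec: EyeRecording, trials: pd.DataFrame,
                     blink_pad: float = 0.15, velocity_nsd: float = 10.0,
                     deconv_window: float = 6.0, band=(0.01, 10.0),
                     out_rate: float = 100.0, baseline_window: float = 0.5,
                     response_window: float = 0.25,
                     residualize_rt: bool = True):
    """Run the full preprocessing chain for one block.

    Returns (epochs, updated trials) where the trial table gains
    ``pupil_baseline`` and ``pupil_response`` (residualized against log RT
    when ``residualize_rt``), plus a ``frac_interp`` diagnostic column.
    """
    rec1 = interpolate_blinks(rec, pad=blink_pad, velocity_nsd=velocity_nsd)
    rec2, _ = remove_event_responses(rec1, window=deconv_window)
    rec3 = bandpass_zscore_resample(rec2, band[0], band[1],
                                    out_rate=out_rate)
    epochs = epoch_and_baseline(rec3, trials,
                                baseline_window=baseline_window)
    scalars = scalar_pupil_response(epochs, window=response_window)
    out = trials.copy()
    out["pupil_baseline"] = epochs.baseline
    out["frac_interp"] = epochs.frac_interp
    if residualize_rt:
        good = ~np.isnan(scalars)
        resid = np.full(len(scalars), np.nan)
        resid[good] = residualize(scalars[good],
                                  out.loc[good, "rt"].to_numpy(),
                                  log_transform=True)
        out["pupil_response"] = resid
    else:
        out["pupil_response"] = scalars
    out["pupil_response_raw"] = scalars
    return epochs, out
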