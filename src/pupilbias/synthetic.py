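"""Synthetic study data with the statistical structure the analysis assumes.

Four generators:

* counterbalanced stimulus-category sequences (blocks of 53 trials with
  exactly 26 category repeats and 26 alternations among the 52 transitions,
  truncated to 50),
* a generative history-biased SDT observer with lapses whose pupil and RT
  scale with decision uncertainty,
* continuous 1000-Hz eye-tracker recordings built from per-trial pupil
  impulses convolved with a canonical pupil impulse-response function, plus
  drift, blink dropouts and measurement noise,
* random-dot kinematogram (RDK) movies with signal/noise dots, limited dot
  lifetime and three interleaved motion subsequences.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .io import EyeRecording, TRIAL_COLUMNS, validate_trial_table

#: The three difficulty sets of unsigned motion-coherence differences (%).
COHERENCE_SETS = {
    "easy": (2.5, 5.0, 10.0, 20.0, 30.0),
    "medium": (1.25, 2.5, 5.0, 10.0, 30.0),
    "hard": (0.625, 1.25, 2.5, 5.0, 20.0),
}

FULL_SEQUENCE_LEN = 53   # generated per block; first 50 are used


def generate_stimulus_sequence(n_blocks: int, coherence_set: str = "easy",
                               block_len: int = 50,
                               seed: int | np.random.Generator = 0,
                               ) -> pd.DataFrame:
    """Counterbalanced stimulus sequences for ``n_blocks`` blocks.

    Each block starts from a 53-trial category sequence whose 52
    consecutive-trial transitions contain exactly 26 repeats and 26
    alternations in shuffled order, integrated from a random initial
    category, then truncated to the first ``block_len`` trials. Unsigned
    coherence levels are assigned within each category by cycling through
    the 5-level set and shuffling, so level counts per category are as
    equal as possible.

    Returns a DataFrame (block, trial, stim_category, coherence_diff) where
    ``coherence_diff = stim_category * level``.
    """
    if coherence_set not in COHERENCE_SETS:
        raise ValueError(
            f"unknown coherence_set {coherence_set!r}; "
            f"expected one of {sorted(COHERENCE_SETS)}")
    if not 1 <= block_len <= FULL_SEQUENCE_LEN:
        raise ValueError(f"block_len must be in [1, {FULL_SEQUENCE_LEN}]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    levels = np.asarray(COHERENCE_SETS[coherence_set])

    rows = []
    for b in range(1, n_blocks + 1):
        cats = _balanced_category_sequence(rng)[:block_len]
        coh = np.empty(block_len)
        for cat in (-1, 1):
            m = cats == cat
            coh[m] = cat * _balanced_levels(levels, int(m.sum()), rng)
        for t in range(block_len):
            rows.append((b, t, int(cats[t]), coh[t]))
    return pd.DataFrame(
        rows, columns=["block", "trial", "stim_category", "coherence_diff"])


def _balanced_category_sequence(rng: np.random.Generator) -> np.ndarray:
    """One 53-trial +/-1 sequence with 26 repeat + 26 alternate transitions."""
    n_trans = FULL_SEQUENCE_LEN - 1
    trans = np.array([1] * (n_trans // 2) + [-1] * (n_trans // 2))
    rng.shuffle(trans)
    cats = np.empty(FULL_SEQUENCE_LEN, dtype=int)
    cats[0] = rng.choice([-1, 1])
    cats[1:] = cats[0] * np.cumprod(trans)
    return cats


def _balanced_levels(levels: np.ndarray, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """n draws from levels with counts as equal as possible, shuffled."""
    reps = np.tile(levels, n // len(levels))
    extra = rng.choice(levels, n % len(levels), replace=False)
    out = np.concatenate([reps, extra])
    rng.shuffle(out)
    return out


def transition_repeat_frequency(categories: np.ndarray) -> float:
    """Fraction of consecutive-trial transitions that repeat the category."""
    cats = np.asarray(categories)
    if len(cats) < 2:
        raise ValueError("need at least two trials")
    return float(np.mean(cats[1:] == cats[:-1]))


# ---------------------------------------------------------------------------
# Generative observer
# ---------------------------------------------------------------------------

def _lagvec(x, default=0.0, n=7):
    v = np.full(n, default, float)
    if x is not None:
        x = np.atleast_1d(np.asarray(x, float))
        v[:len(x)] = x[:n]
    return v


@dataclass
class ObserverParams:
    """Parameters of the generative history-biased observer.

    The decision variable is dv = mu_t + sigma * eta with mu_t the trial's
    signed evidence and eta standard Gaussian (or standard logistic when
    ``noise='logistic'``, which makes the fitted logistic-regression weights
    directly comparable to the generating ones). The effective criterion is
    shifted trial by trial:

        c_t = c - sigma * b_t,
        b_t = overall_bias + sum_k [ kernel_choice[k] * choice_{t-k}
                                     + kernel_stim[k] * stim_{t-k}
                                     + pupil_{t-k} * (mod_pupil_choice[k] * choice_{t-k}
                                                      + mod_pupil_stim[k] * stim_{t-k})
                                     + rt_{t-k} * (mod_rt_choice[k] * choice_{t-k}
                                                   + mod_rt_stim[k] * stim_{t-k}) ]

    so bias weights are expressed in criterion units of sigma (= logit units
    for the logistic observer). Modulator values (pupil response, log RT)
    enter in standardized units. Uncertainty is 1 - F(|dv - c_t| / sigma)
    with F the noise CDF; pupil and RT scale linearly with uncertainty.
    """

    sigma: float = 2.723
    c: float = 0.0
    overall_bias: float = 0.0
    kernel_choice: np.ndarray | None = None
    kernel_stim: np.ndarray | None = None
    mod_pupil_choice: np.ndarray | None = None
    mod_pupil_stim: np.ndarray | None = None
    mod_rt_choice: np.ndarray | None = None
    mod_rt_stim: np.ndarray | None = None
    lapse: float = 0.0
    noise: str = "gaussian"          # 'gaussian' or 'logistic'
    n_lags: int = 7
    # uncertainty -> pupil / RT mapping
    pupil_gain: float = 2.0          # z-units per unit uncertainty
    pupil_noise: float = 0.25        # additive Gaussian SD, z-units
    rt_base: float = 0.35            # s
    rt_gain: float = 1.0             # s per unit uncertainty
    rt_noise: float = 0.2            # SD of the log-normal additive term
    # evidence model: evidence = evidence_scale * coherence_diff + noise
    evidence_scale: float = 0.15     # motion-energy units per % coherence
    evidence_noise: float = 0.8      # motion-energy units

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.lapse < 0.5:
            raise ValueError("lapse must lie in [0, 0.5)")
        if self.noise not in ("gaussian", "logistic"):
            raise ValueError("noise must be 'gaussian' or 'logistic'")
        for name in ("kernel_choice", "kernel_stim", "mod_pupil_choice",
                     "mod_pupil_stim", "mod_rt_choice", "mod_rt_stim"):
            setattr(self, name, _lagvec(getattr(self, name), n=self.n_lags))


def _noise_cdf(x, kind):
    if kind == "gaussian":
        from scipy.stats import norm
        return norm.cdf(x)
    return 1.0 / (1.0 + np.exp(-np.asarray(x)))


def _uncertainty_moments(obs: ObserverParams, coh_levels, rng):
    """Moments of pupil and log-RT under the zero-history observer.

    Used to standardize modulator values inside the generative feedback
    loop, matching the z-scoring the fitting code applies afterwards.
    """
    n = 20_000
    coh = rng.choice(coh_levels, n) * rng.choice([-1, 1], n)
    mu = obs.evidence_scale * coh + rng.normal(0, obs.evidence_noise, n)
    if obs.noise == "gaussian":
        dv = mu + obs.sigma * rng.standard_normal(n)
    else:
        dv = mu + obs.sigma * rng.logistic(size=n)
    unc = 1.0 - _noise_cdf(np.abs(dv) / obs.sigma, obs.noise)
    pupil = obs.pupil_gain * unc + rng.normal(0, obs.pupil_noise, n)
    rt = np.clip(obs.rt_base + obs.rt_gain * unc
                 + rng.lognormal(np.log(0.2), obs.rt_noise, n), 1e-3, 3.0)
    logrt = np.log(rt)
    return ((pupil.mean(), max(pupil.std(), 1e-9)),
            (logrt.mean(), max(logrt.std(), 1e-9)))


def simulate_observer(stim_sequence: pd.DataFrame, obs: ObserverParams,
                      session: int = 1,
                      seed: int | np.random.Generator = 0,
                      return_truth: bool = False):
    """Simulate choices, RTs and (noise-free-measurement) pupil responses.

    ``stim_sequence`` is the output of :func:`generate_stimulus_sequence`.
    History terms reach back at most to the start of the current block.
    Returns a validated trial table; with ``return_truth=True`` also a
    DataFrame of per-trial latent quantities (mu, dv, uncertainty,
    pupil_true).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    levels = np.unique(np.abs(stim_sequence["coherence_diff"]))
    (p_mean, p_sd), (r_mean, r_sd) = _uncertainty_moments(obs, levels, rng)

    rows, truth = [], []
    for block, grp in stim_sequence.groupby("block", sort=True):
        cats = grp["stim_category"].to_numpy()
        cohs = grp["coherence_diff"].to_numpy(float)
        nb = len(cats)
        choices = np.zeros(nb)
        pupils = np.zeros(nb)
        logrts = np.zeros(nb)
        t_cursor = 2.0  # block start padding
        for i in range(nb):
            mu = obs.evidence_scale * cohs[i] + rng.normal(0, obs.evidence_noise)
            b = obs.overall_bias
            for k in range(1, obs.n_lags + 1):
                if i - k < 0:
                    break
                ch, st = choices[i - k], cats[i - k]
                mp = (pupils[i - k] - p_mean) / p_sd
                mr = (logrts[i - k] - r_mean) / r_sd
                b += (obs.kernel_choice[k - 1] * ch
                      + obs.kernel_stim[k - 1] * st
                      + mp * (obs.mod_pupil_choice[k - 1] * ch
                              + obs.mod_pupil_stim[k - 1] * st)
                      + mr * (obs.mod_rt_choice[k - 1] * ch
                              + obs.mod_rt_stim[k - 1] * st))
            c_t = obs.c - obs.sigma * b
            if obs.noise == "gaussian":
                dv = mu + obs.sigma * rng.standard_normal()
            else:
                dv = mu + obs.sigma * rng.logistic()
            choice = 1 if dv >= c_t else -1
            if obs.lapse > 0 and rng.random() < obs.lapse:
                choice = int(rng.choice([-1, 1]))
            unc = 1.0 - float(_noise_cdf(abs(dv - c_t) / obs.sigma, obs.noise))
            pupil_true = obs.pupil_gain * unc
            pupil = pupil_true + rng.normal(0, obs.pupil_noise)
            rt = float(np.clip(
                obs.rt_base + obs.rt_gain * unc
                + rng.lognormal(np.log(0.2), obs.rt_noise), 1e-3, 3.0))

            t_ref_on = t_cursor
            t_test_on = t_ref_on + 0.75 + 0.5
            t_test_off = t_test_on + 0.75
            t_response = t_test_off + rt
            t_feedback = t_response + rng.uniform(1.5, 2.5)
            t_cursor = t_feedback + rng.uniform(2.5, 3.5)

            choices[i], pupils[i], logrts[i] = choice, pupil, np.log(rt)
            rows.append(dict(
                session=session, block=int(block), trial=i,
                stim_category=int(cats[i]), coherence_diff=cohs[i],
                evidence=mu, evidence_strength=abs(mu),
                choice=choice, correct=int(choice == cats[i]), rt=rt,
                pupil_baseline=rng.normal(0, 0.2), pupil_response=pupil,
                t_ref_on=t_ref_on, t_test_on=t_test_on,
                t_test_off=t_test_off, t_response=t_response,
                t_feedback=t_feedback))
            truth.append(dict(session=session, block=int(block), trial=i,
                              mu=mu, dv=dv, uncertainty=unc,
                              pupil_true=pupil_true))
    trials = pd.DataFrame(rows)[TRIAL_COLUMNS]
    validate_trial_table(trials)
    if return_truth:
        return trials, pd.DataFrame(truth)
    return trials


# ---------------------------------------------------------------------------
# Synthetic eye recording
# ---------------------------------------------------------------------------

def pupil_irf(t, t_max: float = 0.93, w: float = 10.1) -> np.ndarray:
    """Canonical pupil impulse-response function, unit peak at ``t_max``.

    An Erlang-type kernel h(t) = (t/t_max)^w exp(-w (t/t_max - 1)) for
    t >= 0, the standard convention in pupillometry.
    """
    t = np.asarray(t, float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / t_max
    out[pos] = x ** w * np.exp(-w * (x - 1.0))
    return out


def synthesize_eye_recording(trials: pd.DataFrame,
                             amplitudes: np.ndarray | None = None,
                             rate: float = 1000.0,
                             irf_tmax: float = 0.93, irf_w: float = 10.1,
                             blink_rate: float = 0.05,
                             noise_sd: float = 0.02,
                             drift_sd: float = 0.1,
                             drift_knot_spacing: float = 30.0,
                             seed: int | np.random.Generator = 0,
                             ) -> EyeRecording:
    """Synthesize a 1000-Hz eye recording for one block of trials.

    The pupil trace is a slow random drift plus one arousal event per
    trial — a boxcar of height = the trial's true pupil response,
    sustained from the choice until feedback resolves it — convolved with
    the unit-area :func:`pupil_irf` (so the pre-feedback plateau equals
    the true amplitude), plus Poisson blink dropouts and white measurement
    noise, mapped to raw tracker units. ``amplitudes`` defaults to the
    table's ``pupil_response`` column. Ground truth is the amplitude
    vector itself, which the caller retains.
    """
    if trials["block"].nunique() != 1 or trials["session"].nunique() != 1:
        raise ValueError("one recording covers exactly one session/block")
    t_resp = trials["t_response"].to_numpy(float)
    if np.any(np.diff(t_resp) <= 0):
        raise ValueError("overlapping or unordered trials")
    if amplitudes is None:
        amplitudes = trials["pupil_response"].to_numpy(float)
    amplitudes = np.asarray(amplitudes, float)
    if len(amplitudes) != len(trials):
        raise ValueError("one amplitude per trial required")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    t_end = trials["t_feedback"].max() + 4.0
    n = int(round(t_end * rate))
    time = np.arange(n) / rate

    # slow drift: random walk on sparse knots, far below the trial rate
    n_knots = max(int(t_end / drift_knot_spacing) + 2, 4)
    knots_t = np.linspace(0, t_end, n_knots)
    knots_v = rng.normal(0, drift_sd, n_knots).cumsum()
    drift = np.interp(time, knots_t, knots_v)
    drift -= drift.mean()

    # sustained arousal input: amplitude-high boxcar from the choice until
    # feedback resolves it, convolved with the unit-area IRF so the
    # pre-feedback plateau equals the true amplitude
    t_fb = trials["t_feedback"].to_numpy(float)
    u = np.zeros(n)
    for amp, a, b in zip(amplitudes, t_resp, t_fb):
        u[int(round(a * rate)): int(round(b * rate))] = amp
    kernel_t = np.arange(0, 4.0, 1.0 / rate)
    kernel = pupil_irf(kernel_t, irf_tmax, irf_w)
    kernel = kernel / kernel.sum()
    signal = drift + fftconvolve(u, kernel)[:n]
    signal += rng.normal(0, noise_sd, n)

    pupil = 1000.0 + 100.0 * signal   # raw tracker units

    events = [(0.0, "block_start", "")]
    for _, row in trials.iterrows():
        lbl = str(int(row["trial"]))
        for kind, col in (("ref_on", "t_ref_on"), ("test_on", "t_test_on"),
                          ("test_off", "t_test_off"),
                          ("response", "t_response"),
                          ("feedback", "t_feedback")):
            events.append((float(row[col]), kind, lbl))

    # Poisson blink dropouts: pupil collapses towards zero for 0.1-0.3 s
    n_blinks = rng.poisson(blink_rate * t_end)
    for bt in np.sort(rng.uniform(1.0, t_end - 1.0, n_blinks)):
        dur = rng.uniform(0.1, 0.3)
        i0, i1 = int(bt * rate), min(int((bt + dur) * rate), n)
        pupil[i0:i1] = rng.uniform(0, 50, i1 - i0)
        events.append((i0 / rate, "blink_start", ""))
        events.append((i1 / rate, "blink_end", ""))

    gaze_x = rng.normal(512, 5, n) + np.interp(
        time, knots_t, rng.normal(0, 3, n_knots))
    gaze_y = rng.normal(384, 5, n) + np.interp(
        time, knots_t, rng.normal(0, 3, n_knots))

    ev = pd.DataFrame(sorted(events), columns=["t", "kind", "label"])
    return EyeRecording(time=time, pupil=pupil, gaze_x=gaze_x,
                        gaze_y=gaze_y, rate=rate, events=ev)


# ---------------------------------------------------------------------------
# Random-dot kinematograms
# ---------------------------------------------------------------------------

@dataclass
class RdkParams:
    """Geometry and dynamics of the random-dot stimulus (display defaults)."""

    outer_radius: float = 12.0    # deg
    inner_radius: float = 2.0     # deg
    density: float = 1.7          # dots / deg^2
    dot_diameter: float = 0.2     # deg
    speed: float = 11.5           # deg/s nominal signal-dot speed
    lifetime: int = 4             # frames (per subsequence) before re-plot
    n_interleaved: int = 3        # interleaved motion subsequences
    frame_rate: float = 60.0      # Hz
    direction: float = 45.0       # deg, one of the four diagonals
    n_dots: int | None = None     # override; default round(density * area)
    px_per_deg: float = 10.0

    @property
    def annulus_area(self) -> float:
        return math.pi * (self.outer_radius ** 2 - self.inner_radius ** 2)

    @property
    def dot_count(self) -> int:
        if self.n_dots is not None:
            return self.n_dots
        return int(round(self.density * self.annulus_area))

    @property
    def effective_speed(self) -> float:
        """Displayed signal-dot speed: dots step speed/frame_rate degrees
        once every n_interleaved frames."""
        step = self.speed / self.frame_rate
        return step / (self.n_interleaved / self.frame_rate)


def _random_annulus(n, params: RdkParams, rng) -> np.ndarray:
    """n uniform points (x, y in deg) in the annulus."""
    r = np.sqrt(rng.uniform(params.inner_radius ** 2,
                            params.outer_radius ** 2, n))
    th = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def generate_rdk_movie(coherence: float, params: RdkParams | None = None,
                       n_frames: int = 45,
                       seed: int | np.random.Generator = 0,
                       return_tracks: bool = False):
    """Render an RDK movie as a (n_frames, H, W) binary array.

    Each frame draws ``dot_count`` dots. Dots shown on frame f derive from
    frame f - n_interleaved (three interleaved subsequences): a coherence
    fraction is selected as signal dots and displaced along ``direction``
    by speed/frame_rate degrees (so the displayed effective speed is
    speed/n_interleaved); the rest are noise dots re-drawn at random
    annulus positions ('random position' noise, 'different' rule). Signal
    dots wrap to the diametrically opposite point when they exit the
    annulus and are re-plotted at random after ``lifetime`` updates.

    With ``return_tracks=True`` also returns the per-frame dot positions
    (deg) and the per-frame boolean signal mask, for trajectory checks.
    """
    params = params or RdkParams()
    if not 0 <= coherence <= 100:
        raise ValueError("coherence must lie in [0, 100]")
    if n_frames < params.n_interleaved:
        raise ValueError("n_frames must be >= n_interleaved")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    n_dots = params.dot_count
    step = params.speed / params.frame_rate
    d = np.deg2rad(params.direction)
    disp = step * np.array([np.cos(d), np.sin(d)])

    positions = np.empty((n_frames, n_dots, 2))
    signal_mask = np.zeros((n_frames, n_dots), dtype=bool)
    ages = np.zeros((params.n_interleaved, n_dots), dtype=int)

    for f in range(n_frames):
        sub = f % params.n_interleaved
        if f < params.n_interleaved:
            positions[f] = _random_annulus(n_dots, params, rng)
            continue
        prev = positions[f - params.n_interleaved]
        sig = rng.random(n_dots) < coherence / 100.0
        expired = ages[sub] >= params.lifetime - 1
        sig &= ~expired
        pos = np.empty_like(prev)
        pos[sig] = prev[sig] + disp
        # wrap dots that left the annulus to the opposite side
        rad = np.hypot(pos[sig, 0], pos[sig, 1])
        outside = rad > params.outer_radius
        wrapped = pos[sig]
        wrapped[outside] *= -1
        inside_hole = np.hypot(wrapped[:, 0], wrapped[:, 1]) < params.inner_radius
        if inside_hole.any():
            wrapped[inside_hole] = _random_annulus(
                int(inside_hole.sum()), params, rng)
        pos[sig] = wrapped
        n_noise = int((~sig).sum())
        pos[~sig] = _random_annulus(n_noise, params, rng)
        ages[sub][sig] += 1
        ages[sub][~sig] = 0
        positions[f] = pos
        signal_mask[f] = sig

    movie = _render(positions, params)
    if return_tracks:
        return movie, positions, signal_mask
    return movie


def _render(positions: np.ndarray, params: RdkParams) -> np.ndarray:
    """Rasterize dot positions to binary frames at px_per_deg resolution."""
    ppd = params.px_per_deg
    half = params.outer_radius
    size = int(round(2 * half * ppd))
    n_frames, n_dots, _ = positions.shape
    movie = np.zeros((n_frames, size, size), dtype=np.uint8)
    r_px = max(params.dot_diameter * ppd / 2.0, 0.5)
    rr = int(np.ceil(r_px))
    oy, ox = np.mgrid[-rr:rr + 1, -rr:rr + 1]
    stencil = np.argwhere(oy ** 2 + ox ** 2 <= r_px ** 2) - rr
    for f in range(n_frames):
        px = np.round((positions[f] + half) * ppd).astype(int)
        ys = px[:, 1, None] + stencil[None, :, 0]
        xs = px[:, 0, None] + stencil[None, :, 1]
        ok = (ys >= 0) & (ys < size) & (xs >= 0) & (xs < size)
        movie[f][ys[ok], xs[ok]] = 1
    return movie
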