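"""Opponent motion-energy filtering of random-dot movies.

A quadrature pair of spatio-temporal filters is built from two spatial
filters (weighted sinusoids in opposite phase under a Gaussian envelope)

    f1(x, y) = cos^4(a) cos(4a) exp(-y^2 / (2 sigma_g^2))
    f2(x, y) = cos^4(a) sin(4a) exp(-y^2 / (2 sigma_g^2)),   a = atan(x / sigma_c)

on a grid rotated so that x aligns with the target direction, and two
temporal filters

    g(t) = (k t)^n exp(-k t) [ 1/n! - (k t)^2 / (n + 2)! ]

with n = 3 (early-peaking, "fast") and n = 5 (late-peaking, "slow"). The
quadrature outputs f1*g_slow + f2*g_fast and f2*g_slow - f1*g_fast are
convolved with the movie, squared and summed; the same energy computed for
the 180-degree opposite direction is subtracted, yielding a
direction-selective opponent energy trace over frames. Averaging the trace
within each stimulus interval and differencing test minus reference gives
signed single-trial evidence; its absolute value is evidence strength.

Defaults (sigma_g = 0.05, sigma_c = 0.35, k = 60) follow the standard
MT-like filter parameterization for psychophysical motion stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
from scipy import signal


@dataclass
class MotionEnergyParams:
    sigma_g: float = 0.05       # deg, Gaussian envelope SD
    sigma_c: float = 0.35       # deg, carrier scale
    k: float = 60.0             # 1/s, temporal envelope rate
    n_fast: int = 3             # stages of the early-peaking temporal filter
    n_slow: int = 5             # stages of the late-peaking temporal filter
    spatial_halfwidth: float = 0.7   # deg
    temporal_support: float = 0.35   # s
    px_per_deg: float = 10.0
    frame_rate: float = 60.0


@dataclass
class FilterBank:
    """Discrete spatial (2D) and temporal (1D) filters for one direction."""

    f_even: np.ndarray     # spatial, even about the motion axis
    f_odd: np.ndarray      # spatial, odd
    g_slow: np.ndarray     # temporal, late peak
    g_fast: np.ndarray     # temporal, early peak
    t: np.ndarray          # temporal sample times (s)
    direction: float       # deg
    params: MotionEnergyParams


def temporal_filter(t, n: int, k: float = 60.0) -> np.ndarray:
    """(kt)^n e^{-kt} [1/n! - (kt)^2/(n+2)!] for t >= 0, zero before."""
    t = np.asarray(t, float)
    kt = k * np.clip(t, 0, None)
    out = kt ** n * np.exp(-kt) * (1.0 / factorial(n)
                                   - kt ** 2 / factorial(n + 2))
    return np.where(t < 0, 0.0, out)


def spatial_filters(params: MotionEnergyParams, direction: float):
    """Even/odd spatial filters sampled on a rotated pixel grid."""
    hw, ppd = params.spatial_halfwidth, params.px_per_deg
    n = int(round(hw * ppd))
    coords = np.arange(-n, n + 1) / ppd
    dx, dy = np.meshgrid(coords, coords)
    th = np.deg2rad(direction)
    x = dx * np.cos(th) + dy * np.sin(th)
    y = -dx * np.sin(th) + dy * np.cos(th)
    alpha = np.arctan(x / params.sigma_c)
    env = np.cos(alpha) ** 4 * np.exp(-y ** 2 / (2 * params.sigma_g ** 2))
    return env * np.cos(4 * alpha), env * np.sin(4 * alpha)


def build_filters(params: MotionEnergyParams | None = None,
                  direction: float = 45.0) -> FilterBank:
    """Build the filter bank; errors if the temporal support truncates the
    filters before they have decayed."""
    params = params or MotionEnergyParams()
    f1, f2 = spatial_filters(params, direction)
    t = np.arange(0, params.temporal_support, 1.0 / params.frame_rate)
    g_slow = temporal_filter(t, params.n_slow, params.k)
    g_fast = temporal_filter(t, params.n_fast, params.k)
    for g in (g_slow, g_fast):
        if abs(g[-1]) > 0.01 * np.max(np.abs(g)):
            raise ValueError(
                "temporal support too short: filter has not decayed")
    return FilterBank(f1, f2, g_slow, g_fast, t, direction, params)


def movie_energy(movie: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Opponent motion energy per frame (target minus anti-direction).

    The movie is convolved spatially with the even/odd filters (zero-padded
    'same' convolution) and temporally with the causal slow/fast filters;
    the two quadrature outputs are squared and summed over pixels. Energy
    for the opposite direction reuses the same spatial responses with the
    odd filter's sign flipped.
    """
    movie = np.asarray(movie, np.float32)
    if movie.ndim != 3:
        raise ValueError("movie must be (frames, H, W)")
    if movie.shape[1] < bank.f_even.shape[0] or \
            movie.shape[2] < bank.f_even.shape[1]:
        raise ValueError("movie frames smaller than the spatial filters")

    # spatial correlation: convolution would flip the odd filter's parity
    # and with it the preferred direction
    s_even = signal.fftconvolve(movie, bank.f_even[None], mode="same",
                                axes=(1, 2))
    s_odd = -signal.fftconvolve(movie, bank.f_odd[None], mode="same",
                                axes=(1, 2))

    def causal(x, g):
        return signal.lfilter(g, [1.0], x, axis=0)

    a_pref = causal(s_even, bank.g_slow) + causal(s_odd, bank.g_fast)
    b_pref = causal(s_odd, bank.g_slow) - causal(s_even, bank.g_fast)
    # 180-degree rotation: even filter unchanged, odd filter negated
    a_anti = causal(s_even, bank.g_slow) - causal(s_odd, bank.g_fast)
    b_anti = -causal(s_odd, bank.g_slow) - causal(s_even, bank.g_fast)

    e_pref = (a_pref ** 2 + b_pref ** 2).sum(axis=(1, 2))
    e_anti = (a_anti ** 2 + b_anti ** 2).sum(axis=(1, 2))
    return np.asarray(e_pref - e_anti, float)


def trial_evidence(ref_trace: np.ndarray, test_trace: np.ndarray,
                   frame_rate: float = 60.0,
                   ramp_skip: float = 0.15) -> tuple[float, float]:
    """Signed evidence and evidence strength from two interval traces.

    The first ``ramp_skip`` seconds of each trace (filter ramp-up) are
    discarded; evidence = mean(test) - mean(ref), strength = |evidence|.
    """
    ref = np.asarray(ref_trace, float)
    test = np.asarray(test_trace, float)
    if ref.size == 0 or test.size == 0:
        raise ValueError("empty energy trace")
    if np.isnan(ref).any() or np.isnan(test).any():
        raise ValueError("NaN frames in energy trace")
    skip = int(round(ramp_skip * frame_rate))
    if skip >= len(ref) or skip >= len(test):
        raise ValueError("traces shorter than the ramp-up skip")
    evidence = float(test[skip:].mean() - ref[skip:].mean())
    return evidence, abs(evidence)
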