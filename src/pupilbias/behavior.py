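"""Psychometric modelling and trial-history behavioral analyses.

The psychometric function for the probability of choosing "test stronger"
(r = 1) given signed evidence s is

    P(r=1 | s) = gamma + (1 - gamma - lambda) * g(alpha * s + delta),

with g the logistic function, alpha perceptual sensitivity, delta a bias
term in log-odds, and gamma = lambda a single stimulus-independent lapse
rate. Accuracy as a function of evidence strength s is modelled by a
cumulative Weibull,

    P(correct | s) = 0.5 + (0.5 - lambda) * (1 - exp(-(s/theta)^beta)),

whose threshold theta marks the evidence strength yielding ~80% accuracy
(with zero lapses, exactly 50 + 50*(1 - 1/e) ~ 81.6%); perceptual
sensitivity is 1/theta.

Serial choice bias is quantified by fitting the psychometric function
conditioned on the previous choice within bins (tertiles) of the previous
trial's pupil response or RT, converting the bias term to a probability
P = e^delta / (1 + e^delta), and collapsing over the two previous-choice
options into a repetition probability. Post-error slowing is the RT
difference between the trials after and before isolated errors, after
regressing evidence strength out of RT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
import statsmodels.api as sm


@dataclass
class PsychometricParams:
    alpha: float            # sensitivity (per evidence unit)
    delta: float            # bias (log-odds)
    lapse: float            # gamma = lambda
    nll: float
    converged: bool


@dataclass
class WeibullParams:
    theta: float            # threshold
    beta: float             # slope
    lapse: float
    nll: float
    converged: bool

    @property
    def sensitivity(self) -> float:
        return 1.0 / self.theta


def psychometric_prob(s, alpha, delta, lapse):
    """P(r=1 | s) under the lapse-augmented logistic model."""
    return lapse + (1.0 - 2.0 * lapse) * expit(alpha * np.asarray(s) + delta)


def weibull_prob(s, theta, beta, lapse):
    """P(correct | s) under the cumulative Weibull model."""
    s = np.asarray(s, float)
    return 0.5 + (0.5 - lapse) * (1.0 - np.exp(-(s / theta) ** beta))


def bias_to_probability(delta: float) -> float:
    """Transform a log-odds bias into P(r=1) at zero evidence."""
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    return float(expit(delta))


def _nll_binary(p, y):
    p = np.clip(p, 1e-10, 1 - 1e-10)
    return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))


def fit_psychometric(s, r, n_restarts: int = 10,
                     seed: int | np.random.Generator = 0,
                     lapse_max: float = 0.499) -> PsychometricParams:
    """Maximum-likelihood psychometric fit with multiple restarts.

    ``s`` is signed evidence, ``r`` the choice coded +1/-1 (or 1/0). The
    two lapse probabilities are constrained equal; lapse is bounded in
    [0, ``lapse_max``]. On small conditional subsets an unconstrained
    lapse admits a degenerate step-function optimum whose bias term is
    uninterpretable; callers fitting such subsets pass a tighter
    ``lapse_max``. Raises on non-identifiable (all-same-choice) data.
    """
    s = np.asarray(s, float)
    y = (np.asarray(r) > 0).astype(float)
    if len(s) != len(y):
        raise ValueError("s and r must have equal length")
    if y.min() == y.max():
        raise ValueError("all choices identical: psychometric fit is "
                         "non-identifiable")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    scale = max(np.std(s), 1e-6)

    def nll(p):
        return _nll_binary(psychometric_prob(s, *p), y)

    best = None
    starts = [(1.0 / scale, 0.0, 0.02)]
    starts += [(rng.uniform(0.05, 3) / scale, rng.normal(0, 1),
                rng.uniform(0, min(0.2, lapse_max)))
               for _ in range(n_restarts - 1)]
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(-50, 50), (-10, 10), (0, lapse_max)])
        if best is None or res.fun < best.fun:
            best = res
    return PsychometricParams(alpha=best.x[0], delta=best.x[1],
                              lapse=best.x[2], nll=best.fun,
                              converged=bool(best.success))


def fit_weibull(s_abs, correct, n_restarts: int = 10,
                seed: int | np.random.Generator = 0) -> WeibullParams:
    """Maximum-likelihood cumulative-Weibull fit to accuracy data."""
    s = np.asarray(s_abs, float)
    y = np.asarray(correct, float)
    if np.any(s < 0):
        raise ValueError("evidence strength must be nonnegative")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    s_hi = max(np.percentile(s[s > 0], 75), 1e-3)

    def nll(p):
        return _nll_binary(weibull_prob(s, *p), y)

    best = None
    starts = [(s_hi, 2.0, 0.02)]
    starts += [(s_hi * rng.uniform(0.2, 3), rng.uniform(0.5, 4),
                rng.uniform(0, 0.2)) for _ in range(n_restarts - 1)]
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(1e-4, 1e3), (0.1, 20), (0, 0.499)])
        if best is None or res.fun < best.fun:
            best = res
    return WeibullParams(theta=best.x[0], beta=best.x[1], lapse=best.x[2],
                         nll=best.fun, converged=bool(best.success))


# ---------------------------------------------------------------------------
# Previous-trial machinery
# ---------------------------------------------------------------------------

def add_previous_trial(trials: pd.DataFrame,
                       columns=("choice", "stim_category", "correct",
                                "pupil_response", "rt")) -> pd.DataFrame:
    """Append ``prev_<col>`` columns, shifting within (session, block).

    The first trial of each block has no predecessor (NaN).
    """
    out = trials.copy()
    grp = out.groupby(["session", "block"], sort=False)
    for col in columns:
        out["prev_" + col] = grp[col].shift(1)
    return out


def _tertile_bins(values: pd.Series, by: pd.Series, n_bins: int) -> pd.Series:
    """Rank-based bins of ``values`` computed within each level of ``by``."""
    def _rankbin(v):
        ranks = v.rank(method="first")
        return np.ceil(ranks / len(v) * n_bins).clip(1, n_bins)
    return values.groupby(by, group_keys=False).apply(_rankbin)


def serial_bias_by_bin(trials: pd.DataFrame, modulator: str = "pupil_response",
                       n_bins: int = 3, min_trials: int = 50,
                       seed: int = 0) -> pd.DataFrame:
    """Choice-repetition probability per previous-trial modulator bin.

    Within each session, trials are binned by the previous trial's
    modulator value ('pupil_response' or 'rt'); within each bin and each
    previous-choice identity a psychometric function is fit to the current
    trials and its bias converted to a probability; collapsing over the two
    previous-choice options yields the repetition probability.
    """
    if modulator not in ("pupil_response", "rt"):
        raise ValueError("modulator must be 'pupil_response' or 'rt'")
    t = add_previous_trial(trials)
    t = t.dropna(subset=["prev_choice", "prev_" + modulator])
    t["mod_bin"] = _tertile_bins(t["prev_" + modulator], t["session"], n_bins)

    rows = []
    for b in range(1, n_bins + 1):
        sub = t[t["mod_bin"] == b]
        p_rep = {}
        for prev in (-1, 1):
            ss = sub[sub["prev_choice"] == prev]
            if len(ss) < min_trials:
                warnings.warn(
                    f"bin {b}, previous choice {prev:+d}: only {len(ss)} "
                    f"trials")
            fit = fit_psychometric(ss["evidence"], ss["choice"], seed=seed,
                                   lapse_max=0.1)
            p = bias_to_probability(fit.delta)
            p_rep[prev] = p if prev == 1 else 1.0 - p
        rows.append(dict(bin=b, n=len(sub),
                         p_repeat=(p_rep[1] + p_rep[-1]) / 2.0,
                         p_repeat_prev_pos=p_rep[1],
                         p_repeat_prev_neg=p_rep[-1]))
    return pd.DataFrame(rows)


def post_error_slowing(trials: pd.DataFrame, modulator: str | None = None,
                       n_bins: int = 3):
    """Post-error slowing: post- minus pre-error RT around isolated errors.

    Evidence strength is first regressed out of RT (per session, with
    intercept). Error trials preceded and followed by a correct trial
    within the same block contribute (post - pre); the mean is returned,
    per modulator tertile when ``modulator`` is given (binned on the error
    trial's value), else overall. NaN where no qualifying triplet exists.
    """
    t = trials.copy().reset_index(drop=True)
    t["rt_resid"] = np.nan
    for _, g in t.groupby("session", sort=False):
        x = np.column_stack([np.ones(len(g)),
                             g["evidence_strength"].to_numpy()])
        beta, *_ = np.linalg.lstsq(x, g["rt"].to_numpy(), rcond=None)
        t.loc[g.index, "rt_resid"] = g["rt"].to_numpy() - x @ beta

    pes_vals, mod_vals = [], []
    for _, g in t.groupby(["session", "block"], sort=False):
        corr = g["correct"].to_numpy()
        rtr = g["rt_resid"].to_numpy()
        for i in range(1, len(g) - 1):
            if corr[i] == 0 and corr[i - 1] == 1 and corr[i + 1] == 1:
                pes_vals.append(rtr[i + 1] - rtr[i - 1])
                if modulator:
                    mod_vals.append(g[modulator].to_numpy()[i])
    if modulator is None:
        return float(np.mean(pes_vals)) if pes_vals else float("nan")
    pes_vals = np.asarray(pes_vals)
    mod_vals = np.asarray(mod_vals)
    out = []
    if len(pes_vals) == 0:
        return pd.DataFrame(
            [dict(bin=b, pes=np.nan, n=0) for b in range(1, n_bins + 1)])
    edges = np.quantile(mod_vals, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.digitize(mod_vals, edges[1:-1]), 0, n_bins - 1)
    for b in range(n_bins):
        m = bins == b
        out.append(dict(bin=b + 1, pes=pes_vals[m].mean() if m.any()
                        else np.nan, n=int(m.sum())))
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Pupil-evidence regressions
# ---------------------------------------------------------------------------

def _zscore(x):
    x = np.asarray(x, float)
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def pupil_evidence_regression(trials: pd.DataFrame, pupil: np.ndarray,
                              gaze_x: np.ndarray | None = None,
                              gaze_y: np.ndarray | None = None) -> dict:
    """Regress evidence strength onto pupil, separately per outcome.

    ``pupil`` is either a vector of per-trial scalars or a
    (n_trials, n_samples) epoch matrix; in the latter case one regression
    is run per sample and the evidence beta is returned as a time series.
    The design contains an intercept, standardized evidence strength,
    standardized log RT, and (sample-by-sample, when provided) gaze
    coordinates as nuisances. Returns {outcome: betas} with outcome in
    {'correct', 'error'}.
    """
    pupil = np.asarray(pupil, float)
    if pupil.shape[0] != len(trials):
        raise ValueError("pupil must have one row per trial")
    correct = trials["correct"].to_numpy()
    if correct.min() == correct.max():
        raise ValueError("need both correct and error trials")
    ev = _zscore(trials["evidence_strength"])
    logrt = _zscore(np.log(trials["rt"].to_numpy(float)))

    out = {}
    for name, mask in (("correct", correct == 1), ("error", correct == 0)):
        y = pupil[mask]
        base = np.column_stack([np.ones(mask.sum()), ev[mask], logrt[mask]])
        if y.ndim == 1:
            x = base
            if np.linalg.matrix_rank(x) < x.shape[1]:
                raise ValueError("rank-deficient design")
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            out[name] = float(beta[1])
        else:
            betas = np.empty(y.shape[1])
            for j in range(y.shape[1]):
                x = base
                if gaze_x is not None:
                    x = np.column_stack([x, _zscore(gaze_x[mask, j]),
                                         _zscore(gaze_y[mask, j])])
                beta, *_ = np.linalg.lstsq(x, y[:, j], rcond=None)
                betas[j] = beta[1]
            out[name] = betas
    return out


def correctness_logistic(trials: pd.DataFrame,
                         pupil_col: str = "pupil_response"):
    """Logistic regression of single-trial correctness on pupil response.

    Returns (weight, standard error) for the standardized pupil predictor.
    """
    correct = trials["correct"].to_numpy()
    if correct.min() == correct.max():
        raise ValueError("need both correct and error trials")
    x = sm.add_constant(_zscore(trials[pupil_col].to_numpy(float)))
    fit = sm.Logit(correct, x).fit(disp=0)
    return float(fit.params[1]), float(fit.bse[1])
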