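"""History-dependent choice bias: regression model, EM fit, inference.

The psychometric model is extended with a history-dependent bias. The
probability of choice r_t = 1 is a lapse mixture

    P(r_t = 1) = (1 - lambda) * g(alpha * s_t + delta(h_t)) + lambda * p_guess

where g is the logistic function, s_t the signed single-trial evidence
(motion energy), and

    delta(h_t) = delta' + sum_k omega_k h_{t-k}

sums, over the previous seven trials, weighted contributions of past
choices and past stimuli (each coded +/-1). The fourteen lag weights are
spanned by three exponentially decaying basis functions (time constants 1,
3 and 9 lags, unit-normalized columns), so only six free history weights
are fit. Positive choice (stimulus) weights mean a tendency to repeat the
previous choice (stimulus); negative weights mean alternation.

Modulation of serial bias by pupil-linked arousal and by RT enters as
multiplicative interactions: the previous trials' (z-scored, residualized)
pupil responses and log RTs multiply the choice- and stimulus-history
regressors, again in basis space, with the modulators' main effects
included as nuisance covariates.

Fitting is by expectation maximization over the latent per-trial lapse
state: the E-step computes lapse posteriors, the M-step updates the lapse
rate and guess probability in closed form and the regression weights by
Newton-IRLS on the posterior-weighted logistic likelihood. The total
log-likelihood is non-decreasing across iterations (asserted). Group-level
tools: trial-permutation significance, block-bootstrap confidence
intervals, the strategy-space transform (correct = choice + stimulus,
error = choice - stimulus weights), the history share of decision-variable
variance by evidence bin, and the population analysis correlating choice
weights with their pupil/RT modulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import pearsonr


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

def exponential_basis(n_lags: int = 7, taus=(1.0, 3.0, 9.0)) -> np.ndarray:
    """(n_lags, n_basis) matrix of unit-norm exponentially decaying columns."""
    lags = np.arange(n_lags)[:, None]
    b = np.exp(-lags / np.asarray(taus)[None, :])
    return b / np.linalg.norm(b, axis=0, keepdims=True)


@dataclass
class HistoryDesign:
    """Design matrix for the history model, valid trials only."""

    x: np.ndarray                 # (n_valid, p)
    y: np.ndarray                 # 0/1 choices
    names: list[str]
    basis: np.ndarray             # (n_lags, n_basis)
    valid: np.ndarray             # mask into the original trial table
    session: np.ndarray           # per valid trial, for bootstrap grouping
    block: np.ndarray
    modulators: tuple[str, ...]
    n_lags: int


def _lag_matrix(values: np.ndarray, n_lags: int) -> np.ndarray:
    """(n, n_lags) matrix with column k-1 holding values[t-k]; zeros where
    the lag reaches before the series start."""
    n = len(values)
    out = np.zeros((n, n_lags))
    for k in range(1, n_lags + 1):
        out[k:, k - 1] = values[:-k]
    return out


def _zscore(x):
    x = np.asarray(x, float)
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def build_design(trials: pd.DataFrame, n_lags: int = 7, n_basis: int = 3,
                 taus=(1.0, 3.0, 9.0),
                 modulators: tuple[str, ...] = ("pupil", "rt")
                 ) -> HistoryDesign:
    """Build the history design from an ordered trial table.

    History never crosses block boundaries; the first ``n_lags`` trials of
    each block are masked out. Modulator values (pupil response, log RT)
    are z-scored per session before forming interactions.
    """
    key = trials[["session", "block", "trial"]].to_numpy()
    if np.any(np.diff(np.lexsort(key.T[::-1])) != 1):
        raise ValueError("trials must be sorted by (session, block, trial)")
    mod_cols = {"pupil": "pupil_response", "rt": "rt"}
    for m in modulators:
        if m not in mod_cols:
            raise ValueError(f"unknown modulator {m!r}")

    b = exponential_basis(n_lags, taus[:n_basis])
    n = len(trials)
    blocks_c, blocks_s = [], []
    mod_lags = {m: [] for m in modulators}
    valid = np.zeros(n, dtype=bool)

    mod_series = {}
    for m in modulators:
        v = trials[mod_cols[m]].to_numpy(float)
        if m == "rt":
            v = np.log(v)
        mod_series[m] = (pd.Series(v)
                         .groupby(trials["session"].to_numpy())
                         .transform(lambda s: _zscore(s.to_numpy()))
                         .to_numpy())

    pos = 0
    for _, g in trials.groupby(["session", "block"], sort=False):
        nb = len(g)
        ch = g["choice"].to_numpy(float)
        st = g["stim_category"].to_numpy(float)
        blocks_c.append(_lag_matrix(ch, n_lags))
        blocks_s.append(_lag_matrix(st, n_lags))
        for m in modulators:
            mod_lags[m].append(
                _lag_matrix(mod_series[m][pos:pos + nb], n_lags))
        if nb > n_lags:
            valid[pos + n_lags: pos + nb] = True
        pos += nb

    lag_c = np.vstack(blocks_c)
    lag_s = np.vstack(blocks_s)
    cols = [trials["evidence"].to_numpy(float)[:, None], np.ones((n, 1)),
            lag_c @ b, lag_s @ b]
    names = (["evidence", "bias"]
             + [f"choice_b{j}" for j in range(n_basis)]
             + [f"stim_b{j}" for j in range(n_basis)])
    for m in modulators:
        lm = np.vstack(mod_lags[m])
        cols += [(lm * lag_c) @ b, (lm * lag_s) @ b, lm @ b]
        names += [f"{m}_x_choice_b{j}" for j in range(n_basis)]
        names += [f"{m}_x_stim_b{j}" for j in range(n_basis)]
        names += [f"{m}_main_b{j}" for j in range(n_basis)]

    x = np.concatenate(cols, axis=1)[valid]
    y = (trials["choice"].to_numpy()[valid] > 0).astype(float)
    return HistoryDesign(
        x=x, y=y, names=names, basis=b, valid=valid,
        session=trials["session"].to_numpy()[valid],
        block=trials["block"].to_numpy()[valid],
        modulators=tuple(modulators), n_lags=n_lags)


# ---------------------------------------------------------------------------
# EM fit
# ---------------------------------------------------------------------------

@dataclass
class HistoryFit:
    weights: dict[str, float]
    kernel_choice: np.ndarray
    kernel_stim: np.ndarray
    mod_kernels: dict[str, dict[str, np.ndarray]]  # modulator -> {choice, stim}
    lapse: float
    p_guess: float
    log_likelihood: float
    n_iter: int
    converged: bool
    basis: np.ndarray
    names: list[str] = field(default_factory=list)
    w: np.ndarray | None = None


def _weighted_logistic(x, y, w0, obs_w, max_iter=50, tol=1e-9):
    """Newton-IRLS for the obs_w-weighted logistic NLL, with step halving."""
    w = w0.copy()
    p = expit(x @ w)
    eps = 1e-10

    def nll(pv):
        pv = np.clip(pv, eps, 1 - eps)
        return -np.sum(obs_w * (y * np.log(pv) + (1 - y) * np.log(1 - pv)))

    f = nll(p)
    for _ in range(max_iter):
        grad = x.T @ (obs_w * (y - p))
        hess = (x * (obs_w * p * (1 - p))[:, None]).T @ x
        hess[np.diag_indices_from(hess)] += 1e-9
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        for _ in range(30):
            w_new = w + t * step
            p_new = expit(x @ w_new)
            f_new = nll(p_new)
            if f_new <= f + 1e-12:
                break
            t /= 2.0
        if f - f_new < tol * (abs(f) + 1):
            w, p, f = w_new, p_new, f_new
            break
        w, p, f = w_new, p_new, f_new
    return w, p


def _total_ll(p_att, y, lapse, p_guess):
    eps = 1e-12
    like_att = np.where(y == 1, p_att, 1 - p_att)
    like_lapse = np.where(y == 1, p_guess, 1 - p_guess)
    return float(np.sum(np.log(
        (1 - lapse) * like_att + lapse * like_lapse + eps)))


def fit(design: HistoryDesign, with_modulation: bool = True,
        max_iter: int = 2000, tol: float = 1e-6, n_restarts: int = 5,
        seed: int | np.random.Generator = 0,
        w_init: np.ndarray | None = None,
        lapse_init: float = 0.05,
        fit_guess: bool = False) -> HistoryFit:
    """Fit the history model by EM over the latent lapse state.

    ``with_modulation=False`` drops all modulator columns (the basic
    history model). The lapse state responds symmetrically (guess
    probability 0.5) unless ``fit_guess=True`` frees it; a free guess
    probability at its 0/1 bound mimics response runs and is confounded
    with choice-history weights, so the symmetric state is the default.
    The log-likelihood is asserted non-decreasing at every EM iteration;
    a fit that exhausts ``max_iter`` is flagged ``converged=False``.
    """
    if with_modulation:
        keep = np.arange(len(design.names))
    else:
        keep = np.array([i for i, nm in enumerate(design.names)
                         if "_" not in nm or nm.startswith(("choice", "stim"))])
    x = design.x[:, keep]
    y = design.y
    names = [design.names[i] for i in keep]
    if len(y) < 500:
        warnings.warn(f"only {len(y)} valid trials; the history model is "
                      "weakly determined below ~500")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    inits = []
    if w_init is not None:
        inits.append(np.asarray(w_init, float))
        n_restarts = max(n_restarts, 1)
    inits.append(np.zeros(x.shape[1]))
    while len(inits) < n_restarts:
        inits.append(rng.normal(0, 0.1, x.shape[1]))

    best = None
    for w0 in inits:
        res = _em_once(x, y, w0, lapse_init, max_iter, tol, fit_guess)
        if best is None or res[2] > best[2]:
            best = res
    w, (lapse, p_guess), ll, n_iter, conv = best

    b = design.basis
    idx = {nm: i for i, nm in enumerate(names)}
    nb = b.shape[1]

    def kernel(prefix):
        wb = np.array([w[idx[f"{prefix}_b{j}"]] for j in range(nb)])
        return b @ wb

    mod_kernels = {}
    if with_modulation:
        for m in design.modulators:
            mod_kernels[m] = {"choice": kernel(f"{m}_x_choice"),
                              "stim": kernel(f"{m}_x_stim"),
                              "main": kernel(f"{m}_main")}
    return HistoryFit(
        weights=dict(zip(names, w)),
        kernel_choice=kernel("choice"), kernel_stim=kernel("stim"),
        mod_kernels=mod_kernels, lapse=lapse, p_guess=p_guess,
        log_likelihood=ll, n_iter=n_iter, converged=conv,
        basis=b, names=names, w=w)


def _em_once(x, y, w0, lapse, max_iter, tol, fit_guess=False):
    w = w0.copy()
    p_guess = 0.5
    p_att = expit(x @ w)
    ll = _total_ll(p_att, y, lapse, p_guess)
    conv = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: posterior probability of the lapse state
        like_att = np.where(y == 1, p_att, 1 - p_att)
        like_lapse = np.where(y == 1, p_guess, 1 - p_guess)
        num = lapse * like_lapse
        post = num / (num + (1 - lapse) * like_att + 1e-300)
        # M-step
        lapse = float(np.clip(post.mean(), 1e-6, 0.499))
        if fit_guess:
            s = post.sum()
            p_guess = float(np.clip((post * y).sum() / s if s > 0 else 0.5,
                                    1e-6, 1 - 1e-6))
        w, p_att = _weighted_logistic(x, y, w, 1.0 - post)
        ll_new = _total_ll(p_att, y, lapse, p_guess)
        assert ll_new >= ll - 1e-7, \
            f"EM log-likelihood decreased: {ll} -> {ll_new}"
        if ll_new - ll < tol:
            ll = ll_new
            conv = True
            break
        ll = ll_new
    return w, (lapse, p_guess), ll, it, conv


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def permutation_significance(trials: pd.DataFrame, n_perm: int = 1000,
                             with_modulation: bool = True,
                             seed: int | np.random.Generator = 0,
                             design_kwargs: dict | None = None,
                             fit_kwargs: dict | None = None) -> dict:
    """Trial-permutation test of history dependence.

    Shuffling trial order destroys sequential structure while preserving
    marginals; the intact model's log-likelihood is compared with the
    distribution of log-likelihoods of models fit to permuted data.
    p = (1 + #{permuted >= intact}) / (n_perm + 1). Permutation refits use
    the intact fit as a warm start.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation p-value")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    design_kwargs = design_kwargs or {}
    fit_kwargs = dict(fit_kwargs or {})
    design = build_design(trials, **design_kwargs)
    intact = fit(design, with_modulation=with_modulation, seed=rng,
                 **fit_kwargs)
    fit_kwargs.setdefault("n_restarts", 1)
    null = np.empty(n_perm)
    order_cols = trials[["session", "block", "trial"]].reset_index(drop=True)
    shuffle_cols = [c for c in trials.columns
                    if c not in ("session", "block", "trial")]
    for i in range(n_perm):
        perm = rng.permutation(len(trials))
        shuffled = trials[shuffle_cols].iloc[perm].reset_index(drop=True)
        pt = pd.concat([order_cols, shuffled], axis=1)
        d = build_design(pt, **design_kwargs)
        f = fit(d, with_modulation=with_modulation, seed=rng,
                w_init=intact.w, **fit_kwargs)
        null[i] = f.log_likelihood
    p = (1 + np.sum(null >= intact.log_likelihood)) / (n_perm + 1)
    return {"p": float(p), "ll_intact": intact.log_likelihood,
            "ll_null": null, "fit": intact}


def bootstrap_ci(trials: pd.DataFrame, n_boot: int = 500,
                 level: float = 0.68, with_modulation: bool = True,
                 seed: int | np.random.Generator = 0,
                 design_kwargs: dict | None = None,
                 fit_kwargs: dict | None = None,
                 return_draws: bool = False):
    """Percentile bootstrap CIs for all fitted weights, resampling blocks.

    Blocks (session, block) are drawn with replacement; refits are warm
    started at the full-data estimate. Returns (fit, DataFrame of lo/hi
    per weight name).
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    design_kwargs = design_kwargs or {}
    fit_kwargs = dict(fit_kwargs or {})
    design = build_design(trials, **design_kwargs)
    full = fit(design, with_modulation=with_modulation, seed=rng,
               **fit_kwargs)
    fit_kwargs.setdefault("n_restarts", 1)

    groups = list(trials.groupby(["session", "block"], sort=False))
    draws = np.empty((n_boot, len(full.w)))
    for i in range(n_boot):
        pick = rng.integers(0, len(groups), len(groups))
        parts = []
        for newb, gi in enumerate(pick):
            g = groups[gi][1].copy()
            g["session"] = 1
            g["block"] = newb + 1
            parts.append(g)
        bt = pd.concat(parts, ignore_index=True)
        d = build_design(bt, **design_kwargs)
        f = fit(d, with_modulation=with_modulation, seed=rng,
                w_init=full.w, **fit_kwargs)
        draws[i] = f.w
    lo = np.percentile(draws, 100 * (0.5 - level / 2), axis=0)
    hi = np.percentile(draws, 100 * (0.5 + level / 2), axis=0)
    ci = pd.DataFrame({"name": full.names, "estimate": full.w,
                       "lo": lo, "hi": hi})
    if return_draws:
        return full, ci, draws
    return full, ci


# ---------------------------------------------------------------------------
# Derived summaries
# ---------------------------------------------------------------------------

def strategy_transform(fit_result: HistoryFit) -> dict:
    """Outcome-based weights and the observer's strategy classification.

    correct = choice + stimulus weights, error = choice - stimulus weights
    (per lag). The observer is a 'repeater' when the lag-1 choice weight is
    positive, an 'alternator' otherwise; the strategy quadrant at lag 1 is
    choice-dominated (repeat/alternate) when |choice| > |stimulus|, else
    stimulus-dominated (win-stay/lose-switch for positive stimulus weight,
    win-switch/lose-stay for negative).
    """
    wc = fit_result.kernel_choice
    ws = fit_result.kernel_stim
    c1, s1 = wc[0], ws[0]
    if abs(c1) >= abs(s1):
        quadrant = "choice_repeat" if c1 > 0 else "choice_alternate"
    else:
        quadrant = "win_stay_lose_switch" if s1 > 0 else "win_switch_lose_stay"
    return {"correct": wc + ws, "error": wc - ws,
            "class": "repeater" if c1 > 0 else "alternator",
            "quadrant": quadrant}


def history_variance_fraction(fit_result: HistoryFit, design: HistoryDesign,
                              n_bins: int = 5) -> pd.DataFrame:
    """History share of decision-variable variance, by evidence bin.

    The linear predictor is split into its history component (past choices
    and stimuli, including modulated terms) and the rest; within each
    evidence-strength bin the ratio var(history) / var(total) is reported.
    """
    names = fit_result.names
    w = fit_result.w
    hist_idx = [i for i, nm in enumerate(names)
                if ("choice" in nm or "stim" in nm)]
    keep = [design.names.index(nm) for nm in names]
    x = design.x[:, keep]
    eta = x @ w
    eta_hist = x[:, hist_idx] @ w[hist_idx]
    strength = np.abs(x[:, names.index("evidence")])
    edges = np.quantile(strength, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.digitize(strength, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = bins == b
        tot = eta[m].var()
        rows.append(dict(bin=b + 1, evidence=strength[m].mean(),
                         fraction=eta_hist[m].var() / tot if tot > 0
                         else 0.0, n=int(m.sum())))
    return pd.DataFrame(rows)


def modulation_population_analysis(choice_weights, pupil_mod_weights,
                                   rt_mod_weights, n_perm: int = 10_000,
                                   seed: int | np.random.Generator = 0
                                   ) -> dict:
    """Group-level contrast of pupil- vs RT-linked bias modulation.

    Pearson correlations between individual lag-1 choice weights and their
    pupil/RT modulation weights; the difference of the two correlations is
    tested by randomly swapping (coin flip per observer) each observer's
    pupil and RT modulation weights. Repeater/alternator subgroup means of
    the modulation weights are compared with unpaired permutation tests.
    """
    cw = np.asarray(choice_weights, float)
    pm = np.asarray(pupil_mod_weights, float)
    rm = np.asarray(rt_mod_weights, float)
    if len(cw) < 5:
        raise ValueError("need at least 5 observers")
    for v in (cw, pm, rm):
        if np.ptp(v) == 0:
            raise ValueError("degenerate (constant) weights")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    r_pupil, p_pupil = pearsonr(cw, pm)
    r_rt, p_rt = pearsonr(cw, rm)
    obs_diff = r_pupil - r_rt

    null = np.empty(n_perm)
    for i in range(n_perm):
        flip = rng.random(len(cw)) < 0.5
        a = np.where(flip, rm, pm)
        b = np.where(flip, pm, rm)
        null[i] = pearsonr(cw, a)[0] - pearsonr(cw, b)[0]
    p_diff = (1 + np.sum(np.abs(null) >= abs(obs_diff))) / (n_perm + 1)

    from .stats import permutation_test
    rep = cw > 0
    groups = {}
    for name, v in (("pupil", pm), ("rt", rm)):
        res = permutation_test(v[rep], v[~rep], paired=False,
                               n_perm=min(n_perm, 5000), seed=rng) \
            if rep.any() and (~rep).any() else None
        groups[name] = {
            "mean_repeaters": float(v[rep].mean()) if rep.any() else np.nan,
            "mean_alternators": float(v[~rep].mean()) if (~rep).any()
            else np.nan,
            "p_between": res.p if res else np.nan}
    return {"r_pupil": float(r_pupil), "p_pupil": float(p_pupil),
            "r_rt": float(r_rt), "p_rt": float(p_rt),
            "diff_correlations": float(obs_diff),
            "p_diff": float(p_diff), "subgroups": groups}
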