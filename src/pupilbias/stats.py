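"""Group-level inference: permutation tests, cluster statistics, Bayes factors.

* Non-parametric permutation tests on means: sign flipping for one-sample
  and paired designs, label exchange for unpaired groups; two-sided p with
  +1 smoothing so p is never exactly zero.
* Cluster-based permutation testing for time courses: per-sample t tests
  form contiguous supra-threshold clusters whose summed-t mass is compared
  with the maximum-mass distribution under observer-level sign flipping,
  controlling the family-wise error rate across time.
* One-way repeated-measures ANOVA (main effect of bin).
* Default-prior (JZS) Bayes factors for the repeated-measures ANOVA (by
  Monte-Carlo integration over the g-priors, or a fast BIC approximation)
  and for Pearson correlations (by adaptive quadrature), with BF10 > 3 or
  < 1/3 read as substantial evidence for H1 or H0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats as sstats


@dataclass
class PermutationResult:
    statistic: float
    p: float
    n_perm: int
    null_mean: float
    null_sd: float


@dataclass
class BayesFactorResult:
    bf10: float
    method: str
    inputs: dict

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


@dataclass
class Cluster:
    start: int
    stop: int       # exclusive
    mass: float
    p: float


def permutation_test(x, y=None, paired: bool = True, n_perm: int = 10_000,
                     seed: int | np.random.Generator = 0
                     ) -> PermutationResult:
    """Two-sided permutation test on a difference of means.

    One-sample (y omitted or scalar) and paired designs flip the signs of
    individual (differences of) observations; unpaired designs exchange
    group labels. The p-value is the smoothed fraction of permutations
    whose |mean difference| reaches the observed one.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    x = np.asarray(x, float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")

    if y is None or np.isscalar(y):
        d = x - (0.0 if y is None else float(y))
        obs = d.mean()
        flips = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
        null = (flips * d).mean(axis=1)
    elif paired:
        y = np.asarray(y, float)
        if y.shape != x.shape:
            raise ValueError("paired samples must have equal length")
        d = x - y
        obs = d.mean()
        flips = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
        null = (flips * d).mean(axis=1)
    else:
        y = np.asarray(y, float)
        obs = x.mean() - y.mean()
        pooled = np.concatenate([x, y])
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(pooled)
            null[i] = perm[:x.size].mean() - perm[x.size:].mean()

    p = (1 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1)
    return PermutationResult(float(obs), float(p), n_perm,
                             float(null.mean()), float(null.std()))


# ---------------------------------------------------------------------------
# Cluster-based permutation
# ---------------------------------------------------------------------------

def _clusters_from_t(t, thr):
    """Contiguous runs of same-sign supra-threshold samples, with masses."""
    out = []
    above = np.abs(t) > thr
    i = 0
    n = len(t)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        sign = np.sign(t[i])
        while j < n and above[j] and np.sign(t[j]) == sign:
            j += 1
        out.append((i, j, float(t[i:j].sum())))
        i = j
    return out


def cluster_permutation(data: np.ndarray, data2: np.ndarray | None = None,
                        n_perm: int = 1000, cluster_alpha: float = 0.05,
                        seed: int | np.random.Generator = 0) -> list[Cluster]:
    """Cluster-corrected permutation test for (observers x samples) data.

    Tests the time course against zero, or (paired) between two conditions
    when ``data2`` is given. Per-sample two-sided t tests at
    ``cluster_alpha`` define clusters; each cluster's summed t is compared
    with the null distribution of the maximum |mass| under observer sign
    flipping.
    """
    x = np.asarray(data, float)
    if data2 is not None:
        x = x - np.asarray(data2, float)
    n_obs, n_samp = x.shape
    if n_obs < 3:
        raise ValueError("need at least 3 observers")
    thr = sstats.t.ppf(1 - cluster_alpha / 2, n_obs - 1)

    def tvals(m, v):
        return m / np.sqrt(v / n_obs)

    m = x.mean(axis=0)
    v = x.var(axis=0, ddof=1)
    t_obs = tvals(m, np.where(v > 0, v, np.inf))
    clusters = _clusters_from_t(t_obs, thr)
    if not clusters:
        return []

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ex2 = (x ** 2).mean(axis=0)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_obs))
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        mi = (flips[i] @ x) / n_obs
        vi = (ex2 - mi ** 2) * n_obs / (n_obs - 1)
        ti = tvals(mi, np.where(vi > 0, vi, np.inf))
        ci = _clusters_from_t(ti, thr)
        null_max[i] = max((abs(c[2]) for c in ci), default=0.0)

    return [Cluster(a, b, mass,
                    float((1 + np.sum(null_max >= abs(mass)))
                          / (n_perm + 1)))
            for a, b, mass in clusters]


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova(values: np.ndarray) -> tuple[float, float]:
    """One-way within-subject ANOVA on an (observers x bins) array.

    Returns (F, p) for the main effect of bin.
    """
    y = np.asarray(values, float)
    n, k = y.shape
    if k < 2:
        raise ValueError("need at least 2 bins")
    if np.isnan(y).any():
        raise ValueError("design must be complete (no NaN)")
    grand = y.mean()
    ss_bins = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_bins - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_err = ss_err / df2
    if ms_err == 0:
        return 0.0 if ss_bins == 0 else np.inf, 1.0 if ss_bins == 0 else 0.0
    f = (ss_bins / df1) / ms_err
    return float(f), float(sstats.f.sf(f, df1, df2))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) orthonormal contrast codes orthogonal to the intercept."""
    h = np.eye(k) - np.ones((k, k)) / k
    u, s, _ = np.linalg.svd(h)
    return u[:, :k - 1]


def bf_anova(values: np.ndarray, method: str = "jzs",
             r_fixed: float = 0.5, r_random: float = 1.0,
             n_mc: int = 4000,
             seed: int | np.random.Generator = 0) -> BayesFactorResult:
    """Default-prior Bayes factor for the one-way within-subject design.

    ``method='jzs'`` integrates the g-prior marginal likelihoods by Monte
    Carlo, with independent scaled inverse-chi-square priors on the effect
    (scale ``r_fixed``) and subject (scale ``r_random``) g parameters;
    ``method='bic'`` uses the unit-information BIC approximation
    BF10 = exp((BIC0 - BIC1) / 2).
    """
    y = np.asarray(values, float)
    n, k = y.shape
    if method == "bic":
        subj = np.kron(np.eye(n), np.ones((k, 1)))
        bins = np.kron(np.ones((n, 1)), np.eye(k))
        yv = y.reshape(-1)
        x0 = subj
        x1 = np.column_stack([subj, bins[:, 1:]])
        bf = np.exp((_bic(yv, x0) - _bic(yv, x1)) / 2.0)
        return BayesFactorResult(float(bf), "bic", {"n": n, "k": k})
    if method != "jzs":
        raise ValueError("method must be 'jzs' or 'bic'")

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    yv = y.reshape(-1)
    yv = yv - yv.mean()
    nn = yv.size
    z = np.kron(_orthonormal_contrasts(n), np.ones((k, 1)) / np.sqrt(k)) \
        * np.sqrt(k)
    xe = np.kron(np.ones((n, 1)), _orthonormal_contrasts(k))

    def log_marginal(w, g):
        # y ~ N(0, sigma^2 (I + W diag(g) W')), sigma^2 integrated out
        sigma = np.eye(nn) + (w * g) @ w.T
        sign, logdet = np.linalg.slogdet(sigma)
        quad = yv @ np.linalg.solve(sigma, yv)
        return -0.5 * logdet - 0.5 * (nn - 1) * np.log(quad)

    # g ~ scaled inverse-chi-square(1, r^2): draw as r^2 / chi2_1
    g_subj = r_random ** 2 / rng.chisquare(1, n_mc)
    g_eff = r_fixed ** 2 / rng.chisquare(1, n_mc)

    w1 = np.column_stack([z, xe])
    lm1 = np.array([
        log_marginal(w1, np.concatenate([np.full(z.shape[1], gs),
                                         np.full(xe.shape[1], ge)]))
        for gs, ge in zip(g_subj, g_eff)])
    lm0 = np.array([log_marginal(z, np.full(z.shape[1], gs))
                    for gs in g_subj])
    shift = max(lm1.max(), lm0.max())
    bf = np.exp(lm1 - shift).mean() / np.exp(lm0 - shift).mean()
    return BayesFactorResult(float(bf), "jzs",
                             {"n": n, "k": k, "n_mc": n_mc})


def _bic(y, x):
    n = y.size
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    sse = np.sum((y - x @ beta) ** 2)
    kpar = np.linalg.matrix_rank(x) + 1
    return n * np.log(sse / n) + kpar * np.log(n)


# ---------------------------------------------------------------------------
# JZS correlation Bayes factor
# ---------------------------------------------------------------------------

def bf_correlation(r: float, n: int) -> BayesFactorResult:
    """Default JZS Bayes factor for a Pearson correlation, from (n, r).

    Computed by numerical integration of the Jeffreys-Zellner-Siow
    marginal likelihood ratio

        BF10 = int_0^inf (1+g)^((n-2)/2) (1 + (1-r^2) g)^(-(n-1)/2)
               sqrt(n/2) / Gamma(1/2) g^(-3/2) exp(-n / (2g)) dg,

    symmetric in the sign of r.
    """
    if not np.isfinite(r) or abs(r) >= 1:
        raise ValueError("require |r| < 1")
    if n < 4:
        raise ValueError("require n >= 4")
    r2 = r * r
    const = np.sqrt(n / 2.0) / special.gamma(0.5)

    def integrand(g):
        return ((1 + g) ** ((n - 2) / 2.0)
                * (1 + (1 - r2) * g) ** (-(n - 1) / 2.0)
                * const * g ** (-1.5) * np.exp(-n / (2.0 * g)))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0, np.inf, limit=300)
    return BayesFactorResult(float(val), "jzs-correlation",
                             {"r": float(r), "n": int(n)})
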