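"""Signal-detection model of decision uncertainty.

On each trial a decision variable dv is drawn from N(mu, sigma), where mu is
the trial's signed sensory evidence and sigma the internal noise SD. The
binary choice is the sign of dv relative to a criterion c, and decision
confidence is the probability of being correct given dv,

    confidence = Phi(|dv - c| / sigma),        uncertainty = 1 - confidence,

so uncertainty ranges from 0 (dv far from the bound) to 0.5 (dv at the
bound). This graded uncertainty has three diagnostic signatures: it
decreases with evidence strength on correct trials but increases on errors;
accuracy falls monotonically from ~100% to ~50% across uncertainty bins
(never below chance); and at matched evidence strength, higher uncertainty
still predicts lower accuracy.

The default sigma = 2.723 is the inverse of a probit psychometric slope of
0.367 per unit of motion energy, fit to group data from a two-interval
motion-coherence discrimination task; evidence strengths are simulated on
[0, 6] motion-energy units to match that task's range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.stats import norm


@dataclass
class SdtParams:
    """Parameters of the static SDT observer."""

    sigma: float = 2.723
    c: float = 0.0
    mu_range: tuple[float, float] = (0.0, 6.0)

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class UncertaintyResult:
    dv: np.ndarray
    choice: np.ndarray        # +1 / -1
    confidence: np.ndarray    # in [0.5, 1]
    uncertainty: np.ndarray   # in [0, 0.5]


@dataclass
class SignatureCurves:
    """Binned summary curves of the three uncertainty signatures."""

    # uncertainty vs evidence strength, split by outcome
    evidence_bins: np.ndarray
    uncertainty_correct: np.ndarray
    uncertainty_error: np.ndarray
    # accuracy (%) vs uncertainty
    uncertainty_bins: np.ndarray
    accuracy_by_uncertainty: np.ndarray
    # accuracy (%) vs evidence strength, median split on uncertainty
    evidence_bins_split: np.ndarray
    accuracy_low_uncertainty: np.ndarray
    accuracy_high_uncertainty: np.ndarray


def decide(dv, params: SdtParams | None = None) -> UncertaintyResult:
    """Choice, confidence and uncertainty for decision-variable samples.

    choice = sign(dv - c), with the (measure-zero) tie dv == c resolved
    to +1; confidence = Phi(|dv - c| / sigma).
    """
    params = params or SdtParams()
    dv = np.atleast_1d(np.asarray(dv, float))
    if not np.all(np.isfinite(dv)):
        raise ValueError("dv must be finite")
    choice = np.where(dv >= params.c, 1, -1)
    confidence = norm.cdf(np.abs(dv - params.c) / params.sigma)
    return UncertaintyResult(dv, choice, confidence, 1.0 - confidence)


def mean_uncertainty(mu: float, params: SdtParams | None = None,
                     outcome: str = "correct") -> float:
    """Expected uncertainty conditional on outcome, for dv ~ N(mu, sigma).

    Computed by numerical integration of (1 - Phi(|x - c|/sigma)) against the
    truncated dv density on the correct (x > c for mu >= 0) or error side of
    the criterion. By the model's symmetry only mu >= 0 need be considered.

    Raises ``FloatingPointError`` when the requested outcome has vanishing
    probability (e.g. errors at very large mu).
    """
    params = params or SdtParams()
    if mu < 0:
        raise ValueError("mu must be nonnegative (model is symmetric)")
    if outcome not in ("correct", "error"):
        raise ValueError("outcome must be 'correct' or 'error'")
    s, c = params.sigma, params.c

    if outcome == "correct":
        lo, hi = c, np.inf
        p_outcome = norm.sf(c, loc=mu, scale=s)
    else:
        lo, hi = -np.inf, c
        p_outcome = norm.cdf(c, loc=mu, scale=s)
    if p_outcome < 1e-300:
        raise FloatingPointError(
            f"outcome {outcome!r} has probability ~0 at mu={mu}")

    def integrand(x):
        return norm.sf(np.abs(x - c) / s) * norm.pdf(x, loc=mu, scale=s)

    val, _ = integrate.quad(integrand, lo, hi, limit=200)
    return val / p_outcome


def simulate_trials(params: SdtParams, n_trials: int,
                    rng: np.random.Generator):
    """Draw signed evidence, dv, choices and uncertainty for n_trials.

    Evidence strength is uniform on ``mu_range`` with random sign (a
    documented stand-in for the task's empirical evidence distribution).
    Returns (mu_signed, result, correct).
    """
    lo, hi = params.mu_range
    strength = rng.uniform(lo, hi, n_trials)
    sign = rng.choice([-1.0, 1.0], n_trials)
    mu = sign * strength
    dv = rng.normal(mu, params.sigma)
    res = decide(dv, params)
    correct = (res.choice == np.sign(sign)).astype(int)
    return mu, res, correct


def _bin_means(x, y, edges):
    """Mean of y within bins of x; empty bins dropped."""
    idx = np.digitize(x, edges[1:-1])
    centers, means = [], []
    for b in range(len(edges) - 1):
        m = idx == b
        if m.any():
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            means.append(y[m].mean())
    return np.array(centers), np.array(means)


def simulate_signatures(params: SdtParams | None = None,
                        n_trials: int = 1_000_000, n_bins: int = 100,
                        seed: int | np.random.Generator = 0
                        ) -> SignatureCurves:
    """Monte-Carlo simulation of the three uncertainty signatures.

    Accuracy-vs-uncertainty uses equal-count (quantile) bins so no bin is
    empty; evidence axes use equal-width bins. Accuracy is returned in %.
    """
    params = params or SdtParams()
    if n_trials < 10_000:
        raise ValueError("n_trials must be at least 1e4 for stable curves")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    mu, res, correct = simulate_trials(params, n_trials, rng)
    strength = np.abs(mu)
    unc = res.uncertainty
    correct = np.asarray(correct, float)

    ev_edges = np.linspace(params.mu_range[0], params.mu_range[1], n_bins + 1)
    ec, uc = _bin_means(strength[correct == 1], unc[correct == 1], ev_edges)
    ee, ue = _bin_means(strength[correct == 0], unc[correct == 0], ev_edges)
    if len(ec) != len(ee) or not np.allclose(ec, ee):
        # align on common bins for the by-outcome comparison
        common = np.intersect1d(ec, ee)
        uc = uc[np.isin(ec, common)]
        ue = ue[np.isin(ee, common)]
        ec = common

    # quantile bins on uncertainty
    q_edges = np.quantile(unc, np.linspace(0, 1, n_bins + 1))
    q_edges[0] -= 1e-12
    q_edges[-1] += 1e-12
    ub, acc_u = _bin_means(unc, 100.0 * correct, q_edges)

    med = np.median(unc)
    low = unc <= med
    eb_lo, acc_lo = _bin_means(strength[low], 100.0 * correct[low], ev_edges)
    eb_hi, acc_hi = _bin_means(strength[~low], 100.0 * correct[~low], ev_edges)
    common = np.intersect1d(eb_lo, eb_hi)
    acc_lo = acc_lo[np.isin(eb_lo, common)]
    acc_hi = acc_hi[np.isin(eb_hi, common)]

    return SignatureCurves(
        evidence_bins=ec, uncertainty_correct=uc, uncertainty_error=ue,
        uncertainty_bins=ub, accuracy_by_uncertainty=acc_u,
        evidence_bins_split=common,
        accuracy_low_uncertainty=acc_lo, accuracy_high_uncertainty=acc_hi,
    )
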