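"""Discretized Bayesian threshold estimation (QUEST+ style).

A location's belief about its differential light sensitivity (DLS, in dB of
stimulus attenuation) is a probability mass function over a discrete
threshold domain. The frequency-of-seeing curve is a modified cumulative
Gaussian

    p_seen(x; mu) = gamma + (1 - gamma - lambda) * (1 - Phi((x - mu) / sigma)),

decreasing in stimulus level x because higher dB means a dimmer stimulus.
Entropy is Shannon entropy in bits; the one-trial-ahead expected entropy
reduction E(dH) drives both stimulus selection and, one level up, the
selection of new test locations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr


class DegenerateUpdateError(ValueError):
    """Posterior update with zero total likelihood."""


@dataclass(frozen=True)
class PsychometricParams:
    """Fixed frequency-of-seeing parameters: slope spread sigma (dB; may be
    inf for a completely flat curve), lapse rate and guess rate."""

    sigma: float = 1.5
    lapse: float = 0.05
    guess: float = 0.02

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError("sigma must be positive (or inf)")
        if not (0 <= self.lapse < 0.5 and 0 <= self.guess < 0.5):
            raise ValueError("lapse and guess rates must lie in [0, 0.5)")
        if self.guess + self.lapse >= 1:
            raise ValueError("guess + lapse must be < 1")

    def with_sigma(self, sigma: float) -> "PsychometricParams":
        return PsychometricParams(sigma, self.lapse, self.guess)


def default_stimulus_domain() -> np.ndarray:
    """0..40 dB in 1 dB steps."""
    return np.arange(0.0, 41.0)


def default_threshold_domain() -> np.ndarray:
    """Candidate DLS values, 0..40 dB in 1 dB steps."""
    return np.arange(0.0, 41.0)


def _check_domain(domain: np.ndarray) -> np.ndarray:
    domain = np.asarray(domain, dtype=float)
    if domain.size == 0 or np.any(np.diff(domain) <= 0):
        raise ValueError("domain must be nonempty and strictly increasing")
    return domain


def validate_pmf(pmf: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    pmf = np.asarray(pmf, dtype=float)
    if np.any(pmf < 0) or abs(pmf.sum() - 1.0) > tol:
        raise ValueError("pmf must be nonnegative and sum to 1")
    return pmf


def uniform_pmf(n_bins: int) -> np.ndarray:
    return np.full(n_bins, 1.0 / n_bins)


def normative_prior(mu_normal: float, thresh_domain, sd_normal: float = 5.0,
                    weight_abnormal: float = 0.2, mu_abnormal: float = 2.0,
                    sd_abnormal: float = 8.0) -> np.ndarray:
    """Bimodal starting prior in the ZEST tradition: a mode at the
    age-normal sensitivity plus a broad low-sensitivity mode admitting
    pathology. Normal locations then converge within a handful of trials
    while damaged locations retain high entropy — the spatial uncertainty
    structure that drives test-location selection."""
    thr = _check_domain(thresh_domain)
    normal = np.exp(-0.5 * ((thr - mu_normal) / sd_normal) ** 2)
    abnormal = np.exp(-0.5 * ((thr - mu_abnormal) / sd_abnormal) ** 2)
    p = (1.0 - weight_abnormal) * normal / normal.sum() \
        + weight_abnormal * abnormal / abnormal.sum()
    return p / p.sum()


def p_seen(x, mu, params: PsychometricParams):
    """Probability of reporting a stimulus of level ``x`` dB seen, given
    true threshold ``mu``. Vectorized over x and/or mu."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    span = 1.0 - params.guess - params.lapse
    if math.isinf(params.sigma):
        out = np.broadcast_arrays(x, mu)[0] * 0.0 + (params.guess + span * 0.5)
    else:
        out = params.guess + span * ndtr((mu - x) / params.sigma)
    return out if out.ndim else float(out)


def entropy(pmf) -> float:
    """Shannon entropy in bits, with 0 * log 0 = 0."""
    p = validate_pmf(pmf)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


_LIK_CACHE: dict = {}


def seen_likelihood_table(stim_domain, thresh_domain,
                          params: PsychometricParams) -> np.ndarray:
    """(n_stimuli, n_thresholds) table of p_seen; cached per configuration."""
    stim = _check_domain(stim_domain)
    thr = _check_domain(thresh_domain)
    key = (stim.tobytes(), thr.tobytes(), params.sigma, params.lapse, params.guess)
    tab = _LIK_CACHE.get(key)
    if tab is None:
        tab = p_seen(stim[:, None], thr[None, :], params)
        tab = np.atleast_2d(tab)
        if len(_LIK_CACHE) > 4096:
            _LIK_CACHE.clear()
        _LIK_CACHE[key] = tab
    return tab


def posterior_update(prior, stimulus: float, seen: bool,
                     params: PsychometricParams, thresh_domain) -> np.ndarray:
    """Bayes-rule update of a threshold PMF after one trial."""
    prior = validate_pmf(prior)
    thr = _check_domain(thresh_domain)
    lik = p_seen(float(stimulus), thr, params)
    if not seen:
        lik = 1.0 - lik
    post = prior * lik
    total = post.sum()
    if total <= 0:
        raise DegenerateUpdateError("zero total likelihood for this response")
    return post / total


def _expected_posterior_entropy_all(prior: np.ndarray,
                                    seen_tab: np.ndarray) -> np.ndarray:
    """Expected posterior entropy for every stimulus row of ``seen_tab``."""

    def branch(joint: np.ndarray) -> np.ndarray:
        p_r = joint.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            post = joint / p_r[:, None]
            term = np.where(joint > 0, post * np.log2(post), 0.0)
        h = -term.sum(axis=1)
        return np.where(p_r > 0, p_r * h, 0.0)

    return branch(seen_tab * prior) + branch((1.0 - seen_tab) * prior)


def expected_entropy_after(prior, stimulus: float,
                           params: PsychometricParams, thresh_domain) -> float:
    """Expected entropy of the posterior after presenting ``stimulus`` once,
    averaging over both possible responses. Never exceeds the prior entropy."""
    prior = validate_pmf(prior)
    tab = seen_likelihood_table([float(stimulus)], thresh_domain, params)
    return float(_expected_posterior_entropy_all(prior, tab)[0])


def expected_entropy_reduction(prior, stim_domain, thresh_domain,
                               params: PsychometricParams):
    """One-trial-ahead expected entropy reduction E(dH).

    Returns ``(e_dh, best_stimulus)`` where ``best_stimulus`` minimizes the
    expected posterior entropy over the stimulus domain (ties break to the
    lowest dB level). E(dH) is clipped at 0 against roundoff.
    """
    prior = validate_pmf(prior)
    stim = _check_domain(stim_domain)
    if math.isinf(params.sigma):
        # flat psychometric function: the response is independent of the
        # threshold, so no stimulus carries any information
        return 0.0, float(stim[0])
    tab = seen_likelihood_table(stim, thresh_domain, params)
    exp_h = _expected_posterior_entropy_all(prior, tab)
    i = int(np.argmin(exp_h))  # first minimum = lowest dB on ties
    e_dh = max(entropy(prior) - float(exp_h[i]), 0.0)
    return e_dh, float(stim[i])


def select_stimulus(prior, stim_domain, thresh_domain,
                    params: PsychometricParams) -> float:
    """The entropy-optimal next stimulus level (see expected_entropy_reduction)."""
    return expected_entropy_reduction(prior, stim_domain, thresh_domain, params)[1]


def estimate_threshold(pmf, thresh_domain) -> float:
    """Posterior-mean DLS estimate in dB."""
    p = validate_pmf(pmf)
    thr = _check_domain(thresh_domain)
    return float(p @ thr)


@dataclass(frozen=True)
class TrialRecord:
    location: tuple
    stimulus: float
    seen: bool


def run_trials(prior, respond, n_trials: int, params: PsychometricParams,
               stim_domain, thresh_domain, location=(0.0, 0.0)):
    """Run ``n_trials`` entropy-optimal trials against ``respond(stimulus)``.

    Returns the final posterior and the list of TrialRecords.
    """
    pmf = validate_pmf(prior)
    records = []
    for _ in range(int(n_trials)):
        stim = select_stimulus(pmf, stim_domain, thresh_domain, params)
        seen = bool(respond(stim))
        pmf = posterior_update(pmf, stim, seen, params, thresh_domain)
        records.append(TrialRecord(tuple(np.asarray(location, float)), stim, seen))
    return pmf, records
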