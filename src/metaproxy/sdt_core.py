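"""Generative signal-detection model of first-order decisions, proxy
responses, and metacognitive noise.

The observer sees one of two stimuli (coded -1/+1) and draws internal
evidence ``e ~ Normal(stimulus * d'/2, 1)``.  The first-order decision is a
threshold on ``e`` at a fixed criterion (0 by default, the optimal unbiased
criterion).  Two independent corruptions of ``e`` model two distinct
imperfections:

* a *proxy* of the decision, ``e + Normal(0, proxy_sigma)`` thresholded at 0,
  standing in for a covert response inferred from motor tracking rather than
  observed directly; and
* a *degraded* copy, ``e + Normal(0, meta_sigma)``, whose absolute value is
  the confidence report, standing in for metacognitive noise between the
  first-order and second-order stages.

With ``meta_sigma = 0`` confidence carries the full first-order information
and the fitted meta-d'/d' ratio (M-ratio) is ~1; increasing ``meta_sigma``
drives it toward 0.  M-ratios above 1 ("hyper-metacognition") are produced
by swapping the roles of the two copies: the first-order decision is then
taken on the degraded evidence while confidence is read from the clean
evidence, making the second-order distributions sharper than the first-order
ones.

All units are evidence standard deviations: the evidence distribution has
SD 1, so d' is both the distribution separation and the sensitivity index,
and first-order accuracy is ``Phi(d'/2)`` at criterion 0.  The default
``proxy_sigma`` of 1.6 evidence-SDs is calibrated so that proxy and actual
decisions agree on ~70% of trials when accuracy is staircased to ~71%
(d' = 1.107), matching the overt-vs-proxy correspondence observed with
real continuous-report data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "DEFAULT_D_PRIME",
    "DEFAULT_PROXY_SIGMA",
    "SimObserver",
    "SimTrials",
    "draw_evidence",
    "decide",
    "make_proxy",
    "degrade_evidence",
    "assign_confidence",
    "simulate_trials",
    "calibrate_meta_noise",
    "meta_sigma_for_m_ratio",
    "CalibrationError",
]

#: d' giving Phi(d'/2) = 0.71, the accuracy a 1-up/2-down staircase holds.
DEFAULT_D_PRIME: float = 2.0 * norm.ppf(0.71)

#: Proxy-noise SD (evidence-SD units) giving ~70% proxy/decision agreement
#: at d' = DEFAULT_D_PRIME.
DEFAULT_PROXY_SIGMA: float = 1.6


@dataclass(frozen=True)
class SimObserver:
    """Parameters of the generative SDT observer.

    Parameters
    ----------
    d_prime
        First-order sensitivity (>= 0); evidence means are ``+-d_prime/2``.
    criterion
        First-order decision bound on the evidence axis (default 0).
    proxy_sigma
        SD of the noise separating the proxy from the evidence (>= 0).
    meta_sigma
        SD of the metacognitive noise degrading the confidence copy (>= 0).
    target_m_ratio
        Intended meta-d'/d' (> 0).  Values above 1 activate the swap of the
        clean and degraded evidence copies described in the module docstring.
    """

    d_prime: float = DEFAULT_D_PRIME
    criterion: float = 0.0
    proxy_sigma: float = DEFAULT_PROXY_SIGMA
    meta_sigma: float = 0.0
    target_m_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.d_prime < 0:
            raise ValueError(f"d_prime must be >= 0, got {self.d_prime}")
        if self.proxy_sigma < 0:
            raise ValueError(f"proxy_sigma must be >= 0, got {self.proxy_sigma}")
        if self.meta_sigma < 0:
            raise ValueError(f"meta_sigma must be >= 0, got {self.meta_sigma}")
        if not self.target_m_ratio > 0:
            raise ValueError(
                f"target_m_ratio must be > 0, got {self.target_m_ratio}"
            )


@dataclass(frozen=True)
class SimTrials:
    """Arrays of simulated trials (one entry per trial)."""

    stimulus: np.ndarray          # {-1, +1}
    evidence: np.ndarray          # clean internal evidence e
    evidence_degraded: np.ndarray  # e + metacognitive noise
    first_order_evidence: np.ndarray  # copy the decision was taken on
    decision: np.ndarray          # {-1, +1}
    evidence_proxy: np.ndarray
    proxy_decision: np.ndarray    # {-1, +1}
    confidence: np.ndarray        # >= 0

    def __len__(self) -> int:
        return self.stimulus.size

    @property
    def accuracy(self) -> np.ndarray:
        """1 where the decision matches the stimulus, else 0."""
        return (self.decision == self.stimulus).astype(int)

    @property
    def proxy_accuracy(self) -> np.ndarray:
        """1 where the proxy decision matches the stimulus, else 0."""
        return (self.proxy_decision == self.stimulus).astype(int)


def draw_evidence(stimulus, observer: SimObserver, rng: np.random.Generator):
    """Draw internal evidence ``e ~ Normal(stimulus * d'/2, 1)``.

    ``stimulus`` may be a scalar or array of -1/+1 codes; the return matches
    its shape.
    """
    stimulus = np.asarray(stimulus)
    if not np.all(np.isin(stimulus, (-1, 1))):
        raise ValueError("stimulus must be coded -1/+1")
    mu = stimulus * observer.d_prime / 2.0
    return rng.normal(mu, 1.0)


def decide(evidence, criterion: float = 0.0):
    """Threshold evidence into a -1/+1 decision (+1 iff evidence >= criterion)."""
    evidence = np.asarray(evidence)
    d = np.where(evidence >= criterion, 1, -1)
    return d if d.ndim else int(d)


def make_proxy(evidence, proxy_sigma: float, rng: np.random.Generator):
    """Corrupt evidence with Gaussian noise and re-threshold at 0.

    Returns ``(evidence_proxy, proxy_decision)``.  The proxy decision is the
    sign of the noisy evidence relative to the same optimal criterion at 0,
    mimicking a covert response inferred with error.
    """
    if proxy_sigma < 0:
        raise ValueError("proxy_sigma must be >= 0")
    evidence = np.asarray(evidence, dtype=float)
    e_proxy = evidence + rng.normal(0.0, 1.0, size=evidence.shape) * proxy_sigma
    return e_proxy, decide(e_proxy, 0.0)


def degrade_evidence(evidence, meta_sigma: float, rng: np.random.Generator):
    """Add metacognitive noise: ``e + Normal(0, meta_sigma)``."""
    if meta_sigma < 0:
        raise ValueError("meta_sigma must be >= 0")
    evidence = np.asarray(evidence, dtype=float)
    return evidence + rng.normal(0.0, 1.0, size=evidence.shape) * meta_sigma


def assign_confidence(evidence, evidence_degraded, target_m_ratio: float):
    """Assign confidence and the first-order evidence copy.

    For ``target_m_ratio <= 1`` the decision is taken on the clean evidence
    and confidence is ``|evidence_degraded|`` (information loss at the second
    order).  For ``target_m_ratio > 1`` the two copies swap roles: the
    decision is taken on the degraded evidence while confidence is
    ``|evidence|``, so the second-order signal is sharper than the
    first-order one.

    Returns ``(first_order_evidence, confidence)``.
    """
    if not target_m_ratio > 0:
        raise ValueError(f"target_m_ratio must be > 0, got {target_m_ratio}")
    evidence = np.asarray(evidence, dtype=float)
    evidence_degraded = np.asarray(evidence_degraded, dtype=float)
    if target_m_ratio <= 1.0:
        return evidence, np.abs(evidence_degraded)
    return evidence_degraded, np.abs(evidence)


def simulate_trials(
    n_trials: int, observer: SimObserver, rng: np.random.Generator
) -> SimTrials:
    """Simulate ``n_trials`` complete trials for one observer.

    Stimuli are -1/+1 with equal probability.  The proxy is derived from the
    same evidence copy the first-order decision used, so that proxy/decision
    correspondence is governed by ``proxy_sigma`` alone in both M-ratio
    regimes.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    stimulus = rng.choice(np.array([-1, 1]), size=n_trials)
    evidence = draw_evidence(stimulus, observer, rng)
    evidence_degraded = degrade_evidence(evidence, observer.meta_sigma, rng)
    first_order, confidence = assign_confidence(
        evidence, evidence_degraded, observer.target_m_ratio
    )
    decision = decide(first_order, observer.criterion)
    e_proxy, proxy_decision = make_proxy(first_order, observer.proxy_sigma, rng)
    return SimTrials(
        stimulus=stimulus,
        evidence=evidence,
        evidence_degraded=evidence_degraded,
        first_order_evidence=first_order,
        decision=decision,
        evidence_proxy=e_proxy,
        proxy_decision=proxy_decision,
        confidence=confidence,
    )


class CalibrationError(RuntimeError):
    """Raised when the meta-d' fit fails for a calibration grid value."""


def _realized_m_ratio(
    meta_sigma: float,
    d_prime: float,
    n_trials: int,
    rng: np.random.Generator,
    swap: bool,
) -> float:
    # Local import: metacog depends on nothing here, but keep module load light.
    from . import metacog

    observer = SimObserver(
        d_prime=d_prime,
        meta_sigma=meta_sigma,
        target_m_ratio=2.0 if swap else 1.0,
    )
    trials = simulate_trials(n_trials, observer, rng)
    scaled, degenerate = metacog.scale_confidence(trials.confidence)
    if degenerate:
        raise CalibrationError(
            f"degenerate confidence distribution at meta_sigma={meta_sigma}"
        )
    bins = metacog.bin_confidence(scaled)
    counts = metacog.tally_type2(trials.stimulus, trials.decision, bins)
    fit = metacog.fit_meta_d(counts)
    if not fit.converged or not np.isfinite(fit.m_ratio):
        raise CalibrationError(
            f"meta-d' fit did not converge at meta_sigma={meta_sigma}"
        )
    return fit.m_ratio


def calibrate_meta_noise(
    meta_sigma_grid,
    d_prime: float,
    n_trials: int,
    rng: np.random.Generator,
    swap: bool = False,
) -> dict[float, float]:
    """Map metacognitive-noise SDs to realized M-ratios by simulation.

    For each grid value, simulates ``n_trials`` trials, runs the full
    measurement stack (min-max confidence scaling, 4 equal-width bins,
    type-2 tally, meta-d' MLE) and records the fitted meta-d'/d'.  Without
    the swap the mapping decreases from ~1 toward 0 as ``meta_sigma`` grows;
    with ``swap=True`` it increases from ~1 upward.

    Raises :class:`CalibrationError` naming the offending grid value if any
    fit fails.
    """
    grid = [float(s) for s in meta_sigma_grid]
    if any(s < 0 for s in grid):
        raise ValueError("meta_sigma grid values must be >= 0")
    if n_trials < 1000:
        raise ValueError("n_trials must be >= 1000 for a stable calibration")
    return {
        s: _realized_m_ratio(s, d_prime, n_trials, rng, swap) for s in grid
    }


def meta_sigma_for_m_ratio(
    target_m_ratio: float,
    d_prime: float,
    rng: np.random.Generator,
    n_trials: int = 50_000,
    grid_size: int = 9,
) -> float:
    """Invert the meta_sigma -> M-ratio mapping for one target.

    Builds an empirical calibration curve around the analytic first guess
    (``meta_sigma ~ sqrt(1/m^2 - 1)`` below 1, ``sqrt(m^2 - 1)`` above,
    from the variance inflation of the degraded copy), enforces
    monotonicity, and interpolates.  Targets within 2% of 1 return 0
    exactly (no added noise).
    """
    if not target_m_ratio > 0:
        raise ValueError("target_m_ratio must be > 0")
    if abs(target_m_ratio - 1.0) < 0.02:
        return 0.0
    swap = target_m_ratio > 1.0
    if swap:
        guess = float(np.sqrt(target_m_ratio**2 - 1.0))
    else:
        guess = float(np.sqrt(1.0 / target_m_ratio**2 - 1.0))
    grid = np.concatenate(
        [[0.0], guess * np.linspace(0.4, 2.0, grid_size - 1)]
    )
    curve = calibrate_meta_noise(grid, d_prime, n_trials, rng, swap=swap)
    sigmas = np.array(sorted(curve))
    ratios = np.array([curve[s] for s in sigmas])
    if swap:
        ratios = np.maximum.accumulate(ratios)
        return float(np.interp(target_m_ratio, ratios, sigmas))
    # decreasing curve: enforce and flip for interpolation
    ratios = np.minimum.accumulate(ratios)
    return float(np.interp(target_m_ratio, ratios[::-1], sigmas[::-1]))
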