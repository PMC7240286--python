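"""Measurement stack: confidence scaling/binning, type-2 counts, meta-d'
maximum likelihood, and regression-based metacognitive sensitivity.

meta-d' (Maniscalco & Lau) expresses type-2 performance — how well
confidence ratings discriminate correct from incorrect decisions — in the
units of first-order sensitivity: it is the d' an ideal SDT observer would
need in order to produce the observed response-conditional confidence
distributions, holding the relative type-1 criterion fixed.  The ratio
meta-d'/d' (M-ratio) is 1 when confidence uses all first-order information,
below 1 under second-order information loss, and above 1 when extra
information reaches the confidence stage.

The regression route (``fit_sensitivity``) measures metacognitive
sensitivity as the logistic slope of accuracy on confidence, with a
condition interaction.  It is deliberately a two-stage procedure —
per-subject maximum-likelihood logistic fits followed by group-level
one-sample t tests on the coefficients — which gives a deterministic,
MCMC-free significance decision for the interaction term as required by
the power simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.stats import norm

__all__ = [
    "Type2Counts",
    "MetaDFit",
    "SensitivityFit",
    "scale_confidence",
    "bin_confidence",
    "tally_type2",
    "fit_meta_d",
    "type2_loglik",
    "fit_sensitivity",
]


# --------------------------------------------------------------------------
# confidence scaling and binning
# --------------------------------------------------------------------------

def scale_confidence(ratings) -> tuple[np.ndarray, bool]:
    """Min-max scale one subject's confidence ratings onto [0, 1].

    Subtracts the subject's minimum rating and divides by the range, which
    removes between-subject usage biases while preserving within-subject
    ordering and condition mean differences (they are affinely related to
    the raw ones).

    Returns ``(scaled, degenerate)``.  If all ratings are identical the
    range is undefined; by convention every value maps to 0.5 and the
    degenerate flag is set so the subject can stay in mean-confidence
    analyses but be excluded from binned type-2 fits.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.size < 2:
        raise ValueError("need at least 2 ratings to scale")
    lo, hi = ratings.min(), ratings.max()
    if hi == lo:
        return np.full_like(ratings, 0.5), True
    return (ratings - lo) / (hi - lo), False


def bin_confidence(scaled, n_bins: int = 4) -> np.ndarray:
    """Discretize scaled confidence in [0, 1] into ``n_bins`` equal-width bins.

    Bins are half-open, ``[0, 1/n), [1/n, 2/n), ..., [1-1/n, 1]``, labelled
    1..n_bins; 1.0 falls in the top bin.
    """
    scaled = np.asarray(scaled, dtype=float)
    if np.any((scaled < 0) | (scaled > 1)):
        raise ValueError("scaled confidence must lie in [0, 1]")
    bins = np.minimum(np.floor(scaled * n_bins).astype(int) + 1, n_bins)
    return bins if bins.ndim else np.asarray(bins)


# --------------------------------------------------------------------------
# type-2 counts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Type2Counts:
    """Confidence-bin contingency counts, ``counts[stimulus, response, bin]``.

    Axis 0 indexes the stimulus (-1 then +1), axis 1 the response (-1 then
    +1), axis 2 the confidence bin (1..n_bins).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape[:2] != (2, 2) or c.ndim != 3:
            raise ValueError("counts must have shape (2, 2, n_bins)")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(float))

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def n_trials(self) -> int:
        return int(self.counts.sum())


def tally_type2(stimulus, response, conf_bin, n_bins: int = 4) -> Type2Counts:
    """Tally trials into stimulus x response x confidence-bin counts.

    Rejects missing responses (NaN or values outside {-1, +1}), reporting
    how many rows offended.
    """
    stimulus = np.asarray(stimulus)
    response = np.asarray(response, dtype=float)
    conf_bin = np.asarray(conf_bin)
    bad = ~np.isin(response, (-1, 1)) | ~np.isfinite(response)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} trials have missing/invalid responses")
    counts = np.zeros((2, 2, n_bins))
    for s_idx, s in enumerate((-1, 1)):
        for r_idx, r in enumerate((-1, 1)):
            mask = (stimulus == s) & (response == r)
            if mask.any():
                counts[s_idx, r_idx] = np.bincount(
                    conf_bin[mask] - 1, minlength=n_bins
                )[:n_bins]
    return Type2Counts(counts)


# --------------------------------------------------------------------------
# meta-d' maximum likelihood
# --------------------------------------------------------------------------

@dataclass
class MetaDFit:
    """Result of a meta-d' maximum-likelihood fit."""

    d_prime: float
    type1_criterion: float
    meta_d: float
    m_ratio: float
    type2_criteria: np.ndarray  # shape (2, n_bins-1): rows = response -1, +1
    log_likelihood: float
    converged: bool
    message: str = ""


def _type1_estimates(counts: np.ndarray) -> tuple[float, float]:
    """Equal-variance d' and criterion from the marginal type-1 counts."""
    n_s1, n_s2 = counts[0].sum(), counts[1].sum()
    far = counts[0, 1].sum() / n_s1   # P(resp +1 | stim -1)
    hr = counts[1, 1].sum() / n_s2    # P(resp +1 | stim +1)
    z_hr, z_far = norm.ppf(hr), norm.ppf(far)
    return z_hr - z_far, -0.5 * (z_hr + z_far)


def type2_loglik(
    counts: Type2Counts,
    meta_d: float,
    c_prime: float,
    incr_minus: np.ndarray,
    incr_plus: np.ndarray,
) -> float:
    """Log likelihood of the response-conditional confidence counts.

    The meta-level observer has sensitivity ``meta_d`` and type-1 criterion
    ``meta_c = c_prime * meta_d`` (the empirical relative criterion
    rescaled into meta-d' units).  ``incr_minus``/``incr_plus`` are the
    positive outward gaps from ``meta_c`` to the type-2 criteria on the
    response -1 / +1 side; cumulative sums enforce their ordering.
    """
    k = counts.n_bins
    incr_minus = np.asarray(incr_minus, dtype=float)
    incr_plus = np.asarray(incr_plus, dtype=float)
    if incr_minus.shape != (k - 1,) or incr_plus.shape != (k - 1,):
        raise ValueError("need n_bins-1 criterion increments per response side")
    if np.any(incr_minus <= 0) or np.any(incr_plus <= 0):
        return -np.inf
    meta_c = c_prime * meta_d
    # full ordered cut points: -inf < t-_{k-1} < ... < t-_1 < meta_c
    #                                 < t+_1 < ... < t+_{k-1} < +inf
    t_minus = meta_c - np.cumsum(incr_minus)     # nearest-to-farthest
    t_plus = meta_c + np.cumsum(incr_plus)
    cuts = np.concatenate(
        [[-np.inf], t_minus[::-1], [meta_c], t_plus, [np.inf]]
    )
    ll = 0.0
    tiny = 1e-300
    for s_idx, s in enumerate((-1, 1)):
        mu = s * meta_d / 2.0
        cdf = norm.cdf(cuts - mu)
        region = np.diff(cdf)                    # 2k regions, low to high
        p_resp_minus = max(cdf[k], tiny)         # P(x < meta_c | stim)
        p_resp_plus = max(1.0 - cdf[k], tiny)
        # response -1: regions 0..k-1 are conf k..1 (farthest = most confident)
        p_minus = region[:k][::-1] / p_resp_minus   # conf 1..k
        # response +1: regions k..2k-1 are conf 1..k
        p_plus = region[k:] / p_resp_plus
        ll += np.sum(counts.counts[s_idx, 0] * np.log(np.maximum(p_minus, tiny)))
        ll += np.sum(counts.counts[s_idx, 1] * np.log(np.maximum(p_plus, tiny)))
    return float(ll)


def fit_meta_d(counts: Type2Counts, padding: bool = True) -> MetaDFit:
    """Fit meta-d' to type-2 counts by maximum likelihood.

    Type-1 d' and criterion come from the marginal counts under the
    equal-variance Gaussian model.  meta-d' and the 2*(n_bins-1) type-2
    criteria then maximize the multinomial likelihood of the
    response-conditional confidence counts for a meta-level observer whose
    type-1 criterion is rescaled by meta-d'/d' (constant relative criterion
    c' = c/d').

    A constant 1/(2*n_bins) is added to every cell before fitting
    (``padding=True``) to avoid 0/1 rates at realistic trial counts.
    """
    k = counts.n_bins
    padded = Type2Counts(counts.counts + (1.0 / (2 * k) if padding else 0.0))
    if counts.counts[:, 0].sum() < 1 or counts.counts[:, 1].sum() < 1:
        raise ValueError("both response columns need at least one trial")
    d1, c1 = _type1_estimates(padded.counts)
    if abs(d1) < 1e-8:
        return MetaDFit(
            d_prime=d1, type1_criterion=c1, meta_d=np.nan, m_ratio=np.nan,
            type2_criteria=np.full((2, k - 1), np.nan),
            log_likelihood=np.nan, converged=False,
            message="type-1 d' is 0; M-ratio undefined",
        )
    c_prime = c1 / d1

    def negll(x):
        meta_d = x[0]
        incr = np.exp(np.clip(x[1:], -30, 30))
        return -type2_loglik(padded, meta_d, c_prime, incr[: k - 1], incr[k - 1:])

    best = None
    for start_scale in (1.0, 0.5):
        x0 = np.concatenate([[d1 * start_scale], np.log(np.full(2 * (k - 1), 0.4))])
        res = optimize.minimize(
            negll, x0, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    meta_d = float(best.x[0])
    incr = np.exp(best.x[1:])
    meta_c = c_prime * meta_d
    t_minus = (meta_c - np.cumsum(incr[: k - 1]))[::-1]  # ascending
    t_plus = meta_c + np.cumsum(incr[k - 1:])
    return MetaDFit(
        d_prime=float(d1),
        type1_criterion=float(c1),
        meta_d=meta_d,
        m_ratio=meta_d / d1,
        type2_criteria=np.vstack([t_minus, t_plus]),
        log_likelihood=float(-best.fun),
        converged=bool(best.success),
        message=best.message,
    )


# --------------------------------------------------------------------------
# regression-based metacognitive sensitivity
# --------------------------------------------------------------------------

@dataclass
class SensitivityFit:
    """Two-stage logistic-regression sensitivity fit.

    ``per_subject`` holds one row per usable subject with the four logistic
    coefficients (intercept, confidence slope, condition effect,
    confidence x condition interaction).  ``group`` maps each term to
    ``(estimate, se, p)`` from a one-sample t test across subjects.
    """

    per_subject: pd.DataFrame
    group: dict[str, tuple[float, float, float]]
    dropped_subjects: list = field(default_factory=list)

    @property
    def slope(self) -> tuple[float, float, float]:
        return self.group["confidence"]

    @property
    def interaction(self) -> tuple[float, float, float]:
        return self.group["confidence:condition"]


_TERMS = ["intercept", "confidence", "condition", "confidence:condition"]


def _fit_subject_logit(acc, conf, cond) -> np.ndarray | None:
    """One subject's logistic fit; None if degenerate or separated."""
    sd = conf.std()
    if sd == 0 or acc.min() == acc.max():
        return None
    conf_z = (conf - conf.mean()) / sd
    x = np.column_stack([np.ones_like(conf_z), conf_z, cond, conf_z * cond])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(acc, x).fit(disp=0, maxiter=200)
        except (np.linalg.LinAlgError, ValueError, Exception):
            return None
    params = np.asarray(res.params)
    if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 15:
        return None  # (quasi-)separation
    return params


def fit_sensitivity(
    trials: pd.DataFrame,
    accuracy: str = "accuracy",
    confidence: str = "confidence",
    condition: str = "condition",
    subject: str = "subject_id",
    min_subjects: int = 5,
) -> SensitivityFit:
    """Metacognitive sensitivity via per-subject logistic fits + group tests.

    Per subject, fits ``accuracy ~ confidence * condition`` with confidence
    standardized within subject and the two condition levels coded -/+0.5
    (so the confidence coefficient is the slope at the average condition).
    Group estimates, SEs, and two-sided p values come from one-sample
    t tests of the subject coefficients against 0.

    Subjects with degenerate confidence, constant accuracy, a single
    condition, or (quasi-)separated fits are dropped with a warning; fewer
    than ``min_subjects`` usable subjects is an error.
    """
    levels = np.sort(trials[condition].unique())
    if levels.size != 2:
        raise ValueError(f"need exactly 2 condition levels, got {list(levels)}")
    cond_code = trials[condition].map({levels[0]: -0.5, levels[1]: 0.5}).to_numpy()

    rows, dropped = [], []
    for sid, idx in trials.groupby(subject).groups.items():
        sub = trials.loc[idx]
        cond = cond_code[trials.index.get_indexer(idx)]
        if np.unique(cond).size < 2:
            dropped.append(sid)
            continue
        params = _fit_subject_logit(
            sub[accuracy].to_numpy(dtype=float),
            sub[confidence].to_numpy(dtype=float),
            cond,
        )
        if params is None:
            dropped.append(sid)
            continue
        rows.append({subject: sid, **dict(zip(_TERMS, params))})
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} subjects from sensitivity fit: {dropped}",
            stacklevel=2,
        )
    if len(rows) < min_subjects:
        raise ValueError(
            f"only {len(rows)} usable subjects (< {min_subjects}); cannot fit"
        )
    per_subject = pd.DataFrame(rows)
    group = {}
    for term in _TERMS:
        vals = per_subject[term].to_numpy()
        t = stats.ttest_1samp(vals, 0.0)
        group[term] = (
            float(vals.mean()),
            float(vals.std(ddof=1) / np.sqrt(len(vals))),
            float(t.pvalue),
        )
    return SensitivityFit(per_subject=per_subject, group=group, dropped_subjects=dropped)
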