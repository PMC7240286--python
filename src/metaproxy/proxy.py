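"""Covert-response proxy from continuous-report traces.

When no overt 2AFC response is collected, the covert decision is inferred
as the percept whose key was held down longest during the 5-s continuous
report.  This module builds that proxy, quantifies how often it matches
overt responses where both exist, extracts per-trial trace features, and
compares logistic models of response predictability with and without the
proxy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .task_sim import decode_trace, interval_schedule

__all__ = [
    "CRFeatures",
    "proxy_response",
    "add_proxy_column",
    "correspondence",
    "extract_cr_features",
    "predictability_comparison",
]


def _as_trace(trace) -> list[tuple[int, float, float]]:
    return decode_trace(trace) if isinstance(trace, str) else list(trace)


def proxy_response(trace) -> tuple[int | None, str]:
    """Infer the covert 2AFC response as the longest-pressed key.

    ``trace`` is a list of ``(key, onset, offset)`` segments (key 0 = no
    key) or its string encoding.  Returns ``(response, status)`` where
    status is ``"ok"``, ``"tie"`` (exact tie, broken toward the
    last-pressed key) or ``"empty"`` (no keyed segment; response None).
    """
    trace = _as_trace(trace)
    pressed = {-1: 0.0, 1: 0.0}
    last_key = None
    for key, on, off in trace:
        if key in pressed:
            pressed[key] += off - on
            last_key = key
    if last_key is None or (pressed[-1] == 0.0 and pressed[1] == 0.0):
        return None, "empty"
    if pressed[-1] == pressed[1]:
        return last_key, "tie"
    return (1 if pressed[1] > pressed[-1] else -1), "ok"


def add_proxy_column(trials: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with ``proxy`` and ``proxy_status`` columns from ``cr_trace``."""
    out = trials.copy()
    res = [proxy_response(t) for t in out["cr_trace"]]
    out["proxy"] = [r if r is not None else np.nan for r, _ in res]
    out["proxy_status"] = [s for _, s in res]
    return out


def correspondence(trials: pd.DataFrame) -> dict:
    """Proportion of trials where the proxy matches the overt response.

    Expects CR+R+ rows (non-empty traces, responses present).  Returns a
    dict with the pooled proportion, the per-subject proportions, and
    their mean and SD — the group-level statistic used to report
    proxy/response correspondence.
    """
    t = trials
    if t["response"].isna().any():
        raise ValueError("correspondence requires overt responses on every row")
    t = add_proxy_column(t)
    usable = t[t["proxy_status"] != "empty"]
    match = (usable["proxy"] == usable["response"]).astype(float)
    per_subject = match.groupby(usable["subject_id"]).mean()
    return {
        "pooled": float(match.mean()),
        "per_subject": per_subject,
        "mean": float(per_subject.mean()),
        "sd": float(per_subject.std(ddof=1)) if len(per_subject) > 1 else np.nan,
        "n_ties": int((t["proxy_status"] == "tie").sum()),
        "n_empty": int((t["proxy_status"] == "empty").sum()),
    }


@dataclass(frozen=True)
class CRFeatures:
    """Per-trial features of a continuous-report trace."""

    n_transitions: int
    first_stimulus: int
    last_stimulus: int
    first_key: int | None
    last_key: int | None
    time_correct_key: float
    time_incorrect_key: float
    per_interval_delays: tuple[float, float, float, float]


def extract_cr_features(trial) -> CRFeatures:
    """Extract trace features from one CR+ trial.

    ``trial`` is a mapping/Series with ``cr_trace``, ``duration_diff_s``
    and ``first_interval`` fields.  Transitions count changes between
    pressed keys (key-0 gaps do not break a run).  Correct/incorrect key
    time is measured against the stimulus actually on screen at each
    moment.  The delay for each of the four intervals is the first onset
    of the matching key at or after the interval start minus that start
    (negative = anticipation; NaN if the key never arrives).
    """
    trace = _as_trace(trial["cr_trace"])
    keyed = [(k, on, off) for k, on, off in trace if k != 0]
    if not keyed:
        raise ValueError("CR- or empty-keyed trial: no features to extract")
    schedule = interval_schedule(
        float(trial["duration_diff_s"]), int(trial["first_interval"])
    )
    keys = [k for k, _, _ in keyed]
    n_transitions = int(np.sum(np.diff(keys) != 0))

    t_correct = t_incorrect = 0.0
    for k, on, off in keyed:
        for color, start, dur in schedule:
            lo, hi = max(on, start), min(off, start + dur)
            if hi > lo:
                if k == color:
                    t_correct += hi - lo
                else:
                    t_incorrect += hi - lo

    delays = []
    for color, start, _ in schedule:
        onsets = [on for k, on, _ in keyed if k == color and on >= start]
        # allow anticipation: a press of the right key already held at start
        held = [on for k, on, off in keyed if k == color and on < start < off]
        if held:
            delays.append(held[0] - start)
        elif onsets:
            delays.append(min(onsets) - start)
        else:
            delays.append(np.nan)

    return CRFeatures(
        n_transitions=n_transitions,
        first_stimulus=schedule[0][0],
        last_stimulus=schedule[-1][0],
        first_key=keys[0],
        last_key=keys[-1],
        time_correct_key=float(t_correct),
        time_incorrect_key=float(t_incorrect),
        per_interval_delays=tuple(float(d) for d in delays),
    )


def predictability_comparison(trials: pd.DataFrame) -> dict:
    """Does the proxy predict overt responses beyond the stimulus?

    Fits two logistic models of the overt response (CR+R+ trials, subject
    fixed intercepts): ``response ~ stimulus`` and ``response ~ stimulus +
    proxy``.  Reports the likelihood-ratio chi-square (1 df), its p value,
    and the BIC difference (stimulus-only minus stimulus+proxy; positive
    favors the proxy model).
    """
    t = add_proxy_column(trials)
    t = t[(t["proxy_status"] != "empty") & t["response"].notna()]
    if len(t) < 100:
        raise ValueError("need at least 100 usable trials")
    y = (t["response"].to_numpy(dtype=float) > 0).astype(int)
    subj = pd.get_dummies(t["subject_id"], dtype=float).to_numpy()
    stim = t["longer_stimulus"].to_numpy(dtype=float)
    prox = t["proxy"].to_numpy(dtype=float)
    x0 = np.column_stack([subj, stim])
    x1 = np.column_stack([subj, stim, prox])

    def _fit(x):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                return sm.Logit(y, x).fit(disp=0, maxiter=200), None
            except Exception as exc:  # singular / separated fits reported
                return None, str(exc)

    res0, err0 = _fit(x0)
    res1, err1 = _fit(x1)
    if res0 is None or res1 is None:
        return {"ok": False, "error": err0 or err1}
    lr = 2.0 * (res1.llf - res0.llf)
    separated = bool(np.max(np.abs(res1.params)) > 15)
    return {
        "ok": True,
        "lr_chi2": float(lr),
        "p_value": float(stats.chi2.sf(max(lr, 0.0), df=1)),
        "delta_bic": float(res0.bic - res1.bic),
        "proxy_coef": float(res1.params[-1]),
        "separated": separated,
        "n_trials": int(len(t)),
    }
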