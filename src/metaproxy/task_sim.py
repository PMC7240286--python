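"""Synthetic generator for the staircased duration-discrimination task.

Each 5-s trial shows two colored stimuli in four alternating intervals; the
two intervals of a color sum to 2.5 s plus or minus half the
staircase-controlled duration difference, and each interval is half its
color's total.  The observer judges which color was shown longer (2AFC),
and four interleaved conditions cross two manipulations:

* CR+/CR-: with/without *continuous report* — holding down one of two keys
  to track the currently visible stimulus throughout the trial;
* R+/R-: with/without an overt first-order 2AFC response after stimulus
  offset (the decision is covert in R-).

Confidence is rated in all four conditions.  Two independent 1-up/2-down
staircases (one per CR condition, updated only on R+ trials) hold
first-order accuracy near the 70.7% convergence point.

The generative model couples everything to a single trial-level SDT
evidence draw ``e = stimulus*d'/2 + eta`` with ``d' = k_sensitivity *
|duration difference|``:

* the 2AFC decision is ``sign(e)``;
* response time decreases linearly in ``|e|`` (plus Gaussian noise,
  floored), which produces the negative RT-confidence correlation seen in
  real data without any explicit accumulator;
* confidence is an affine map of ``|e + metacognitive noise|``, plus a
  small additive boost in CR+ conditions (continuous report raises
  confidence without changing accuracy);
* the continuous-report trace follows the true stimulus alternation with a
  motor tracking lag, occasional wrong-key lapses, and — crucially — a
  perceptual coupling term that shifts each tracked switch in the direction
  of the trial's evidence noise ``eta``.  The coupling makes the
  longest-pressed key informative about the *decision* beyond the stimulus,
  which is what lets a continuous-report proxy predict overt responses at
  the intermediate (~65%) rates seen empirically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import sdt_core

__all__ = [
    "StaircaseState",
    "GeneratorParams",
    "TrialRecord",
    "staircase_update",
    "run_staircase",
    "interval_schedule",
    "generate_trial",
    "simulate_session",
    "encode_trace",
    "decode_trace",
    "CONDITIONS",
]

#: the four condition combinations, (continuous report, overt response)
CONDITIONS: tuple[tuple[str, str], ...] = (
    ("CR+", "R+"), ("CR+", "R-"), ("CR-", "R+"), ("CR-", "R-"),
)

TRIAL_SECONDS = 5.0


@dataclass(frozen=True)
class StaircaseState:
    """1-up/2-down staircase over the duration difference (seconds)."""

    level: float = 0.5
    step: float = 0.05
    consecutive_correct: int = 0
    n_updates: int = 0
    floor: float = 0.01
    ceiling: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.floor <= self.level <= self.ceiling):
            raise ValueError(
                f"need 0 < floor <= level <= ceiling, got "
                f"{self.floor}/{self.level}/{self.ceiling}"
            )
        if self.step <= 0:
            raise ValueError("step must be > 0")


def staircase_update(state: StaircaseState, correct: int) -> StaircaseState:
    """Apply one 1-up/2-down update.

    Errors make the task easier (level + step) immediately; two consecutive
    correct responses make it harder (level - step).  The level is clamped
    to [floor, ceiling].  Converges where P(correct)^2 = 1/2, i.e. at
    ~70.7% accuracy.
    """
    if correct not in (0, 1, False, True):
        raise ValueError("correct must be 0 or 1")
    if correct:
        if state.consecutive_correct + 1 >= 2:
            level = max(state.level - state.step, state.floor)
            return replace(
                state, level=level, consecutive_correct=0,
                n_updates=state.n_updates + 1,
            )
        return replace(
            state,
            consecutive_correct=state.consecutive_correct + 1,
            n_updates=state.n_updates + 1,
        )
    level = min(state.level + state.step, state.ceiling)
    return replace(
        state, level=level, consecutive_correct=0,
        n_updates=state.n_updates + 1,
    )


def run_staircase(
    n_trials: int,
    rng: np.random.Generator,
    state: Optional[StaircaseState] = None,
    k_sensitivity: float = 2.2,
) -> tuple[np.ndarray, np.ndarray, StaircaseState]:
    """Drive the staircase with a simulated SDT observer.

    Per trial the observer's sensitivity is ``k_sensitivity * level`` and a
    single evidence draw decides correctness.  Returns (levels before each
    trial, accuracies, final state).
    """
    state = state or StaircaseState()
    levels = np.empty(n_trials)
    correct = np.empty(n_trials, dtype=int)
    for i in range(n_trials):
        levels[i] = state.level
        d = k_sensitivity * state.level
        e = rng.normal(d / 2.0, 1.0)  # stimulus +1 w.l.o.g.; model is symmetric
        correct[i] = int(e >= 0)
        state = staircase_update(state, correct[i])
    return levels, correct, state


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable parameters of the synthetic task generator.

    Defaults are calibrated so that a default session reproduces the
    headline statistics of the behavioral data this generator emulates:
    ~71-72% staircased accuracy, ~65% proxy/response correspondence on
    CR+R+ trials, a negative RT-confidence correlation, and slightly
    higher confidence under continuous report.
    """

    k_sensitivity: float = 2.2       # d' per second of duration difference
    tracking_lag_mean: float = 0.3   # s, mean motor lag at each tracked switch
    tracking_lag_sd: float = 0.25    # s
    lapse_rate: float = 0.08         # P(a trace segment presses the wrong key)
    percept_coupling: float = 0.08   # s of switch shift per unit evidence noise
    rt_base: float = 1.2             # s
    rt_slope: float = 0.25           # s per unit |evidence|
    rt_sd: float = 0.25              # s
    rt_floor: float = 0.2            # s
    conf_noise_sd: float = 0.5       # metacognitive noise SD (evidence units)
    conf_base: float = 5.0           # confidence-scale intercept (0-100 units)
    conf_scale: float = 30.0         # confidence units per |degraded evidence|
    cr_conf_boost: float = 4.0       # additive confidence increment in CR+
    subject_jitter_sd: float = 0.2   # lognormal sigma on per-subject params
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tracking_lag_sd", "rt_sd", "conf_noise_sd",
                     "subject_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.lapse_rate <= 1:
            raise ValueError("lapse_rate must be in [0, 1]")


@dataclass
class TrialRecord:
    """One behavioral trial."""

    subject_id: int
    condition_cr: str                 # "CR+" or "CR-"
    condition_r: str                  # "R+" or "R-"
    longer_stimulus: int              # -1 or +1
    duration_diff: float              # signed seconds; sign = longer stimulus
    first_interval: int               # stimulus shown in the first interval
    cr_trace: list                    # [(key, onset, offset)]; empty iff CR-
    response: Optional[int]           # -1/+1; None iff R-
    rt: Optional[float]               # seconds; None iff R-
    confidence_raw: float             # [0, 100], all conditions
    accuracy: Optional[int]           # 0/1; None iff R-


def interval_schedule(
    duration_diff: float, first_color: int
) -> list[tuple[int, float, float]]:
    """Four-interval schedule as ``(color, start, duration)`` triples.

    Each color's summed duration is ``2.5 + color*duration_diff/2`` and each
    of its two intervals is half that total, colors alternating starting
    with ``first_color``.
    """
    if abs(duration_diff) > TRIAL_SECONDS / 2:
        raise ValueError("|duration_diff| must be <= 2.5 s")
    if first_color not in (-1, 1):
        raise ValueError("first_color must be -1 or +1")
    totals = {c: TRIAL_SECONDS / 2 + c * duration_diff / 2 for c in (-1, 1)}
    colors = [first_color, -first_color, first_color, -first_color]
    out, t = [], 0.0
    for c in colors:
        dur = totals[c] / 2
        out.append((c, t, dur))
        t += dur
    return out


def _make_trace(
    schedule: list[tuple[int, float, float]],
    eta: float,
    p: GeneratorParams,
    rng: np.random.Generator,
) -> list[tuple[int, float, float]]:
    """Continuous-report key trace for one trial.

    The tracked switch into each interval is delayed by the motor lag plus
    Gaussian jitter, and shifted by ``percept_coupling * eta`` in the
    direction that lengthens the key matching the sign of the evidence
    noise.  Segments lapse to the wrong key with probability
    ``lapse_rate``.  Untracked time before the first key press is an
    explicit key-0 segment.
    """
    colors = [c for c, _, _ in schedule]
    bounds = [s for _, s, _ in schedule] + [TRIAL_SECONDS]
    # onset of tracking interval i: boundary + lag; the coupling shifts the
    # switch *out of* interval i-1 (delaying it lengthens that key).
    times = np.empty(4)
    for i in range(4):
        lag = p.tracking_lag_mean + rng.normal(0.0, p.tracking_lag_sd)
        left = colors[i - 1] if i > 0 else -colors[0]
        times[i] = bounds[i] + lag + p.percept_coupling * eta * left
    times = np.maximum.accumulate(np.clip(times, 0.0, TRIAL_SECONDS))
    keys = [
        -c if rng.random() < p.lapse_rate else c for c in colors
    ]
    segments: list[tuple[int, float, float]] = []
    if times[0] > 0:
        segments.append((0, 0.0, float(times[0])))
    ends = list(times[1:]) + [TRIAL_SECONDS]
    for key, start, end in zip(keys, times, ends):
        if end > start:
            segments.append((int(key), float(start), float(end)))
    return segments


def generate_trial(
    params: GeneratorParams,
    state: StaircaseState,
    condition: tuple[str, str],
    rng: np.random.Generator,
    subject_id: int = 0,
) -> TrialRecord:
    """Generate one trial at the staircase's current duration difference."""
    cr, r = condition
    if cr not in ("CR+", "CR-") or r not in ("R+", "R-"):
        raise ValueError(f"unknown condition {condition!r}")
    stim = int(rng.choice((-1, 1)))
    diff = stim * state.level
    first = int(rng.choice((-1, 1)))
    schedule = interval_schedule(diff, first)

    d_trial = params.k_sensitivity * state.level
    observer = sdt_core.SimObserver(d_prime=d_trial)
    e = float(sdt_core.draw_evidence(stim, observer, rng))
    eta = e - stim * d_trial / 2.0
    e_deg = float(sdt_core.degrade_evidence(e, params.conf_noise_sd, rng))
    decision = sdt_core.decide(e)
    accuracy = int(decision == stim)

    trace = _make_trace(schedule, eta, params, rng) if cr == "CR+" else []

    if r == "R+":
        response: Optional[int] = decision
        rt = max(
            params.rt_floor,
            params.rt_base - params.rt_slope * abs(e)
            + rng.normal(0.0, params.rt_sd),
        )
    else:
        response, rt, accuracy = None, None, None

    conf = params.conf_base + params.conf_scale * abs(e_deg)
    if cr == "CR+":
        conf += params.cr_conf_boost
    conf = float(np.clip(conf, 0.0, 100.0))

    return TrialRecord(
        subject_id=subject_id,
        condition_cr=cr,
        condition_r=r,
        longer_stimulus=stim,
        duration_diff=diff,
        first_interval=first,
        cr_trace=trace,
        response=response,
        rt=rt,
        confidence_raw=conf,
        accuracy=accuracy,
    )


def encode_trace(trace: list[tuple[int, float, float]]) -> str:
    """Serialize a trace as semicolon-separated ``key:onset:offset`` triples."""
    return ";".join(f"{k}:{on:.4f}:{off:.4f}" for k, on, off in trace)


def decode_trace(s: str) -> list[tuple[int, float, float]]:
    """Inverse of :func:`encode_trace`; empty string -> empty trace."""
    if not s:
        return []
    out = []
    for part in s.split(";"):
        k, on, off = part.split(":")
        out.append((int(k), float(on), float(off)))
    return out


def _jittered(params: GeneratorParams, rng: np.random.Generator) -> GeneratorParams:
    """Per-subject lognormal jitter on sensitivity and metacognitive noise."""
    s = params.subject_jitter_sd
    return replace(
        params,
        k_sensitivity=params.k_sensitivity * float(rng.lognormal(0.0, s)),
        conf_noise_sd=params.conf_noise_sd * float(rng.lognormal(0.0, s)),
    )


def _record_to_row(t: TrialRecord) -> dict:
    return {
        "subject_id": t.subject_id,
        "condition_cr": t.condition_cr,
        "condition_r": t.condition_r,
        "longer_stimulus": t.longer_stimulus,
        "duration_diff_s": t.duration_diff,
        "first_interval": t.first_interval,
        "cr_trace": encode_trace(t.cr_trace),
        "response": np.nan if t.response is None else t.response,
        "rt_s": np.nan if t.rt is None else t.rt,
        "confidence_raw": t.confidence_raw,
        "accuracy": np.nan if t.accuracy is None else t.accuracy,
    }


def simulate_session(
    params: Optional[GeneratorParams] = None,
    n_subjects: int = 23,
    trials_per_condition: int = 60,
    pre_staircase_trials: int = 25,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate a full multi-subject session.

    Per subject: parameters are jittered, two pre-experiment staircases
    (one per CR condition, ``pre_staircase_trials`` trials each, no
    confidence ratings, levels carried over) set the starting difficulty,
    then ``4 * trials_per_condition`` main trials run in a randomized
    interleaved order.  Each CR condition's staircase is updated only on
    its own R+ trials.

    Returns one row per main trial in the trial-table schema.
    """
    if n_subjects < 1 or trials_per_condition < 1:
        raise ValueError("counts must be positive")
    params = params or GeneratorParams()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    rows = []
    for sid in range(1, n_subjects + 1):
        p = _jittered(params, rng)
        stairs = {"CR+": StaircaseState(), "CR-": StaircaseState()}
        for cr in ("CR+", "CR-"):
            _, _, stairs[cr] = run_staircase(
                pre_staircase_trials, rng, stairs[cr], p.k_sensitivity
            )
        conditions = [c for c in CONDITIONS for _ in range(trials_per_condition)]
        rng.shuffle(conditions)
        for cond in conditions:
            cr, r = cond
            trial = generate_trial(p, stairs[cr], cond, rng, subject_id=sid)
            if r == "R+":
                stairs[cr] = staircase_update(stairs[cr], trial.accuracy)
            rows.append(_record_to_row(trial))
    return pd.DataFrame(rows)
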