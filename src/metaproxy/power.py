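"""Monte Carlo power analysis for detecting M-ratio differences.

The design question: two within-subject conditions are expected to differ
in metacognitive efficiency (M-ratio).  The analysis regresses accuracy on
confidence, condition, and their interaction; a significant interaction is
the detection event.  When the first-order response is not observed
directly but inferred through a noisy proxy, accuracy itself is measured
with error — how much power does that cost?

Each grid cell fixes a pair of target M-ratios.  Per simulated experiment,
every subject contributes ``n_trials_per_condition`` SDT trials per
condition (evidence, decision, noisy proxy, degraded-evidence confidence),
and the two-stage logistic sensitivity fit is run twice: once scoring
accuracy against actual decisions and once against proxy decisions.  Power
is the fraction of experiments with interaction p < alpha.  On the
diagonal (equal M-ratios) the interaction is null, so the "power" there is
the realized type-I error rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metacog, sdt_core

__all__ = [
    "PowerGridConfig",
    "resolve_meta_sigmas",
    "simulate_experiment",
    "experiment_pvalues",
    "estimate_power",
    "power_difference",
]

DEFAULT_M_RATIOS = tuple(np.round(np.arange(0.2, 2.01, 0.2), 1))


@dataclass(frozen=True)
class PowerGridConfig:
    """Configuration of the power grid."""

    m_ratio_values: tuple = DEFAULT_M_RATIOS
    n_experiments: int = 250
    n_subjects: int = 23
    n_trials_per_condition: int = 80
    proxy_sigma: float = sdt_core.DEFAULT_PROXY_SIGMA
    d_prime: float = sdt_core.DEFAULT_D_PRIME
    alpha: float = 0.05
    seed: int = 0
    calibration_trials: int = 50_000

    def __post_init__(self) -> None:
        if min(self.n_experiments, self.n_subjects,
               self.n_trials_per_condition) < 1:
            raise ValueError("counts must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if any(not m > 0 for m in self.m_ratio_values):
            raise ValueError("m_ratio values must be > 0")


def resolve_meta_sigmas(
    config: PowerGridConfig, rng: np.random.Generator
) -> dict[float, float]:
    """Calibrate one metacognitive-noise SD per distinct target M-ratio."""
    return {
        float(m): sdt_core.meta_sigma_for_m_ratio(
            float(m), config.d_prime, rng, n_trials=config.calibration_trials
        )
        for m in sorted(set(config.m_ratio_values))
    }


def simulate_experiment(
    m_ratio_pair: tuple[float, float],
    config: PowerGridConfig,
    rng: np.random.Generator,
    meta_sigmas: dict[float, float],
) -> pd.DataFrame:
    """Simulate one two-condition experiment as a trial table.

    Returns ``2 * n_subjects * n_trials_per_condition`` rows with columns
    subject_id, condition ("A"/"B"), accuracy, proxy_accuracy, confidence.
    All subjects share the configured d'.
    """
    frames = []
    for label, target in zip(("A", "B"), m_ratio_pair):
        observer = sdt_core.SimObserver(
            d_prime=config.d_prime,
            proxy_sigma=config.proxy_sigma,
            meta_sigma=meta_sigmas[float(target)],
            target_m_ratio=float(target),
        )
        for sid in range(1, config.n_subjects + 1):
            t = sdt_core.simulate_trials(
                config.n_trials_per_condition, observer, rng
            )
            frames.append(pd.DataFrame({
                "subject_id": sid,
                "condition": label,
                "accuracy": t.accuracy,
                "proxy_accuracy": t.proxy_accuracy,
                "confidence": t.confidence,
            }))
    return pd.concat(frames, ignore_index=True)


def experiment_pvalues(
    trials: pd.DataFrame, min_subjects: int = 5
) -> tuple[float, float]:
    """Interaction p values for the actual- and proxy-scored analyses."""
    p_actual = metacog.fit_sensitivity(
        trials, accuracy="accuracy", min_subjects=min_subjects
    ).interaction[2]
    p_proxy = metacog.fit_sensitivity(
        trials, accuracy="proxy_accuracy", min_subjects=min_subjects
    ).interaction[2]
    return p_actual, p_proxy


def _cell_power(
    pair: tuple[float, float],
    config: PowerGridConfig,
    rng: np.random.Generator,
    meta_sigmas: dict[float, float],
) -> dict:
    hits_actual = hits_proxy = n_failed = 0
    n_ok = 0
    for _ in range(config.n_experiments):
        trials = simulate_experiment(pair, config, rng, meta_sigmas)
        try:
            p_a, p_p = experiment_pvalues(trials)
        except ValueError:
            n_failed += 1
            continue
        n_ok += 1
        hits_actual += p_a < config.alpha
        hits_proxy += p_p < config.alpha
    return {
        "m_ratio_a": pair[0],
        "m_ratio_b": pair[1],
        "power_actual": hits_actual / n_ok if n_ok else np.nan,
        "power_proxy": hits_proxy / n_ok if n_ok else np.nan,
        "n_experiments": n_ok,
        "n_failed": n_failed,
        "flagged": n_failed > 0.2 * config.n_experiments,
    }


def estimate_power(
    config: PowerGridConfig,
    pairs: list[tuple[float, float]] | None = None,
    meta_sigmas: dict[float, float] | None = None,
    progress=None,
) -> pd.DataFrame:
    """Estimate the power grid.

    By default evaluates every ordered pair of ``config.m_ratio_values``;
    ``pairs`` restricts the computation to a subset of cells.  Each cell
    gets an independent seeded stream derived from ``config.seed``, so any
    subset reproduces bit-exactly.  Cells where more than 20% of
    experiments fail to fit are flagged.
    """
    rng = np.random.default_rng(config.seed)
    if meta_sigmas is None:
        meta_sigmas = resolve_meta_sigmas(config, rng)
    values = [float(m) for m in config.m_ratio_values]
    if pairs is None:
        pairs = [(a, b) for a in values for b in values]
    rows = []
    for i, pair in enumerate(pairs):
        # per-cell stream keyed by the pair, independent of evaluation order
        key = (config.seed, int(round(pair[0] * 1000)),
               int(round(pair[1] * 1000)))
        cell_rng = np.random.default_rng(key)
        rows.append(_cell_power(tuple(pair), config, cell_rng, meta_sigmas))
        if progress is not None:
            progress(i + 1, len(pairs))
    return pd.DataFrame(rows)


def power_difference(grid: pd.DataFrame) -> pd.DataFrame:
    """Per-cell ``power_actual - power_proxy`` with binomial SEs."""
    out = grid.copy()
    n = out["n_experiments"].to_numpy(dtype=float)
    se = np.sqrt(
        out["power_actual"] * (1 - out["power_actual"]) / n
        + out["power_proxy"] * (1 - out["power_proxy"]) / n
    )
    out["power_diff"] = out["power_actual"] - out["power_proxy"]
    out["diff_se"] = se
    return out
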