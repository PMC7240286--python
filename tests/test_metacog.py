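"""Tests of the measurement stack: scaling, binning, type-2 counts,
meta-d' MLE, and the two-stage sensitivity regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaproxy import metacog, sdt_core
from metaproxy.metacog import (
    Type2Counts,
    bin_confidence,
    fit_meta_d,
    fit_sensitivity,
    scale_confidence,
    tally_type2,
    type2_loglik,
)


class TestScaleConfidence:
    def test_affine_map(self):
        scaled, flag = scale_confidence([20, 60, 100])
        assert not flag
        assert scaled.tolist() == [0.0, 0.5, 1.0]

    def test_degenerate_all_equal(self):
        scaled, flag = scale_confidence([7, 7, 7])
        assert flag
        assert scaled.tolist() == [0.5, 0.5, 0.5]

    def test_too_few_ratings(self):
        with pytest.raises(ValueError):
            scale_confidence([3.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(0, 100, allow_nan=False), min_size=2, max_size=40
        ).filter(lambda xs: max(xs) > min(xs))
    )
    def test_range_and_order_preserved(self, xs):
        scaled, flag = scale_confidence(xs)
        assert not flag
        assert scaled.min() == 0.0 and scaled.max() == 1.0
        assert np.all(np.diff(scaled[np.argsort(xs, kind="stable")]) >= 0)


class TestBinConfidence:
    @pytest.mark.parametrize(
        "x, expected", [(0.0, 1), (0.249999, 1), (0.25, 2), (0.5, 3),
                        (0.75, 4), (1.0, 4)]
    )
    def test_half_open_equal_width_bins(self, x, expected):
        assert bin_confidence(np.array([x]))[0] == expected

    def test_monotone_and_idempotent_under_rescaling(self, rng):
        """Binning after re-scaling already-scaled values is unchanged."""
        x = rng.uniform(size=500)
        x[0], x[1] = 0.0, 1.0  # pin the range
        b1 = bin_confidence(x)
        rescaled, _ = scale_confidence(x)
        assert np.array_equal(b1, bin_confidence(rescaled))
        order = np.argsort(x)
        assert np.all(np.diff(b1[order]) >= 0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bin_confidence([1.2])


class TestTallyType2:
    def test_single_cell(self):
        c = tally_type2([1] * 10, [1] * 10, [4] * 10)
        assert c.counts[1, 1, 3] == 10
        assert c.n_trials == 10

    def test_totals_conserved(self, rng):
        n = 500
        stim = rng.choice([-1, 1], n)
        resp = rng.choice([-1, 1], n)
        bins = rng.integers(1, 5, n)
        c = tally_type2(stim, resp, bins)
        assert c.n_trials == n
        acc = c.counts[0, 0].sum() + c.counts[1, 1].sum()
        assert acc == np.sum(stim == resp)

    def test_empty_input(self):
        c = tally_type2([], [], [])
        assert c.n_trials == 0

    def test_missing_responses_rejected(self):
        with pytest.raises(ValueError, match="2 trials"):
            tally_type2([1, 1, -1], [1, np.nan, 0], [1, 2, 3])


class TestFitMetaD:
    def _counts_from_sim(self, meta_sigma, n, seed, target=1.0):
        rng = np.random.default_rng(seed)
        obs = sdt_core.SimObserver(meta_sigma=meta_sigma,
                                   target_m_ratio=target)
        t = sdt_core.simulate_trials(n, obs, rng)
        scaled, _ = scale_confidence(t.confidence)
        return tally_type2(t.stimulus, t.decision, bin_confidence(scaled))

    def test_lossless_confidence_recovers_m_ratio_1(self):
        """With confidence = |evidence|, meta-d' equals d' (M-ratio ~ 1)."""
        counts = self._counts_from_sim(0.0, 100_000, seed=21)
        fit = fit_meta_d(counts)
        assert fit.converged
        assert fit.m_ratio == pytest.approx(1.0, abs=0.05)

    def test_shuffled_confidence_gives_zero_meta_d(self):
        """Shuffling confidence bins within response destroys all type-2
        information, so meta-d' drops to ~0 while d' is unchanged."""
        counts = self._counts_from_sim(0.0, 100_000, seed=22)
        rng = np.random.default_rng(0)
        shuffled = counts.counts.copy()
        for r in (0, 1):
            col = shuffled[:, r, :].sum(axis=0)      # pooled over stimulus
            tot = shuffled[:, r, :].sum(axis=1)
            p = col / col.sum()
            shuffled[0, r, :] = tot[0] * p
            shuffled[1, r, :] = tot[1] * p
        fit = fit_meta_d(Type2Counts(shuffled))
        assert abs(fit.meta_d) < 0.08
        assert fit.d_prime == pytest.approx(1.107, abs=0.05)

    def test_optimum_beats_brute_force_grid(self):
        """The MLE solution's likelihood dominates a coarse scan of
        meta-d' in [-1, 3] (type-2 criteria increments held at the
        optimum)."""
        counts = self._counts_from_sim(0.8, 20_000, seed=23)
        fit = fit_meta_d(counts)
        padded = Type2Counts(counts.counts + 1.0 / 8)
        c_prime = fit.type1_criterion / fit.d_prime
        meta_c = c_prime * fit.meta_d
        incr_minus = -np.diff(
            np.concatenate([[meta_c], fit.type2_criteria[0][::-1]])
        )
        incr_plus = np.diff(
            np.concatenate([[meta_c], fit.type2_criteria[1]])
        )
        ll_opt = type2_loglik(padded, fit.meta_d, c_prime,
                              incr_minus, incr_plus)
        assert ll_opt == pytest.approx(fit.log_likelihood, abs=1e-6)
        for m in np.arange(-1.0, 3.0, 0.01):
            assert ll_opt >= type2_loglik(
                padded, m, c_prime, incr_minus, incr_plus
            ) - 1e-9

    def test_pooling_identical_conditions_changes_nothing(self):
        """Counts from two generatively identical conditions give
        M-ratios equal up to Monte Carlo error."""
        a = self._counts_from_sim(0.5, 60_000, seed=24)
        b = self._counts_from_sim(0.5, 60_000, seed=25)
        fa, fb = fit_meta_d(a), fit_meta_d(b)
        assert fa.m_ratio == pytest.approx(fb.m_ratio, abs=0.08)

    def test_type2_criteria_ordered_outward(self):
        counts = self._counts_from_sim(0.5, 30_000, seed=26)
        fit = fit_meta_d(counts)
        meta_c = fit.meta_d * fit.type1_criterion / fit.d_prime
        assert np.all(np.diff(fit.type2_criteria[0]) > 0)
        assert fit.type2_criteria[0][-1] < meta_c < fit.type2_criteria[1][0]
        assert np.all(np.diff(fit.type2_criteria[1]) > 0)

    def test_zero_d_prime_flagged(self):
        counts = Type2Counts(np.full((2, 2, 4), 10.0))
        fit = fit_meta_d(counts)
        assert not fit.converged
        assert np.isnan(fit.m_ratio)

    def test_empty_response_column_rejected(self):
        c = np.zeros((2, 2, 4))
        c[:, 1, :] = 5
        with pytest.raises(ValueError):
            fit_meta_d(Type2Counts(c))


def _two_condition_table(rng, m_ratios=(1.0, 1.0), n_subjects=12,
                         n_trials=80, shuffle_confidence=False):
    sigmas = {
        m: sdt_core.meta_sigma_for_m_ratio(m, sdt_core.DEFAULT_D_PRIME, rng,
                                           n_trials=20_000)
        for m in set(m_ratios)
    }
    frames = []
    for cond, m in zip(("A", "B"), m_ratios):
        obs = sdt_core.SimObserver(meta_sigma=sigmas[m], target_m_ratio=m)
        for sid in range(n_subjects):
            t = sdt_core.simulate_trials(n_trials, obs, rng)
            conf = t.confidence.copy()
            if shuffle_confidence:
                rng.shuffle(conf)
            frames.append(pd.DataFrame({
                "subject_id": sid, "condition": cond,
                "accuracy": t.accuracy, "confidence": conf,
            }))
    return pd.concat(frames, ignore_index=True)


class TestFitSensitivity:
    def test_null_confidence_gives_null_slope(self, rng):
        """Confidence shuffled within subject: group slope within 2 SE of 0."""
        table = _two_condition_table(rng, shuffle_confidence=True)
        fit = fit_sensitivity(table)
        est, se, _ = fit.slope
        assert abs(est) < 2 * se + 1e-12

    def test_equal_m_ratios_positive_slope_null_interaction(self, rng):
        table = _two_condition_table(rng, m_ratios=(1.0, 1.0))
        fit = fit_sensitivity(table)
        s_est, s_se, s_p = fit.slope
        assert s_est > 0 and s_p < 0.01
        i_est, i_se, _ = fit.interaction
        assert abs(i_est) < 2 * i_se + 1e-12

    def test_affine_confidence_invariance(self, rng):
        """Subject-wise affine rescaling of confidence leaves the fit
        unchanged (confidence is standardized within subject)."""
        table = _two_condition_table(rng, n_subjects=8)
        fit1 = fit_sensitivity(table)
        table2 = table.copy()
        for sid, idx in table2.groupby("subject_id").groups.items():
            table2.loc[idx, "confidence"] = (
                3.0 * (sid + 1) * table2.loc[idx, "confidence"] + 10 * sid
            )
        fit2 = fit_sensitivity(table2)
        assert fit1.slope[0] == pytest.approx(fit2.slope[0], rel=1e-6)
        assert fit1.interaction[2] == pytest.approx(fit2.interaction[2],
                                                    rel=1e-6)

    def test_too_few_subjects_rejected(self, rng):
        table = _two_condition_table(rng, n_subjects=3)
        with pytest.raises(ValueError, match="usable subjects"):
            fit_sensitivity(table)

    def test_separated_subject_dropped(self, rng):
        table = _two_condition_table(rng, n_subjects=8)
        # one subject with accuracy perfectly predicted by confidence
        sep = table[table.subject_id == 0].copy()
        sep["subject_id"] = 99
        sep["accuracy"] = (sep["confidence"]
                           > sep["confidence"].median()).astype(int)
        with pytest.warns(UserWarning, match="dropped"):
            fit = fit_sensitivity(pd.concat([table, sep],
                                            ignore_index=True))
        assert 99 in fit.dropped_subjects
        assert len(fit.per_subject) == 8

    def test_needs_two_condition_levels(self, rng):
        table = _two_condition_table(rng, n_subjects=6)
        with pytest.raises(ValueError, match="condition levels"):
            fit_sensitivity(table[table.condition == "A"])
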