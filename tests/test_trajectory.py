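"""Stage-2 trajectory classifier: ANOVA ranking, consensus set, cascade."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as _stats

from ledgaze.features import describe_feature
from ledgaze.trajectory import (
    CONSENSUS_FEATURE_IDS,
    anova_f,
    anova_rank,
    consensus_features,
    overall_system_accuracy,
    run_cascade,
    top_k_curve,
)


class TestAnova:
    def test_matches_sum_of_squares_oracle(self, rng):
        """F equals the explicit SSB/SSW decomposition (and scipy) to 1e-8."""
        X = np.column_stack([
            np.concatenate([rng.normal(0, 1, 50), rng.normal(10, 1, 50)]),
            rng.standard_normal(100),
        ])
        y = np.array([0] * 50 + [1] * 50)
        F = anova_f(X, y)
        # independent oracle: textbook two-group decomposition, scalar loops
        for j in range(2):
            groups = [X[y == g, j] for g in (0, 1)]
            grand = X[:, j].mean()
            ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            f_oracle = (ssb / 1) / (ssw / 98)
            assert F[j] == pytest.approx(f_oracle, abs=1e-8)
        # cross-check against the library implementation
        scipy_F = _stats.f_oneway(X[y == 0], X[y == 1]).statistic
        np.testing.assert_allclose(F, scipy_F, rtol=1e-10)

    def test_identical_groups_give_small_F(self, rng):
        X = rng.standard_normal((200, 5))
        y = np.array([0, 1, 2, 3] * 50)
        F = anova_f(X, y)
        crit = _stats.f.ppf(0.95, 3, 196)
        assert np.median(F) < crit

    def test_rank_is_descending(self, rng):
        X = rng.standard_normal((60, 8))
        X[:, 3] += np.repeat([0.0, 4.0], 30)  # one strong feature
        y = np.repeat([0, 1], 30)
        ranked = anova_rank(X, y)
        assert ranked.iloc[0]["feature_id"] == 4
        assert (np.diff(ranked["F"].dropna()) <= 1e-12).all()

    def test_degenerate_feature_skipped_with_warning(self, rng):
        X = np.column_stack([rng.standard_normal(40), np.repeat([1.0, 2.0], 20)])
        y = np.repeat([0, 1], 20)
        with pytest.warns(UserWarning, match="zero within-group variance"):
            ranked = anova_rank(X, y)
        assert np.isnan(ranked.iloc[-1]["F"])

    def test_needs_two_groups(self, rng):
        with pytest.raises(ValueError):
            anova_f(rng.standard_normal((10, 2)), np.zeros(10))


class TestConsensus:
    def test_default_set_resolves_to_consensus_statistics(self):
        assert len(CONSENSUS_FEATURE_IDS) == 16
        for fid in CONSENSUS_FEATURE_IDS:
            _, band, stat = describe_feature(fid)
            assert (band, stat) in {
                ("delta", "mean"), ("delta", "skewness"),
                ("theta", "trapz"), ("theta", "entropy"),
            }
        channels = {describe_feature(fid)[0] for fid in CONSENSUS_FEATURE_IDS}
        assert channels == {"AF3", "F7", "F8", "AF4"}

    def test_f8_delta_ids_in_default_set(self):
        assert 82 in CONSENSUS_FEATURE_IDS and 83 in CONSENSUS_FEATURE_IDS

    def test_single_subject_counts(self):
        ranking = pd.DataFrame({"feature_id": np.arange(1, 161)})
        counts = consensus_features([ranking], top_n=20)
        assert set(counts.unique()) == {1}
        assert len(counts) == 20

    def test_multi_subject_occurrences(self):
        a = np.arange(1, 21)
        b = np.arange(11, 31)
        counts = consensus_features([a, b], top_n=20)
        assert counts.loc[15] == 2 and counts.loc[5] == 1 and counts.loc[25] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consensus_features([])


class TestTopKCurve:
    def test_curve_shape_and_full_set_limit(self, rng):
        X = rng.standard_normal((80, 10))
        X[:, 0] += np.repeat([0.0, 3.0], 40)
        y = np.repeat([0, 1], 40)
        ranked = anova_rank(X, y)["feature_id"].to_numpy()
        curve = top_k_curve(X, y, ranked, classifier="lda", k_max=10, repeats=2, seed=0)
        assert curve.shape == (10,)
        assert curve[-1] >= curve[0] - 0.05

    def test_k_truncated_to_feature_count(self, rng):
        X = rng.standard_normal((40, 3))
        y = np.repeat([0, 1], 20)
        curve = top_k_curve(X, y, np.array([1, 2, 3]), k_max=20, repeats=2)
        assert curve.shape == (3,)


class TestOverallSystemAccuracy:
    def test_definitional_arithmetic(self):
        assert overall_system_accuracy(97, 100) == pytest.approx(0.97)
        assert overall_system_accuracy(100, 100) == 1.0

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            overall_system_accuracy(0, 0)


def _toy_cascade_data(rng, n_per_cell=10, separation=8.0):
    """Linearly separable gate and trajectory features."""
    trajectories = ["up_down", "right_left", "left_cross", "right_cross"]
    led, traj, s1, s2 = [], [], [], []
    for t_i, t in enumerate(trajectories):
        for on in (True, False):
            for _ in range(n_per_cell):
                led.append(on)
                traj.append(t)
                s1.append(rng.normal(separation if on else 0.0, 1.0, 4))
                s2.append(rng.normal(t_i * separation, 1.0, 16))
    return (np.array(s1), np.array(s2), np.array(led), np.array(traj))


class TestRunCascade:
    def test_perfect_toy_is_perfect(self, rng):
        s1, s2, led, traj = _toy_cascade_data(rng)
        res = run_cascade(s1, s2, led, traj, repeats=3, seed=0)
        assert res.stage1_overall == 1.0
        assert res.stage2_overall == 1.0
        assert res.overall_system == 1.0
        assert res.itr_bits_per_min == pytest.approx(40.0)

    def test_overall_equals_stage2_when_gate_perfect(self, rng):
        s1, s2, led, traj = _toy_cascade_data(rng, separation=8.0)
        # degrade only stage-2 features
        s2 = s2 + rng.normal(0, 6.0, s2.shape)
        res = run_cascade(s1, s2, led, traj, repeats=3, seed=0)
        assert res.stage1_overall == 1.0
        assert res.overall_system == pytest.approx(res.stage2_overall)

    def test_shuffled_labels_are_chance(self, rng):
        s1, s2, led, traj = _toy_cascade_data(rng, n_per_cell=25)
        res = run_cascade(s1, s2, led, rng.permutation(traj),
                          stage2_classifier="lda", repeats=5, seed=0)
        assert 0.1 < res.stage2_overall < 0.45

    def test_gate_rejecting_everything_errors(self, rng):
        # identical gate features with a heavy off-majority: the gate always
        # predicts non-illuminated, so nothing reaches stage 2
        trajectories = ["up_down", "right_left", "left_cross", "right_cross"]
        led = np.array([True] * 8 + [False] * 80)
        traj = np.array(trajectories * 2 + trajectories * 20)
        s1 = np.zeros((88, 4))
        s2 = rng.standard_normal((88, 16))
        with pytest.raises(RuntimeError, match="no illuminated segments"):
            run_cascade(s1, s2, led, traj, repeats=1, seed=0)

    def test_segment_count_conservation(self, rng):
        s1, s2, led, traj = _toy_cascade_data(rng)
        res = run_cascade(s1, s2, led, traj, repeats=3, seed=0)
        assert res.counts["segments_in"] == (
            res.counts["gate_passed"] + res.counts["gate_rejected"]
        )

    def test_deterministic_under_seed(self, rng):
        s1, s2, led, traj = _toy_cascade_data(rng)
        s2 = s2 + np.random.default_rng(0).normal(0, 5.0, s2.shape)
        a = run_cascade(s1, s2, led, traj, repeats=3, seed=4)
        b = run_cascade(s1, s2, led, traj, repeats=3, seed=4)
        assert a.stage2_overall == b.stage2_overall
        assert a.overall_system == b.overall_system

    def test_misaligned_inputs_rejected(self, rng):
        s1, s2, led, traj = _toy_cascade_data(rng)
        with pytest.raises(ValueError, match="aligned"):
            run_cascade(s1[:-1], s2, led, traj)


def test_frontal_low_band_features_outrank_gamma(small_tables):
    """ANOVA ranks for trajectory discrimination put delta/theta features of
    the frontal channels well ahead of gamma-band features."""
    _, s2 = small_tables
    on = s2[s2.led_on]
    f_cols = [c for c in on.columns if c.startswith("feature_")]
    ranked = anova_rank(on[f_cols].to_numpy(float), on["trajectory"].to_numpy())
    band_of = {fid: describe_feature(fid)[1] for fid in range(1, 161)}
    ranks = ranked.set_index("feature_id")["rank"]
    low = [ranks[fid] for fid in range(1, 161) if band_of[fid] in ("delta", "theta")]
    gamma = [ranks[fid] for fid in range(1, 161) if band_of[fid] == "gamma"]
    assert np.median(low) < np.median(gamma)
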