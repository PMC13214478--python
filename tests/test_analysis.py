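import numpy as np
import pandas as pd
import pytest

import srtkit as sk


def mixed_null_data(rng, n_participants=20, n_orders=24,
                    participant_sd=0.0, noise_sd=0.7, drift=0.0):
    """SRT table drawn directly from the mixed model (oracle generator)."""
    rows = []
    for pid in range(1, n_participants + 1):
        u = rng.normal(0.0, participant_sd)
        for order in range(1, n_orders + 1):
            rows.append(
                {
                    "participant_id": pid,
                    "presentation_order": order,
                    "list_id": order,
                    "is_training": order <= 2,
                    "srt_db": -5.3 + u + drift * (order - 1)
                    + rng.normal(0.0, noise_sd),
                }
            )
    return pd.DataFrame(rows)


class TestListEquivalence:
    def test_all_equal(self):
        df = pd.DataFrame(
            {
                "participant_id": [1, 2, 1, 2],
                "list_id": [1, 1, 2, 2],
                "is_training": False,
                "srt_db": -5.0,
                "presentation_order": [3, 3, 4, 4],
            }
        )
        rep = sk.list_equivalence(df)
        assert (rep.per_list["normalized_db"] == 0).all()
        assert rep.grand_sd_db == 0.0
        assert rep.max_pairwise_diff_db == 0.0

    def test_hand_computed_two_lists(self):
        df = pd.DataFrame(
            {
                "participant_id": [1, 2, 1, 2],
                "list_id": [1, 1, 2, 2],
                "is_training": False,
                "srt_db": [-5.0, -5.0, -6.0, -6.0],
                "presentation_order": [3, 3, 4, 4],
            }
        )
        rep = sk.list_equivalence(df)
        assert sorted(rep.per_list["normalized_db"]) == pytest.approx([-0.5, 0.5])
        assert rep.max_pairwise_diff_db == pytest.approx(1.0)
        assert rep.grand_mean_db == pytest.approx(-5.5)

    def test_permutation_invariance(self, small_study):
        base = sk.list_equivalence(small_study.results)
        shuffled = small_study.results.sample(frac=1.0, random_state=0)
        other = sk.list_equivalence(shuffled)
        pd.testing.assert_frame_equal(
            base.per_list.reset_index(drop=True),
            other.per_list.reset_index(drop=True),
        )

    def test_missing_list_reported_not_dropped(self, small_study):
        rep = sk.list_equivalence(
            small_study.results, expected_lists=range(1, 47)
        )
        missing = rep.per_list.loc[rep.per_list["list_id"].isin([45, 46])]
        assert (missing["n"] == 0).all()
        assert missing["mean_srt_db"].isna().all()

    def test_each_list_scored_ten_times(self, small_study):
        rep = sk.list_equivalence(small_study.results)
        assert (rep.per_list["n"] == 10).all()
        assert len(rep.per_list) == 44


class TestWithinSubject:
    def test_two_point_sd(self):
        df = pd.DataFrame(
            {
                "participant_id": [1, 1],
                "list_id": [1, 2],
                "is_training": False,
                "srt_db": [-5.0, -6.0],
                "presentation_order": [3, 4],
            }
        )
        per, avg = sk.within_subject_stats(df)
        assert avg == pytest.approx(np.sqrt(0.5))

    def test_constant_participant_sd_zero(self):
        df = pd.DataFrame(
            {
                "participant_id": [1, 1, 1],
                "list_id": [1, 2, 3],
                "is_training": False,
                "srt_db": -5.0,
                "presentation_order": [3, 4, 5],
            }
        )
        per, avg = sk.within_subject_stats(df)
        assert avg == 0.0

    def test_training_rows_excluded_by_contract(self, small_study):
        results = small_study.results
        with_flag = sk.within_subject_stats(results)
        stripped = sk.within_subject_stats(
            results.loc[~results["is_training"]]
        )
        pd.testing.assert_frame_equal(with_flag[0], stripped[0])
        assert with_flag[1] == stripped[1]

    def test_single_measurement_raises(self):
        df = pd.DataFrame(
            {
                "participant_id": [1],
                "list_id": [1],
                "is_training": False,
                "srt_db": [-5.0],
                "presentation_order": [3],
            }
        )
        with pytest.raises(ValueError):
            sk.within_subject_stats(df)

    def test_average_invariant_to_relabeling(self, small_study):
        results = small_study.results.copy()
        _, avg = sk.within_subject_stats(results)
        results["participant_id"] = 100 - results["participant_id"]
        _, avg2 = sk.within_subject_stats(results)
        assert avg == pytest.approx(avg2)


class TestTrainingEffect:
    def test_null_rarely_significant(self):
        # zero drift, zero participant variance: ~nominal type-I per replicate
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            fit = sk.training_effect(mixed_null_data(rng), include_training=True)
            hits += fit.significant
        assert hits <= 10  # >= 90% non-significant

    def test_type_one_error_bounded(self):
        # realistic null (participant heterogeneity, no drift), 500 replicates
        hits = 0
        n = 500
        for rep in range(n):
            rng = np.random.default_rng(5000 + rep)
            df = mixed_null_data(rng, participant_sd=0.5)
            hits += sk.training_effect(df).significant
        assert hits / n <= 0.08

    def test_drift_recovered_from_model_data(self):
        ests = []
        for rep in range(50):
            rng = np.random.default_rng(300 + rep)
            df = mixed_null_data(rng, participant_sd=0.5, drift=-0.02)
            ests.append(sk.training_effect(df).order_slope_db)
        assert -0.03 < np.mean(ests) < -0.01

    def test_variance_components_recovered(self):
        sd_u, sd_e = 0.5, 0.7
        var_u = []
        for rep in range(100):
            rng = np.random.default_rng(800 + rep)
            df = mixed_null_data(rng, participant_sd=sd_u, noise_sd=sd_e)
            fit = sk.training_effect(df)
            var_u.append(fit.random_intercept_var)
        assert abs(np.mean(var_u) - sd_u**2) / sd_u**2 < 0.5

    def test_ci_contains_point_estimate(self, small_study):
        fit = sk.training_effect(small_study.results)
        lo, hi = fit.order_slope_ci
        assert lo <= fit.order_slope_db <= hi
        assert fit.random_intercept_var >= 0
        assert fit.residual_var >= 0
        assert fit.df_den == fit.n_obs - 2

    def test_exclude_training_drops_rows(self, small_study):
        fit_all = sk.training_effect(small_study.results, include_training=True)
        fit_test = sk.training_effect(small_study.results, include_training=False)
        assert fit_all.n_obs == 480
        assert fit_test.n_obs == 440


class TestPosthocSlopes:
    def test_slope_recovery_from_track_trials(self, steep_list):
        # 200 tracks simulated at sentence slope 18.5 %/dB.  Pooling every
        # track's trials into one fit is a consistent estimator and must
        # recover the generating slope closely; the per-track grand average
        # is a noisy, upward-biased small-sample statistic and is only held
        # to a broad plausibility band (see the methods note).
        sentences, _ = steep_list
        listener = sk.VirtualListener(1)
        logs, pooled = {}, []
        for i in range(200):
            rng = np.random.default_rng(np.random.SeedSequence([21, i]))
            track = sk.simulate_track(sentences, listener, rng)
            logs[(1, i + 1)] = track.to_frame()
            pooled.extend(
                (p.nominal_snr_db, 3, p.k_correct) for p in track.scored()
            )
        fit = sk.fit_psychometric(pooled)
        assert fit.converged
        assert abs(fit.slope - 18.5) < 1.5

        study = sk.StudyResult(results=pd.DataFrame(), trial_logs=logs)
        per, grand, n_excluded = sk.posthoc_slopes(study)
        assert 18.5 / 2 < grand < 18.5 * 2
        assert n_excluded < 20  # the odd unfittable track is tolerated

    def test_constant_snr_track_excluded(self):
        log = pd.DataFrame(
            {
                "index": range(1, 21),
                "sentence_id": range(1, 21),
                "phase": 2,
                "nominal_snr_db": -5.0,
                "adjusted_snr_db": -5.0,
                "k_correct": [1, 2] * 10,
                "correct": True,
                "is_escalation_replay": False,
            }
        )
        study = sk.StudyResult(results=pd.DataFrame(), trial_logs={(1, 1): log})
        with pytest.raises(ValueError, match="non-convergent"):
            sk.posthoc_slopes(study)

    def test_order_invariance(self, small_study):
        per, grand, _ = sk.posthoc_slopes(small_study)
        reversed_logs = dict(reversed(list(small_study.trial_logs.items())))
        study2 = sk.StudyResult(results=small_study.results,
                                trial_logs=reversed_logs)
        _, grand2, _ = sk.posthoc_slopes(study2)
        assert grand == pytest.approx(grand2)


class TestDegenerateOracle:
    def test_mixed_equals_ols_on_balanced_data(self):
        # balanced design, no participant effect: REML fixed effects must
        # coincide with ordinary least squares
        rng = np.random.default_rng(0)
        df = mixed_null_data(rng, participant_sd=0.0, noise_sd=0.3,
                             drift=-0.05)
        fit = sk.training_effect(df)
        X = np.column_stack(
            [np.ones(len(df)), df["presentation_order"].to_numpy(float)]
        )
        beta, *_ = np.linalg.lstsq(X, df["srt_db"].to_numpy(float), rcond=None)
        assert fit.intercept_db == pytest.approx(beta[0], abs=1e-6)
        assert fit.order_slope_db == pytest.approx(beta[1], abs=1e-6)
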