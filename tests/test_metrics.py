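"""Evaluation statistics: AUC, confusion metrics, DeLong, McNemar,
uncertainty-percentile analysis, and the nested-CV harness."""

import numpy as np
import pandas as pd
import pytest

from stagedrisk import (
    CohortConfig,
    ConfigError,
    CVConfig,
    DataError,
    EnsembleConfig,
    PredictionDistribution,
    binary_metrics,
    delong,
    delong_ci,
    generate_cohort,
    mcnemar_sens_spec,
    nested_cv,
    roc_auc,
    uncertainty_percentile_auc,
)
from stagedrisk.evaluate import _delong_structural


# ---------------------------------------------------------------------------
# independent oracles


def pair_counting_auc(y, s):
    """Brute-force Mann–Whitney AUC over all (positive, negative) pairs."""
    y, s = np.asarray(y), np.asarray(s)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def delong_components_oracle(y, scores):
    """Placement values V10/V01 by definition (double loops)."""
    y = np.asarray(y)
    pos = [s[y == 1] for s in scores]
    neg = [s[y == 0] for s in scores]
    m, n = len(pos[0]), len(neg[0])
    k = len(scores)
    v10 = np.zeros((k, m))
    v01 = np.zeros((k, n))
    for r in range(k):
        for i in range(m):
            v10[r, i] = np.mean(
                [1.0 if pos[r][i] > q else (0.5 if pos[r][i] == q else 0.0)
                 for q in neg[r]]
            )
        for j in range(n):
            v01[r, j] = np.mean(
                [1.0 if p > neg[r][j] else (0.5 if p == neg[r][j] else 0.0)
                 for p in pos[r]]
            )
    aucs = v10.mean(axis=1)
    s10 = np.cov(v10, ddof=1)
    s01 = np.cov(v01, ddof=1)
    return aucs, np.atleast_2d(s10) / m + np.atleast_2d(s01) / n


# ---------------------------------------------------------------------------
# roc_auc


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_complete_tie(self):
        assert roc_auc([0, 1], [0.7, 0.7]) == 0.5

    def test_matches_pair_counting_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(5, 30)
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)  # coarse grid to exercise ties
            assert roc_auc(y, s) == pytest.approx(pair_counting_auc(y, s))

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestBinaryMetrics:
    def test_perfect_probabilities(self):
        m = binary_metrics([0, 1, 0, 1], [0.1, 0.9, 0.2, 0.8])
        assert m == {"accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0}

    def test_all_negative_predictions_on_imbalanced_cohort(self):
        y = np.array([1] * 94 + [0] * 453)
        m = binary_metrics(y, np.zeros(547))
        assert m["accuracy"] == pytest.approx(453 / 547)
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 1.0

    def test_hand_counted_instance(self):
        m = binary_metrics([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
        assert m == {"accuracy": 0.5, "sensitivity": 0.5, "specificity": 0.5}

    def test_missing_class_flagged_as_nan(self):
        m = binary_metrics([1, 1], [0.9, 0.1])
        assert np.isnan(m["specificity"]) and m["sensitivity"] == 0.5


# ---------------------------------------------------------------------------
# DeLong


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        y = [0, 1, 0, 1, 1, 0]
        s = [0.2, 0.8, 0.3, 0.7, 0.6, 0.1]
        assert delong(y, s, s) == 1.0

    def test_variance_matches_structural_components_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            y = np.array([1] * 5 + [0] * 7)
            s1 = np.round(rng.random(12), 1)
            s2 = np.round(rng.random(12), 1)
            aucs, cov = _delong_structural(y, np.vstack([s1, s2]))
            aucs_o, cov_o = delong_components_oracle(y, [s1, s2])
            np.testing.assert_allclose(aucs, aucs_o, atol=1e-12)
            np.testing.assert_allclose(cov, cov_o, atol=1e-12)

    def test_symmetric_under_model_swap(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 40)
        y[:3] = [0, 1, 1]
        s1, s2 = rng.random(40), rng.random(40)
        assert delong(y, s1, s2) == pytest.approx(delong(y, s2, s1))

    def test_ci_truncated_for_perfect_classifier(self):
        y = [0, 0, 0, 1, 1]
        s = [0.1, 0.2, 0.3, 0.8, 0.9]
        auc, lo, hi = delong_ci(y, s)
        assert auc == 1.0 and hi == 1.0 and 0.0 <= lo <= 1.0

    def test_constant_scores_degenerate(self):
        with pytest.raises(DataError):
            delong_ci([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])

    def test_detects_large_auc_difference(self):
        rng = np.random.default_rng(3)
        n = 200
        y = np.array([1] * 100 + [0] * 100)
        good = y + 0.3 * rng.standard_normal(n)
        bad = rng.standard_normal(n)
        assert delong(y, good, bad) < 0.001


# ---------------------------------------------------------------------------
# McNemar


class TestMcNemar:
    def test_identical_predictions(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        pred = np.array([1, 0, 0, 1, 1, 0])
        assert mcnemar_sens_spec(y, pred, pred) == (1.0, 1.0)

    def test_exact_binomial_tail(self):
        # among positives: A uniquely correct on 10, B never uniquely correct
        y = np.ones(12, dtype=int)
        pred1 = np.array([1] * 10 + [0, 1])
        pred2 = np.array([0] * 10 + [0, 1])
        y_full = np.concatenate([y, [0, 0]])
        p1 = np.concatenate([pred1, [0, 1]])
        p2 = np.concatenate([pred2, [0, 1]])
        p_sens, _ = mcnemar_sens_spec(y_full, p1, p2)
        assert p_sens == pytest.approx(2 * 0.5**10)

    def test_symmetric_discordance_gives_p_one(self):
        # among negatives: 3 uniquely correct each way
        y = np.zeros(8, dtype=int)
        pred1 = np.array([0, 0, 0, 1, 1, 1, 0, 1])
        pred2 = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        y_full = np.concatenate([y, [1, 1]])
        p1 = np.concatenate([pred1, [1, 0]])
        p2 = np.concatenate([pred2, [1, 0]])
        _, p_spec = mcnemar_sens_spec(y_full, p1, p2)
        assert p_spec == 1.0

    def test_large_discordance_uses_chisquare(self):
        rng = np.random.default_rng(4)
        y = np.ones(100, dtype=int)
        pred1 = np.array([1] * 40 + [0] * 60)
        pred2 = np.array([0] * 25 + [1] * 40 + [0] * 35)
        y_full = np.concatenate([y, [0]])
        p1 = np.concatenate([pred1, [0]])
        p2 = np.concatenate([pred2, [0]])
        p_sens, _ = mcnemar_sens_spec(y_full, p1, p2)
        from scipy.stats import chi2

        b, c = 25, 25  # discordant counts by construction
        stat = (abs(b - c) - 1) ** 2 / (b + c)
        assert p_sens == pytest.approx(float(chi2.sf(stat, 1)))


# ---------------------------------------------------------------------------
# uncertainty-percentile analysis


class TestUncertaintyPercentiles:
    def _dist(self, mu, sd):
        mu, sd = np.asarray(mu, float), np.asarray(sd, float)
        return PredictionDistribution(probs=mu[:, None], mu=mu, sd=sd)

    def test_zero_percentile_is_full_sample(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        mu = rng.random(60)
        curve = uncertainty_percentile_auc(y, self._dist(mu, rng.random(60)), [0])
        assert curve.loc[0, "auc"] == pytest.approx(roc_auc(y, mu))
        assert curve.loc[0, "n"] == 60

    def test_constant_uncertainty_gives_flat_curve(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        mu = rng.random(50)
        curve = uncertainty_percentile_auc(
            y, self._dist(mu, np.full(50, 0.1)), [0, 25, 50, 75]
        )
        assert curve["auc"].nunique() == 1

    def test_grid_validation(self):
        with pytest.raises(ConfigError):
            uncertainty_percentile_auc(
                [0, 1], self._dist([0.2, 0.8], [0.1, 0.1]), [100]
            )

    def test_auc_declines_with_uncertainty_on_synthetic_cohorts(self):
        """Restricting to ever-more-uncertain subsets degrades AUC:
        negative Spearman trend in >= 16 of 20 seeds."""
        from scipy.stats import spearmanr

        from stagedrisk import fit_ensemble, predict_distribution

        hits = 0
        for seed in range(20):
            c = generate_cohort(
                CohortConfig(n_subjects=300, n_positives=60, beta1=0.5,
                             beta2=1.5, seed=seed)
            )
            combined = pd.concat([c.X1, c.X2], axis=1)
            ens = fit_ensemble(combined, c.y,
                               EnsembleConfig(n_base_models=15, seed=seed))
            dist = predict_distribution(ens, combined)
            curve = uncertainty_percentile_auc(c.y, dist,
                                               np.arange(0, 90, 10))
            ok = curve.dropna(subset=["auc"])
            rho = spearmanr(ok["percentile"], ok["auc"]).statistic
            hits += rho < 0
        assert hits >= 16


# ---------------------------------------------------------------------------
# nested CV


class TestNestedCV:
    def test_fold_sizes_match_study_geometry(self):
        cohort = generate_cohort(CohortConfig(seed=0))
        cv = CVConfig(n_outer_folds=10, n_validation=45, seed=0)
        rep = nested_cv(
            cohort, cv,
            EnsembleConfig(n_base_models=3, seed=0),
            EnsembleConfig(n_base_models=3, seed=1),
        )
        assert set(rep.fold_info["n_test"]) <= {54, 55}
        assert (rep.fold_info["n_val"] == 45).all()
        # 492-ish outer-train minus the two 45-row validation sets
        assert set(rep.fold_info["n_train"]) <= {402, 403}

    def test_deterministic_under_seed(self, small_cohort):
        cv = CVConfig(n_outer_folds=3, n_validation=20, seed=5)
        kwargs = dict(
            ens1_config=EnsembleConfig(n_base_models=3, seed=5),
            ens2_config=EnsembleConfig(n_base_models=3, seed=6),
        )
        r1 = nested_cv(small_cohort, cv, **kwargs)
        r2 = nested_cv(small_cohort, cv, **kwargs)
        pd.testing.assert_frame_equal(r1.per_fold, r2.per_fold)
        assert r1.delong_pvalues == r2.delong_pvalues

    def test_strong_stage2_signal_lifts_ensemble2(self, small_cohort):
        cv = CVConfig(n_outer_folds=3, n_validation=20, seed=2)
        rep = nested_cv(
            small_cohort, cv,
            EnsembleConfig(n_base_models=5, seed=2),
            EnsembleConfig(n_base_models=5, seed=3),
        )
        avg = rep.per_fold.groupby("model")["auc"].mean()
        assert avg["ensemble2"] > avg["ensemble1"]
        # report shape: three models, AVG and STD rows, four metrics
        frame = rep.summary_frame()
        assert frame.shape == (6, 4)
        assert rep.val2_per_fold["model"].nunique() == 3

    def test_validation_too_large_rejected(self, small_cohort):
        with pytest.raises(ConfigError):
            nested_cv(small_cohort, CVConfig(n_outer_folds=3, n_validation=80))
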