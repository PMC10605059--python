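"""Noise curves, biomarker ranking, Kaplan-Meier and log-rank machinery."""

import numpy as np
import pandas as pd
import pytest

from evidentomics import (EvidentialMultiomicsClassifier, cross_validate,
                          km_estimate, logrank_test, noise_experiment,
                          rank_biomarkers, stratify_risk)
from evidentomics.experiments import km_survival_at


class TestKaplanMeier:
    def test_two_deaths_no_censoring(self):
        km = km_estimate([1.0, 2.0], [1, 1])
        assert np.isclose(km_survival_at(km, 1.0), 0.5)
        assert np.isclose(km_survival_at(km, 2.0), 0.0)

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.allclose(km.survival, 1.0)

    def test_estimate_non_increasing(self, rng):
        t = rng.exponential(2.0, size=50)
        e = rng.integers(0, 2, size=50)
        if e.sum() == 0:
            e[0] = 1
        km = km_estimate(t, e)
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert km.survival.iloc[0] == 1.0

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = rng.exponential(2.0, size=80)
        e = rng.integers(0, 2, size=80)
        e[0] = 1
        km = km_estimate(t, e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        for q in np.quantile(t, [0.1, 0.5, 0.9]):
            assert np.isclose(km_survival_at(km, q),
                              kmf.predict(q), atol=1e-9)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_statistic_zero_p_one(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 1]
        stat, p = logrank_test(t, e, t, e)
        assert stat == 0.0 and p == 1.0

    def test_hand_tabulated_four_subjects(self):
        # A: events at 1, 3; B: events at 2, 4 -- tabulate risk sets by hand
        ta, ea = [1.0, 3.0], [1, 1]
        tb, eb = [2.0, 4.0], [1, 1]
        O_E, V = 0.0, 0.0
        for t, (n1, n2, d1) in {1.0: (2, 2, 1), 2.0: (1, 2, 0),
                                3.0: (1, 1, 1), 4.0: (0, 1, 0)}.items():
            n, d = n1 + n2, 1
            if n < 2:      # a lone subject contributes no information
                continue
            O_E += d1 - d * n1 / n
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
        expected = O_E ** 2 / V
        stat, p = logrank_test(ta, ea, tb, eb)
        assert np.isclose(stat, expected, atol=1e-12)
        assert 0 < p <= 1

    def test_matches_lifelines(self, rng):
        stats_mod = pytest.importorskip("lifelines.statistics")
        ta = rng.exponential(1.0, size=40)
        tb = rng.exponential(2.0, size=35)
        ea = rng.integers(0, 2, size=40)
        eb = rng.integers(0, 2, size=35)
        ea[0] = eb[0] = 1
        res = stats_mod.logrank_test(ta, tb, event_observed_A=ea,
                                     event_observed_B=eb)
        stat, p = logrank_test(ta, ea, tb, eb)
        assert np.isclose(stat, res.test_statistic, atol=1e-8)
        assert np.isclose(p, res.p_value, atol=1e-8)

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            logrank_test([1.0], [0], [2.0], [0])


@pytest.fixture(scope="module")
def tiny_cv(small_dataset):
    ds, truth = small_dataset
    cv = cross_validate(ds, n_folds=3, seed=2, n_epochs=12)
    return ds, truth, cv


class TestNoiseExperiment:
    def test_clean_row_equals_cross_validation_exactly(self, tiny_cv):
        ds, _, cv = tiny_cv
        curve = noise_experiment(ds, cv, exponents=[0, 2], include_clean=True)
        agg = cv.aggregate()
        assert np.isclose(curve.accuracy[0], agg["accuracy"]["mean"], atol=1e-12)
        assert np.isclose(curve.uncertainty[0],
                          agg["mean_uncertainty"]["mean"], atol=1e-12)

    def test_levels_strictly_increasing_and_ci_nonnegative(self, tiny_cv):
        ds, _, cv = tiny_cv
        curve = noise_experiment(ds, cv, exponents=[0, 1, 3])
        assert np.all(np.diff(curve.levels) > 0)
        assert np.all(curve.uncertainty_ci >= 0)
        frame = curve.to_frame()
        assert list(frame.columns)[0] == "noise_sd"


class TestBiomarkers:
    def test_table_structure_and_rank_order(self, tiny_cv):
        ds, _, cv = tiny_cv
        table = rank_biomarkers(cv.models[0], ds, top_n=5).rows
        for (mod, cls), grp in table.groupby(["modality", "class"]):
            assert list(grp["rank"]) == list(range(1, len(grp) + 1))
            assert np.all(np.diff(grp["score"]) <= 1e-12)

    def test_invariant_to_sample_order(self, tiny_cv):
        ds, _, cv = tiny_cv
        table1 = rank_biomarkers(cv.models[0], ds, top_n=3).rows
        perm = list(np.random.default_rng(0).permutation(ds.sample_ids))
        table2 = rank_biomarkers(cv.models[0], ds.subset(perm), top_n=3).rows
        merged = table1.merge(table2, on=["modality", "class", "feature"],
                              suffixes=("_a", "_b"))
        assert len(merged) == len(table1)
        assert np.allclose(merged.score_a, merged.score_b, atol=1e-9)

    def test_zero_weight_feature_never_outranks(self):
        # scores are class contrasts of |W|; a feature with identically zero
        # weight scores 0 and cannot beat a positive-contrast feature
        from evidentomics.experiments import BiomarkerTable  # noqa: F401
        from evidentomics import FeatureMatrix, align_dataset

        class FakeModel:
            def gated_values(self, X):
                W = np.zeros((4, 3))
                W[:2, 0] = 0.9     # feature f0 active in class 0 only
                return [W]

        ids = ["a", "b", "c", "d"]
        m = FeatureMatrix("mrna", ids, ["f0", "f1", "f2"], np.zeros((4, 3)))
        ds = align_dataset([m], {"a": 0, "b": 0, "c": 1, "d": 1}, ["x", "y"])
        table = rank_biomarkers(FakeModel(), ds, top_n=3).rows
        top_class0 = table[(table["class"] == "x")].iloc[0]
        assert top_class0.feature == "f0" and top_class0.score > 0


class TestStratifyRisk:
    def test_median_split_balances_groups(self, survival_dataset):
        ds, _ = survival_dataset
        X, dims = ds.stacked_X()
        clf = EvidentialMultiomicsClassifier(modality_dims=dims, n_epochs=10,
                                             random_state=4)
        clf.fit(X, ds.y)
        rg = stratify_risk(clf, ds, by_class=False)
        n_high = (rg.groups == "high").sum()
        assert abs(n_high - ds.n_samples / 2) <= ds.n_samples * 0.25
        assert set(rg.groups.unique()) == {"high", "low"}
        assert ("all", "high") in rg.km_curves

    def test_identical_scores_error(self, survival_dataset):
        ds, _ = survival_dataset

        class Flat:
            def predict_opinion(self, X):
                n = X.shape[0]
                return np.full((n, 2), 0.45), np.full(n, 0.1)

        with pytest.raises(ValueError, match="identical"):
            stratify_risk(Flat(), ds)

    def test_missing_survival_errors(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(ValueError, match="survival"):
            stratify_risk(object(), ds)
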