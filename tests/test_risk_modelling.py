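"""Risk modelling: preprocessing, selectors, ensembles, leakage audit."""

import numpy as np
import pandas as pd
import pytest

from rimradiomics.evaluation import concordance_index
from rimradiomics.risk_modelling import (EnsembleModel, ModelCombo,
                                         Preprocessor, ensemble_predict,
                                         fit_risk_model, make_learner,
                                         rank_features,
                                         representative_combo,
                                         train_ensemble, tune_hyperparams)
from rimradiomics.synthetic_data import OutcomeSpec, generate_outcomes


def signal_table(n=300, p=12, noise=0.3, seed=0, beta=2.0):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    X = pd.DataFrame(rng.standard_normal((n, p)),
                     columns=[f"f{i:02d}" for i in range(p)])
    X["f00"] = z + noise * rng.standard_normal(n)
    recs = generate_outcomes(z, OutcomeSpec(beta=beta, seed=seed + 1))
    t = np.array([r.time_months for r in recs])
    d = np.array([r.event for r in recs])
    return X, t, d


class TestPreprocessor:
    def test_duplicated_feature_becomes_one_meta_feature(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(100)
        df = pd.DataFrame({"a": a, "a_copy": a,
                           "b": rng.standard_normal(100)})
        prep = Preprocessor().fit(df)
        out = prep.transform(df)
        assert out.shape[1] == 2
        meta = [c for c in out.columns if c.startswith("meta_")][0]
        za = (a - a.mean()) / a.std()
        assert np.allclose(out[meta], za)

    def test_independent_features_stay_singletons(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((500, 8)),
                          columns=list("abcdefgh"))
        out = Preprocessor().fit(df).transform(df)
        assert list(out.columns) == sorted(df.columns)

    def test_validation_transformed_with_exploratory_stats(self):
        rng = np.random.default_rng(2)
        expl = pd.DataFrame(rng.standard_normal((80, 3)), columns=list("abc"))
        val = pd.DataFrame(rng.standard_normal((40, 3)) + 2.0,
                           columns=list("abc"))
        prep = Preprocessor().fit(expl)
        ze, zv = prep.transform(expl), prep.transform(val)
        assert np.allclose(ze.mean(), 0.0, atol=1e-12)
        assert np.allclose(ze.std(ddof=0), 1.0, atol=1e-12)
        assert zv.mean().mean() > 1.0  # shifted cohort stays shifted

    def test_zero_variance_features_dropped(self):
        df = pd.DataFrame({"a": np.arange(20.0), "const": np.ones(20)})
        out = Preprocessor().fit(df).transform(df)
        assert list(out.columns) == ["a"]

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            Preprocessor().fit(pd.DataFrame({"a": [1.0]}))


class TestSelectors:
    @pytest.mark.parametrize("selector",
                             ["spearman", "mim", "mifs", "mrmr", "rfvi"])
    def test_signal_feature_ranked_first(self, selector):
        X, t, d = signal_table(n=300, p=10)
        ranking = rank_features(selector, X, t, d, n_bootstrap=10, seed=3)
        assert ranking[0] == "f00"

    def test_mrmr_penalises_exact_copy(self):
        # f0 strong signal, f1 = exact copy, f2 weaker independent signal:
        # the copy must be selected after the non-redundant informative one
        rng = np.random.default_rng(5)
        n = 400
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        X = pd.DataFrame({"f0": z1, "f1": z1.copy(),
                          "f2": z2 + 0.5 * rng.standard_normal(n)})
        recs = generate_outcomes(z1 + 0.7 * z2,
                                 OutcomeSpec(beta=2.0, seed=6))
        t = np.array([r.time_months for r in recs])
        d = np.array([r.event for r in recs])
        ranking = rank_features("mrmr", X, t, d, n_bootstrap=10, seed=7)
        assert ranking.index("f2") < ranking.index("f1")

    def test_unknown_selector_rejected(self):
        X, t, d = signal_table(n=50, p=3)
        with pytest.raises(ValueError, match="unknown selector"):
            rank_features("pca", X, t, d, n_bootstrap=2)

    def test_ranking_deterministic(self):
        X, t, d = signal_table(n=100, p=6)
        a = rank_features("spearman", X, t, d, n_bootstrap=5, seed=9)
        b = rank_features("spearman", X, t, d, n_bootstrap=5, seed=9)
        assert a == b


class TestTuning:
    def test_budget_one_returns_single_configuration(self):
        X, t, d = signal_table(n=120, p=4)
        prep = Preprocessor().fit(X)
        table = prep.transform(X)
        hp = tune_hyperparams(ModelCombo("spearman", "cox"), table, t, d,
                              ranking=list(table.columns), budget=1, seed=0)
        assert "k" in hp and 1 <= hp["k"] <= 4

    def test_pure_noise_oob_concordance_near_half(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.standard_normal((200, 5)),
                         columns=[f"n{i}" for i in range(5)])
        t, d = (rng.exponential(20, 200) + 0.1,
                (rng.uniform(size=200) > 0.3).astype(int))
        from rimradiomics.risk_modelling.ensemble import _fit_one
        hp = {"k": 3}
        idx = rng.integers(0, 200, 200)
        oob = np.setdiff1d(np.arange(200), idx)
        m = _fit_one(ModelCombo("spearman", "cox"), hp,
                     X.to_numpy()[idx, :3], t[idx], d[idx], seed=1)
        c = concordance_index(m.predict_risk(X.to_numpy()[oob, :3]),
                              t[oob], d[oob])
        assert 0.4 <= c <= 0.6

    def test_invalid_budget_rejected(self):
        X, t, d = signal_table(n=50, p=3)
        with pytest.raises(ValueError):
            tune_hyperparams(ModelCombo("spearman", "cox"), X, t, d,
                             ranking=list(X.columns), budget=0)


class TestEnsemble:
    def test_single_bootstrap_equals_single_model(self):
        X, t, d = signal_table(n=100, p=4)
        ens = train_ensemble(ModelCombo("spearman", "cox"), ["f00"], {},
                             X, t, d, n_bootstrap=1, seed=3)
        single = ens.models[0].predict_risk(X[["f00"]].to_numpy())
        assert np.allclose(ensemble_predict(ens, X), single)

    def test_prediction_is_mean_over_models(self):
        class Stub:
            def __init__(self, v):
                self.v = v

            def predict_risk(self, X):
                return np.full(X.shape[0], self.v)

        ens = EnsembleModel(combo=ModelCombo("spearman", "cox"),
                            signature=["f00"], hyperparams={},
                            models=[Stub(1.0), Stub(3.0)])
        X = pd.DataFrame({"f00": np.zeros(5)})
        assert np.allclose(ensemble_predict(ens, X), 2.0)
        ens.models.reverse()
        assert np.allclose(ensemble_predict(ens, X), 2.0)

    def test_missing_signature_column_rejected(self):
        ens = EnsembleModel(combo=ModelCombo("spearman", "cox"),
                            signature=["zz"], hyperparams={}, models=[])
        with pytest.raises(ValueError, match="missing"):
            ensemble_predict(ens, pd.DataFrame({"a": [1.0]}))

    def test_cox_recovers_positive_coefficient(self):
        X, t, d = signal_table(n=300, p=1, noise=0.1)
        ens = train_ensemble(ModelCombo("spearman", "cox"), ["f00"],
                             {"alpha": 1e-6}, X[["f00"]], t, d,
                             n_bootstrap=10, seed=4)
        coefs = [m.est.coef_[0] for m in ens.models]
        assert np.mean(coefs) > 0

    def test_degenerate_bootstraps_dropped_not_fatal(self):
        # 1 event among 12 patients: some resamples are all-censored
        rng = np.random.default_rng(8)
        X = pd.DataFrame({"f": rng.standard_normal(12)})
        t = rng.exponential(10, 12) + 0.1
        d = np.zeros(12, dtype=int)
        d[0] = 1
        ens = train_ensemble(ModelCombo("spearman", "cox"), ["f"],
                             {"alpha": 1e-2}, X, t, d, n_bootstrap=30,
                             seed=5)
        assert 0 < len(ens.models) < 30

    def test_all_censored_training_fails_loudly(self):
        X = pd.DataFrame({"f": np.arange(20.0)})
        t = np.linspace(1, 20, 20)
        d = np.zeros(20, dtype=int)
        with pytest.raises(RuntimeError):
            train_ensemble(ModelCombo("spearman", "cox"), ["f"], {},
                           X, t, d, n_bootstrap=4, seed=0)


class TestLearnerContracts:
    @pytest.mark.parametrize("learner", ["cox", "bt-cox", "bglm-cox",
                                         "rsf", "msr-rf", "bt-weibull"])
    def test_risk_orientation_higher_is_worse(self, learner):
        X, t, d = signal_table(n=250, p=1, noise=0.1)
        m = make_learner(learner, random_state=0)
        m.fit(X[["f00"]].to_numpy(), t, d)
        c = concordance_index(m.predict_risk(X[["f00"]].to_numpy()), t, d)
        assert c > 0.6, f"{learner}: C={c}"


class TestPipelineProperties:
    def test_full_fit_deterministic(self):
        X, t, d = signal_table(n=150, p=6)
        kw = dict(n_bootstrap_select=5, n_bootstrap_train=5,
                  signature_size=2, seed=21)
        m1 = fit_risk_model(ModelCombo("spearman", "cox"), X, t, d, **kw)
        m2 = fit_risk_model(ModelCombo("spearman", "cox"), X, t, d, **kw)
        assert m1.ensemble.signature == m2.ensemble.signature
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_no_leakage_from_validation(self):
        # every exploratory-derived quantity must be identical no matter
        # what the validation rows or outcomes look like
        X, t, d = signal_table(n=200, p=6)
        expl = X.iloc[:140]
        model = fit_risk_model(ModelCombo("spearman", "cox"), expl,
                               t[:140], d[:140], n_bootstrap_select=5,
                               n_bootstrap_train=5, signature_size=2,
                               seed=13)
        rng = np.random.default_rng(0)
        val_a = X.iloc[140:]
        val_b = val_a.sample(frac=1.0, random_state=1)  # shuffled rows
        model2 = fit_risk_model(ModelCombo("spearman", "cox"), expl,
                                t[:140], d[:140], n_bootstrap_select=5,
                                n_bootstrap_train=5, signature_size=2,
                                seed=13)
        assert model.ranking == model2.ranking
        pd.testing.assert_series_equal(model.preprocessor.means_,
                                       model2.preprocessor.means_)
        cutoff_a = np.median(model.predict(expl))
        cutoff_b = np.median(model2.predict(expl))
        assert cutoff_a == cutoff_b
        # validation predictions are a pure function of the fitted model
        pa = model.predict(val_a)
        pb = model.predict(val_b.sort_index())
        assert np.allclose(pa, pb)

    def test_representative_combo_median_rule(self):
        c = pd.DataFrame(
            [[0.60, 0.62, 0.64], [0.70, 0.72, 0.74], [0.50, 0.52, 0.54]],
            index=["s1", "s2", "s3"], columns=["l1", "l2", "l3"])
        # selector medians 0.62/0.72/0.52 -> grand median 0.62 -> s1;
        # learner medians 0.60/0.62/0.64 -> median 0.62 -> l2
        assert representative_combo(c) == ("s1", "l2")
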