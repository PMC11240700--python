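"""The five survival learners and their shared contract."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from radsurv.deepsurv import DeepsurvConfig, cox_ph_loss, cox_ph_loss_grad
from radsurv.evaluation import harrell_cindex
from radsurv.models import (
    DeepsurvModel,
    GBMModel,
    LassoCoxModel,
    ModelSpec,
    RSFModel,
    StepwiseCoxModel,
    apply_one_hot,
    efron_null_loglik,
    make_model,
    one_hot_encode,
)
from radsurv.simulate import (
    CensoringConfig,
    WeibullBaseline,
    generate_survival_times,
)


def _sim(n, beta, seed, p_extra=0, event_frac=0.8):
    rng = np.random.default_rng(seed)
    p = len(beta)
    X = rng.standard_normal((n, p + p_extra))
    t, e = generate_survival_times(
        X[:, :p] @ np.asarray(beta),
        WeibullBaseline(),
        CensoringConfig(target_event_fraction=event_frac),
        seed=seed + 1,
    )
    cols = [f"x{j}" for j in range(p + p_extra)]
    return pd.DataFrame(X, columns=cols), t, e


@pytest.fixture(scope="module")
def strong_signal():
    return _sim(300, [np.log(3.0)], seed=31)


class TestOneHot:
    def test_three_level_variable_two_indicators(self):
        df = pd.DataFrame({"ps": ["0", "1", "2", "1"]})
        design, enc = one_hot_encode(df, reference={"ps": "0"})
        assert list(design.columns) == ["ps=1", "ps=2"]
        np.testing.assert_array_equal(design["ps=1"], [0, 1, 0, 1])

    def test_binary_roundtrip(self):
        df = pd.DataFrame({"b": ["no", "yes", "no"]})
        design, enc = one_hot_encode(df)
        again = apply_one_hot(df, enc)
        pd.testing.assert_frame_equal(design, again)

    def test_unseen_level_raises_with_name(self):
        df = pd.DataFrame({"b": ["no", "yes"]})
        _, enc = one_hot_encode(df)
        with pytest.raises(ValueError, match="maybe"):
            apply_one_hot(pd.DataFrame({"b": ["maybe"]}), enc)

    def test_numeric_passthrough(self):
        df = pd.DataFrame({"v": [1.5, 2.5]})
        design, _ = one_hot_encode(df)
        np.testing.assert_array_equal(design["v"], [1.5, 2.5])


class TestStepwiseCox:
    def test_retains_true_covariate(self):
        hits = 0
        for seed in range(10):
            X, t, e = _sim(500, [0.7], seed=seed, p_extra=5)
            m = StepwiseCoxModel().fit(X, t, e)
            if "x0" in m.selected_:
                hits += 1
        assert hits >= 9

    def test_final_aic_not_worse_than_full(self):
        X, t, e = _sim(150, [0.0, 0.0, 0.0], seed=50)
        m = StepwiseCoxModel().fit(X, t, e)
        _, full_aic = m._fit_subset(X, t, e, list(X.columns))
        final_aic = (
            m._fit_subset(X, t, e, m.selected_)[1]
            if m.selected_
            else -2.0 * efron_null_loglik(t, e)
        )
        assert final_aic <= full_aic + 1e-9

    def test_matches_backward_walk_oracle(self):
        X, t, e = _sim(120, [0.8, 0.0, 0.0], seed=51)
        m = StepwiseCoxModel().fit(X, t, e)
        # independent backward walk over all subsets via lifelines AIC
        df = X.copy()
        df["T"], df["E"] = t, e

        def aic(cols):
            if not cols:
                return -2.0 * efron_null_loglik(t, e)
            cph = CoxPHFitter().fit(df[["T", "E"] + cols], "T", "E")
            return float(cph.AIC_partial_)

        cols = list(X.columns)
        cur = aic(cols)
        while cols:
            cands = [(aic([c2 for c2 in cols if c2 != c]), c) for c in cols]
            best_aic, best_c = min(cands)
            if best_aic >= cur:
                break
            cur, cols = best_aic, [c2 for c2 in cols if c2 != best_c]
        assert sorted(m.selected_) == sorted(cols)

    def test_survival_contract(self, strong_signal):
        X, t, e = strong_signal
        m = StepwiseCoxModel().fit(X, t, e)
        times = np.arange(0.0, 25.0, 3.0)
        S = m.predict_survival(X.iloc[:5], times)
        assert np.allclose(S[:, 0], 1.0)
        assert (np.diff(S, axis=1) <= 1e-12).all()


class TestLassoCox:
    def test_large_lambda_full_shrinkage(self, strong_signal):
        X, t, e = strong_signal
        m = LassoCoxModel(alpha=50.0).fit(X, t, e)
        assert np.allclose(m.coef_, 0.0)
        assert np.ptp(m.predict_risk(X)) == 0.0

    def test_zero_lambda_matches_unpenalized_cox(self):
        X, t, e = _sim(200, [0.5, -0.3], seed=33)
        m = LassoCoxModel(alpha=0.0).fit(X, t, e)
        df = X.copy()
        df["T"], df["E"] = t, e
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(m.coef_, cph.params_.to_numpy(), atol=1e-3)

    def test_support_monotone_along_path(self):
        X, t, e = _sim(150, [0.6, -0.4, 0.2], seed=34, p_extra=3)
        nonzeros = []
        for alpha in (0.005, 0.02, 0.08, 0.3):
            m = LassoCoxModel(alpha=alpha).fit(X, t, e)
            nonzeros.append(int((m.coef_ != 0).sum()))
        assert all(a >= b for a, b in zip(nonzeros, nonzeros[1:]))

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            LassoCoxModel(alpha=-1.0)


class TestForestAndBoosting:
    def test_rsf_null_cindex(self):
        cs = []
        for seed in range(4):
            Xtr, ttr, etr = _sim(200, [0.0, 0.0], seed=100 + seed)
            Xte, tte, ete = _sim(150, [0.0, 0.0], seed=200 + seed)
            m = RSFModel(mtry=1, nodesize=15, n_trees=200, seed=seed).fit(Xtr, ttr, etr)
            cs.append(harrell_cindex(m.predict_risk(Xte), tte, ete))
        assert abs(np.mean(cs) - 0.5) < 0.05

    def test_rsf_strong_signal(self, strong_signal):
        X, t, e = strong_signal
        Xte, tte, ete = _sim(200, [np.log(3.0)], seed=37)
        m = RSFModel(mtry=1, nodesize=15, n_trees=300, seed=2).fit(X, t, e)
        assert harrell_cindex(m.predict_risk(Xte), tte, ete) > 0.65

    def test_rsf_seed_determinism(self, strong_signal):
        X, t, e = strong_signal
        r1 = RSFModel(n_trees=100, seed=5).fit(X, t, e).predict_risk(X.iloc[:20])
        r2 = RSFModel(n_trees=100, seed=5).fit(X, t, e).predict_risk(X.iloc[:20])
        np.testing.assert_array_equal(r1, r2)

    def test_rsf_mtry_validation(self, strong_signal):
        X, t, e = strong_signal
        with pytest.raises(ValueError):
            RSFModel(mtry=10).fit(X, t, e)

    def test_gbm_null_cindex(self):
        cs = []
        for seed in range(4):
            Xtr, ttr, etr = _sim(200, [0.0, 0.0], seed=300 + seed)
            Xte, tte, ete = _sim(150, [0.0, 0.0], seed=400 + seed)
            m = GBMModel(shrinkage=0.05, depth=2, mnotn=8, n_trees=200, seed=seed).fit(
                Xtr, ttr, etr
            )
            cs.append(harrell_cindex(m.predict_risk(Xte), tte, ete))
        assert abs(np.mean(cs) - 0.5) < 0.05

    def test_gbm_training_cindex_improves(self, strong_signal):
        X, t, e = strong_signal
        weak = GBMModel(shrinkage=0.01, depth=1, mnotn=8, n_trees=1, seed=4).fit(X, t, e)
        strong = GBMModel(shrinkage=0.01, depth=1, mnotn=8, n_trees=50, seed=4).fit(X, t, e)
        c1 = harrell_cindex(weak.predict_risk(X), t, e)
        c2 = harrell_cindex(strong.predict_risk(X), t, e)
        assert c2 > c1

    def test_gbm_determinism_and_validation(self, strong_signal):
        X, t, e = strong_signal
        with pytest.raises(ValueError):
            GBMModel(shrinkage=0.0)
        r1 = GBMModel(n_trees=50, seed=6).fit(X, t, e).predict_risk(X.iloc[:10])
        r2 = GBMModel(n_trees=50, seed=6).fit(X, t, e).predict_risk(X.iloc[:10])
        np.testing.assert_array_equal(r1, r2)


class TestDeepsurvLoss:
    def test_single_event_equal_scores_log_n(self):
        for n in (4, 10, 32):
            s = np.zeros(n)
            t = np.arange(1.0, n + 1)
            e = np.zeros(n)
            e[0] = 1
            assert cox_ph_loss(s, t, e) == pytest.approx(np.log(n))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(40)
        s = rng.normal(size=25)
        t = rng.exponential(5, 25) + 0.1
        e = rng.binomial(1, 0.7, 25)
        base = cox_ph_loss(s, t, e)
        for seed in range(5):
            perm = np.random.default_rng(seed).permutation(25)
            assert cox_ph_loss(s[perm], t[perm], e[perm]) == pytest.approx(base)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(41)
        s = rng.normal(size=12)
        t = rng.exponential(5, 12) + 0.1
        e = rng.binomial(1, 0.7, 12)
        e[0] = 1
        g = cox_ph_loss_grad(s, t, e)
        eps = 1e-6
        for k in range(12):
            sp, sm = s.copy(), s.copy()
            sp[k] += eps
            sm[k] -= eps
            fd = (cox_ph_loss(sp, t, e) - cox_ph_loss(sm, t, e)) / (2 * eps)
            assert g[k] == pytest.approx(fd, abs=1e-5)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_ph_loss(np.zeros(5), np.arange(1.0, 6.0), np.zeros(5))


class TestDeepsurvModel:
    def test_cox_limit_recovers_coefficients(self):
        X, t, e = _sim(400, [0.6, -0.5], seed=42)
        cfg = DeepsurvConfig(
            hidden_layers=0,
            dropout=0.0,
            l2_reg=0.0,
            batch_norm=False,
            batch_size=400,
            epochs=1500,
            early_stopping=False,
            learning_rate=0.05,
            lr_decay=0.0,
            seed=1,
        )
        m = DeepsurvModel(config=cfg).fit(X, t, e)
        df = X.copy()
        df["T"], df["E"] = t, e
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(
            m.net_.linear_weights, cph.params_.to_numpy(), atol=0.05
        )

    def test_risk_orientation_and_survival_contract(self, strong_signal):
        X, t, e = strong_signal
        m = DeepsurvModel(
            config=DeepsurvConfig(hidden_layers=1, hidden_nodes=8, seed=2)
        ).fit(X, t, e)
        risk = m.predict_risk(X)
        # higher true hazard -> higher predicted risk on average
        hi = risk[X["x0"] > 0.5].mean()
        lo = risk[X["x0"] < -0.5].mean()
        assert hi > lo
        S = m.predict_survival(X.iloc[:4], np.arange(0.0, 25.0, 3.0))
        assert np.allclose(S[:, 0], 1.0)
        assert (np.diff(S, axis=1) <= 1e-12).all()

    def test_seed_determinism(self, strong_signal):
        X, t, e = strong_signal
        cfg = dict(hidden_layers=1, hidden_nodes=8, epochs=30, seed=9)
        r1 = DeepsurvModel(config=DeepsurvConfig(**cfg)).fit(X, t, e).predict_risk(X.iloc[:10])
        r2 = DeepsurvModel(config=DeepsurvConfig(**cfg)).fit(X, t, e).predict_risk(X.iloc[:10])
        np.testing.assert_array_equal(r1, r2)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DeepsurvConfig(dropout=1.0)
        with pytest.raises(ValueError):
            DeepsurvConfig(activation="tanh")


class TestRiskOrientation:
    @pytest.mark.parametrize(
        "label,hp",
        [
            ("stepwise_cox", {}),
            ("lasso_cox", {"alpha": 0.01}),
            ("rsf", {"mtry": 1, "nodesize": 15, "n_trees": 100}),
            ("gbm", {"n_trees": 100}),
            ("deepsurv", {"hidden_layers": 1, "hidden_nodes": 8, "epochs": 100}),
        ],
    )
    def test_every_learner_orients_risk_upward(self, strong_signal, label, hp):
        X, t, e = strong_signal
        m = make_model(ModelSpec(label, hp, seed=3)).fit(X, t, e)
        risk = m.predict_risk(X)
        assert risk[X["x0"] > 0.5].mean() > risk[X["x0"] < -0.5].mean()
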