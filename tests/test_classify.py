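import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from conftest import binary_labels, toy_matrix
from cyclepred import classify
from oracles import brute_force_plr_1feature


def _series(y, m):
    return pd.Series(np.asarray(y, dtype=int), index=m.gene_ids)


class TestFitPLR:
    def test_matches_brute_force_grid_oracle(self):
        x = np.array([-1.0, -0.5, 0.5, 1.0])
        y = np.array([0, 0, 1, 1])
        m = toy_matrix(x[:, None])
        model = classify.fit_plr(m, _series(y, m), lam=1.0, standardize=False)
        b0_ref, b1_ref = brute_force_plr_1feature(x, y, 1.0)
        assert abs(model.beta0 - b0_ref) < 1e-4
        assert abs(model.beta[0] - b1_ref) < 1e-4

    def test_symmetric_data_forces_zero_intercept(self):
        x = np.array([-2.0, -1.0, -0.25, 0.25, 1.0, 2.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        m = toy_matrix(x[:, None])
        model = classify.fit_plr(m, _series(y, m), lam=0.7, standardize=False)
        assert abs(model.beta0) < 1e-8

    def test_infinite_shrinkage_leaves_only_intercept(self):
        rng = np.random.default_rng(0)
        m = toy_matrix(rng.normal(size=(60, 4)))
        y = np.r_[np.ones(40, int), np.zeros(20, int)]
        model = classify.fit_plr(m, _series(y, m), lam=1e9)
        assert np.max(np.abs(model.beta)) < 1e-3
        assert abs(model.beta0 - logit(np.mean(y))) < 1e-3

    def test_objective_decreases_monotonically(self):
        rng = np.random.default_rng(1)
        m = toy_matrix(rng.normal(size=(80, 6)))
        y = (rng.random(80) < expit(m.values.to_numpy() @ np.r_[2.0, np.zeros(5)])).astype(int)
        model = classify.fit_plr(m, _series(y, m), lam=0.5)
        hist = np.asarray(model.objective_history)
        assert model.converged
        assert (np.diff(hist) <= 0).all()

    def test_duplicating_genes_and_doubling_lambda_is_exact(self):
        rng = np.random.default_rng(2)
        m = toy_matrix(rng.normal(size=(40, 3)))
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        model = classify.fit_plr(m, _series(y, m), lam=1.3)
        dup = toy_matrix(
            np.vstack([m.values.to_numpy()] * 2),
            genes=[f"g{i}" for i in range(80)],
        )
        y2 = pd.Series(np.r_[y, y], index=dup.gene_ids)
        model2 = classify.fit_plr(dup, y2, lam=2.6)
        assert abs(model.beta0 - model2.beta0) < 1e-8
        np.testing.assert_allclose(model.beta, model2.beta, atol=1e-8)

    def test_negative_lambda_rejected(self):
        m = toy_matrix([[1.0], [2.0]])
        with pytest.raises(ValueError):
            classify.fit_plr(m, _series([0, 1], m), lam=-1.0)

    def test_single_class_rejected(self):
        m = toy_matrix([[1.0], [2.0]])
        with pytest.raises(ValueError, match="both classes"):
            classify.fit_plr(m, _series([1, 1], m), lam=1.0)


class TestPredictProba:
    def test_null_model_scores_half(self):
        m = toy_matrix([[3.0], [-1.0]])
        model = classify.PLRModel(
            beta0=0.0, beta=np.zeros(1), lam=1.0, feature_ids=["f0"],
            means=np.zeros(1), sds=np.ones(1), converged=True, objective_value=0.0,
        )
        assert (classify.predict_proba(model, m) == 0.5).all()

    def test_log3_linear_predictor_gives_three_quarters(self):
        m = toy_matrix([[np.log(3.0)]])
        model = classify.PLRModel(
            beta0=0.0, beta=np.ones(1), lam=1.0, feature_ids=["f0"],
            means=np.zeros(1), sds=np.ones(1), converged=True, objective_value=0.0,
        )
        assert classify.predict_proba(model, m).iloc[0] == pytest.approx(0.75, abs=1e-12)

    def test_monotone_in_positively_weighted_feature(self):
        m = toy_matrix(np.linspace(-2, 2, 9)[:, None])
        model = classify.PLRModel(
            beta0=0.3, beta=np.array([1.7]), lam=1.0, feature_ids=["f0"],
            means=np.zeros(1), sds=np.ones(1), converged=True, objective_value=0.0,
        )
        p = classify.predict_proba(model, m).to_numpy()
        assert (np.diff(p) > 0).all()

    def test_missing_feature_column_named(self):
        m = toy_matrix([[1.0]], features=["other"])
        model = classify.PLRModel(
            beta0=0.0, beta=np.ones(1), lam=1.0, feature_ids=["f0"],
            means=np.zeros(1), sds=np.ones(1), converged=True, objective_value=0.0,
        )
        with pytest.raises(KeyError, match="f0"):
            classify.predict_proba(model, m)


class TestCoefZScores:
    def test_null_features_calibrate_at_one_percent(self):
        """Pure-noise features yield ~1% of |z| past the 1% normal tail."""
        rng = np.random.default_rng(3)
        n_sims, n, p = 50, 200, 10
        hits = 0
        for _ in range(n_sims):
            m = toy_matrix(rng.normal(size=(n, p)))
            y = np.zeros(n, int)
            y[rng.choice(n, n // 2, replace=False)] = 1
            model = classify.fit_plr(m, _series(y, m), lam=1.0)
            _, pvals = classify.coef_zscores(model, m, _series(y, m))
            hits += int((pvals < 0.01).sum())
        total = n_sims * p
        sd = np.sqrt(total * 0.01 * 0.99)
        assert abs(hits - 0.01 * total) < 3 * sd

    def test_duplicated_column_shares_and_dilutes_z(self):
        """Two copies of one signal split the coefficient of the
        half-penalty single fit exactly and each carries less evidence."""
        rng = np.random.default_rng(4)
        n = 150
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(0.2 + 1.5 * x)).astype(int)
        m1 = toy_matrix(x[:, None], features=["f"])
        m2 = toy_matrix(np.c_[x, x], features=["f", "f_copy"])
        y1, y2 = _series(y, m1), _series(y, m2)
        single_half = classify.fit_plr(m1, y1, lam=0.6, standardize=False)
        dup = classify.fit_plr(m2, y2, lam=1.2, standardize=False)
        np.testing.assert_allclose(dup.beta, single_half.beta[0] / 2, atol=1e-6)
        z1, _ = classify.coef_zscores(single_half, m1, y1)
        z2, _ = classify.coef_zscores(dup, m2, y2)
        assert z2.iloc[0] == pytest.approx(z2.iloc[1], abs=1e-9)
        assert abs(z2.iloc[0]) < abs(z1.iloc[0])

    def test_zero_coefficient_gives_zero_z(self):
        rng = np.random.default_rng(5)
        m = toy_matrix(rng.normal(size=(30, 2)))
        y = _series(np.r_[np.ones(15, int), np.zeros(15, int)], m)
        model = classify.fit_plr(m, y, lam=1.0)
        model.beta[1] = 0.0
        z, _ = classify.coef_zscores(model, m, y)
        assert z.iloc[1] == 0.0


class TestRMLR:
    def test_two_class_model_equals_binary_plr(self):
        rng = np.random.default_rng(6)
        m = toy_matrix(rng.normal(size=(60, 3)))
        phases = pd.Series(["G1"] * 30 + ["S"] * 30, index=m.gene_ids)
        lam_binary = 0.8
        rmlr = classify.fit_rmlr(m, phases, lam=2 * lam_binary)
        y = _series((phases == "G1").astype(int), m)
        plr = classify.fit_plr(m, y, lam=lam_binary)
        p_multi = classify.predict_phase_proba(rmlr, m)["G1"]
        p_binary = classify.predict_proba(plr, m)
        np.testing.assert_allclose(p_multi.to_numpy(), p_binary.to_numpy(), atol=1e-6)

    def test_infinite_shrinkage_recovers_phase_frequencies(self):
        rng = np.random.default_rng(7)
        m = toy_matrix(rng.normal(size=(40, 2)))
        phases = pd.Series(["G1"] * 20 + ["S"] * 12 + ["G2"] * 8, index=m.gene_ids)
        rmlr = classify.fit_rmlr(m, phases, lam=1e9)
        proba = classify.predict_phase_proba(rmlr, m)
        freqs = phases.value_counts(normalize=True)
        for c in rmlr.classes:
            np.testing.assert_allclose(proba[c], freqs[c], atol=1e-3)

    def test_class_order_permutation_is_consistent(self):
        rng = np.random.default_rng(8)
        m = toy_matrix(rng.normal(size=(48, 3)))
        phases = pd.Series((["G1"] * 12 + ["S"] * 12 + ["G2"] * 12 + ["M"] * 12), index=m.gene_ids)
        a = classify.predict_phase_proba(classify.fit_rmlr(m, phases, 1.0), m)
        b = classify.predict_phase_proba(
            classify.fit_rmlr(m, phases, 1.0, classes=("M", "G2", "S", "G1")), m
        )
        for c in ("G1", "S", "G2", "M"):
            np.testing.assert_allclose(a[c].to_numpy(), b[c].to_numpy(), atol=1e-6)

    def test_objective_monotone_and_converged(self):
        rng = np.random.default_rng(9)
        m = toy_matrix(rng.normal(size=(60, 4)))
        phases = pd.Series((["G1"] * 15 + ["S"] * 15 + ["G2"] * 15 + ["M"] * 15), index=m.gene_ids)
        rmlr = classify.fit_rmlr(m, phases, 0.5)
        assert rmlr.converged
        assert (np.diff(rmlr.objective_history) <= 0).all()
        proba = classify.predict_phase_proba(rmlr, m)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)


class TestPredictPhase:
    def _proba(self, rows, genes=None):
        return pd.DataFrame(
            rows, columns=["G1", "S", "G2", "M"],
            index=genes or [f"g{i}" for i in range(len(rows))],
        )

    def test_confident_call(self):
        calls = classify.assign_phases(self._proba([[0.97, 0.01, 0.01, 0.01]]), 0.5)
        assert calls.iloc[0] == "G1"

    def test_below_threshold_is_unclear(self):
        calls = classify.assign_phases(self._proba([[0.4, 0.3, 0.2, 0.1]]), 0.5)
        assert calls.iloc[0] == "unclear"

    def test_zero_threshold_never_unclear(self):
        rng = np.random.default_rng(10)
        arr = rng.dirichlet(np.ones(4), size=50)
        calls = classify.assign_phases(self._proba(arr), 0.0)
        assert (calls != "unclear").all()

    def test_tie_breaks_toward_earlier_phase(self):
        calls = classify.assign_phases(self._proba([[0.3, 0.3, 0.3, 0.1]]), 0.0)
        assert calls.iloc[0] == "G1"

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify.assign_phases(self._proba([[0.7, 0.1, 0.1, 0.1]]), 1.5)


class TestSerialization:
    def test_plr_round_trip_preserves_predictions(self, tmp_path, fitted_binary):
        sub, model = fitted_binary
        path = tmp_path / "plr.tsv"
        classify.write_plr_model(model, path)
        back = classify.read_plr_model(path)
        np.testing.assert_allclose(
            classify.predict_proba(back, sub).to_numpy(),
            classify.predict_proba(model, sub).to_numpy(),
        )
        np.testing.assert_allclose(back.zscores, model.zscores)

    def test_rmlr_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(11)
        m = toy_matrix(rng.normal(size=(40, 3)))
        phases = pd.Series((["G1"] * 10 + ["S"] * 10 + ["G2"] * 10 + ["M"] * 10), index=m.gene_ids)
        model = classify.fit_rmlr(m, phases, 1.0)
        path = tmp_path / "rmlr.tsv"
        classify.write_rmlr_model(model, path)
        back = classify.read_rmlr_model(path)
        np.testing.assert_allclose(
            classify.predict_phase_proba(back, m).to_numpy(),
            classify.predict_phase_proba(model, m).to_numpy(),
        )
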