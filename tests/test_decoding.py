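import math

import numpy as np
import pytest

from pupilstate.corrmaps import SpatialMap
from pupilstate.decoding import (
    DEFAULT_RIDGE_ALPHA,
    ComponentSeries,
    LinearDecoder,
    ModelSpec,
    compare_methods,
    component_count_sweep,
    crossval,
    fit_linear,
    fit_pca,
    pearson,
    predict,
    project,
    shift_sweep,
    template_predict,
)
from pupilstate.gru import GRUConfig, GRUDecoder, correlation_loss, fit_gru
from pupilstate.synthetic import (
    StateProfile,
    Trial,
    generate_cohort,
    generate_component_maps,
)


class TestFitPCA:
    def test_single_component_recovery(self, single_component_cohort):
        trials, truth = single_component_cohort
        basis = fit_pca(trials, n_components=1)
        r = np.corrcoef(basis.components[0], truth.atlas.maps[0])[0, 1]
        assert abs(r) >= 0.999

    def test_evr_properties(self, cohort_small):
        trials, _ = cohort_small
        basis = fit_pca(trials[:4], n_components=10)
        evr = basis.explained_variance_ratio
        assert evr.sum() <= 1.0 + 1e-9
        assert np.all(np.diff(evr) <= 1e-12)

    def test_orthogonality_invariant(self, cohort_small):
        trials, _ = cohort_small
        basis = fit_pca(trials[:4], n_components=8)
        G = basis.components @ basis.components.T
        off = np.abs(G - np.diag(np.diag(G))).max()
        assert off <= 1e-6 * np.abs(np.diag(G)).max()

    def test_default_component_count_is_300(self):
        import inspect

        assert inspect.signature(fit_pca).parameters["n_components"].default == 300
        assert ModelSpec().n_components == 300

    def test_rank_bound_rejected(self, cohort_small):
        trials, _ = cohort_small
        with pytest.raises(ValueError, match="rank"):
            fit_pca(trials[:1], n_components=10_000)

    def test_sign_convention_deterministic(self, cohort_small):
        trials, _ = cohort_small
        a = fit_pca(trials[:4], n_components=5)
        b = fit_pca(trials[:4], n_components=5)
        assert np.allclose(a.components, b.components)
        for comp in a.components:
            assert comp[np.argmax(np.abs(comp))] > 0


class TestProject:
    def test_training_trial_reproduces_scores_up_to_scale(self, cohort_small):
        trials, _ = cohort_small
        train = trials[:4]
        basis = fit_pca(train, n_components=5)
        series = project(train[0], basis)
        direct = basis.components @ (
            np.asarray(train[0].fmri, dtype=float) - basis.mean_map[:, None])
        for k in range(5):
            assert abs(pearson(series.scores[k], direct[k])) >= 1 - 1e-9

    def test_zero_signal_flagged(self, cohort_small, geom_small):
        trials, _ = cohort_small
        basis = fit_pca(trials[:4], n_components=3)
        zero = Trial("z", np.zeros_like(trials[0].fmri),
                     np.zeros(trials[0].n_frames) , tr=1.0, geometry=geom_small)
        with pytest.warns(UserWarning, match="constant"):
            series = project(zero, basis)
        assert series.constant_rows.all()
        assert np.all(series.scores == 0)

    def test_component_shaped_data_loads_one_component(self, cohort_small,
                                                       geom_small):
        trials, _ = cohort_small
        basis = fit_pca(trials[:4], n_components=4)
        T = 50
        s = np.sin(np.arange(T) * 0.2)
        fmri = basis.mean_map[:, None] + basis.components[2][:, None] * s
        trial = Trial("c", fmri, s, tr=1.0, geometry=geom_small)
        series = project(trial, basis)
        # orthogonality: only component 2 carries the signal
        raw = basis.components @ (fmri - basis.mean_map[:, None])
        power = raw.var(axis=1)
        assert power[2] > 1e3 * max(np.delete(power, 2).max(), 1e-30)
        assert abs(pearson(series.scores[2], s)) >= 1 - 1e-9

    def test_geometry_mismatch(self, cohort_small):
        trials, _ = cohort_small
        basis = fit_pca(trials[:4], n_components=3)
        bad = Trial("b", np.zeros((7, 20)), np.arange(20.0), tr=1.0)
        with pytest.raises(ValueError, match="basis"):
            project(bad, basis)


class TestTemplatePredict:
    def _map(self, values):
        return SpatialMap(np.asarray(values, dtype=float), None, kind="prediction")

    def test_volume_equal_to_template(self):
        rng = np.random.default_rng(0)
        tpl = rng.standard_normal(30)
        fmri = np.stack([tpl, -tpl], axis=1)
        trial = Trial("t", fmri, np.zeros(2) + [0, 1], tr=1.0)
        out = template_predict(self._map(tpl), trial)
        assert out[0] == pytest.approx(1.0, abs=1e-12)
        assert out[1] == pytest.approx(-1.0, abs=1e-12)

    def test_toy_matches_per_frame_hand_correlation(self):
        tpl = np.array([0.1, -0.3, 0.2, 0.5, -0.1, 0.0])
        rng = np.random.default_rng(1)
        fmri = rng.standard_normal((6, 3))
        trial = Trial("t", fmri, np.zeros(3), tr=1.0)
        out = template_predict(self._map(tpl), trial)
        for t in range(3):
            x, y = tpl, fmri[:, t]
            n = 6
            num = n * (x * y).sum() - x.sum() * y.sum()
            den = math.sqrt((n * (x * x).sum() - x.sum() ** 2)
                            * (n * (y * y).sum() - y.sum() ** 2))
            assert out[t] == pytest.approx(num / den, abs=1e-12)

    def test_constant_volume_flagged_zero(self):
        tpl = np.arange(6.0)
        fmri = np.ones((6, 2))
        fmri[:, 1] = np.arange(6.0)
        trial = Trial("t", fmri, np.zeros(2), tr=1.0)
        with pytest.warns(UserWarning, match="constant"):
            out = template_predict(self._map(tpl), trial)
        assert out[0] == 0.0
        assert out[1] == pytest.approx(1.0)

    def test_bounded(self, cohort_small, geom_small):
        trials, _ = cohort_small
        tpl = SpatialMap(np.random.default_rng(2).standard_normal(
            geom_small.n_voxels), geom_small, kind="prediction")
        out = template_predict(tpl, trials[0])
        assert np.all(out >= -1.0) and np.all(out <= 1.0)


def ridge_oracle(X, y, alpha):
    """Normal equations on centered data, independent of the implementation."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    return np.linalg.inv(Xc @ Xc.T + alpha * np.eye(X.shape[0])) @ (Xc @ yc)


class TestFitLinear:
    def _toy(self, K=6, T=400, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((K, T))
        w = rng.standard_normal(K)
        return X, w, w @ X + 0.5

    def test_ols_exact_recovery(self):
        X, w, y = self._toy()
        dec = fit_linear(X, y, variant="ols")
        assert np.max(np.abs(dec.weights - w)) <= 1e-6
        assert dec.intercept == pytest.approx(0.5, abs=1e-6)

    def test_ridge_limit_approaches_ols(self):
        X, w, y = self._toy(seed=1)
        ols = fit_linear(X, y, variant="ols")
        ridge = fit_linear(X, y, variant="ridge", alpha=1e-10)
        assert np.allclose(ridge.weights, ols.weights, atol=1e-8)

    def test_ridge_matches_normal_equations_oracle(self):
        X, w, y = self._toy(K=20, T=1000, seed=2)
        X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        y = w[:20] @ X + np.random.default_rng(3).standard_normal(1000)
        dec = fit_linear(X, y, variant="ridge", alpha=DEFAULT_RIDGE_ALPHA)
        assert np.max(np.abs(dec.weights
                             - ridge_oracle(X, y, DEFAULT_RIDGE_ALPHA))) <= 1e-8

    def test_singular_ols_advises_ridge(self):
        X = np.ones((3, 10))
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            fit_linear(X, np.arange(10.0), variant="ols")

    def test_lasso_shrinks_to_zero(self):
        X, w, y = self._toy(seed=4)
        dec = fit_linear(X, y, variant="lasso", alpha=100.0)
        assert np.allclose(dec.weights, 0.0)


class TestGRU:
    def test_zero_weights_zero_output(self):
        dec = GRUDecoder(3, hidden_size=5, seed=0)
        for k in dec.params:
            dec.params[k][...] = 0.0
        X = np.random.default_rng(0).standard_normal((3, 20))
        assert np.allclose(dec.forward(X), 0.0)

    def test_single_step_scalar_hand_evaluation(self):
        dec = GRUDecoder(1, hidden_size=1, seed=0)
        vals = {"W_ir": 0.3, "W_iz": -0.2, "W_in": 0.5, "W_hr": 0.1,
                "W_hz": 0.4, "W_hn": -0.3, "b_ir": 0.05, "b_iz": -0.1,
                "b_in": 0.2, "b_hr": 0.0, "b_hz": 0.15, "b_hn": -0.05,
                "w_out": 2.0}
        for k, v in vals.items():
            dec.params[k][...] = v
        x = 0.7
        y = dec.forward(np.array([[x]]))
        # hand evaluation with h(0)=0
        sig = lambda u: 1.0 / (1.0 + math.exp(-u))
        r = sig(0.3 * x + 0.05 + 0.0)
        z = sig(-0.2 * x - 0.1 + 0.15)
        n = math.tanh(0.5 * x + 0.2 + r * (-0.05))
        h = (1 - z) * n + z * 0.0
        assert y[0] == pytest.approx(2.0 * h, abs=1e-12)

    def test_default_epochs_seven(self):
        assert GRUConfig().epochs == 7
        assert GRUConfig().hidden_size == 300
        assert GRUConfig().batch_size == 12

    def test_correlation_loss_gradient_check(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(30)
        t = rng.standard_normal(30)
        loss, grad = correlation_loss(y, t)
        eps = 1e-6
        for i in (0, 7, 29):
            yp = y.copy(); yp[i] += eps
            ym = y.copy(); ym[i] -= eps
            fd = (correlation_loss(yp, t)[0] - correlation_loss(ym, t)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(fd, abs=1e-7)

    def test_bptt_gradient_check(self):
        rng = np.random.default_rng(2)
        dec = GRUDecoder(3, hidden_size=4, seed=3)
        X = rng.standard_normal((2, 3, 12))
        T = rng.standard_normal((2, 12))

        def total_loss():
            y = dec.forward(X)
            return np.mean([correlation_loss(y[b], T[b])[0] for b in range(2)])

        y, cache = dec.forward(X, return_cache=True)
        dY = np.stack([correlation_loss(y[b], T[b])[1] for b in range(2)]) / 2
        grads, _ = dec.backward(cache, dY)
        eps = 1e-6
        for name in ("W_ir", "W_hz", "W_hn", "b_in", "w_out"):
            p = dec.params[name]
            idx = (0,) * p.ndim
            p[idx] += eps; lp = total_loss()
            p[idx] -= 2 * eps; lm = total_loss()
            p[idx] += eps
            assert grads[name][idx] == pytest.approx((lp - lm) / (2 * eps),
                                                     abs=1e-5)

    def test_fit_reproducible(self):
        rng = np.random.default_rng(4)
        X = [rng.standard_normal((3, 40)) for _ in range(4)]
        Y = [rng.standard_normal(40) for _ in range(4)]
        cfg = GRUConfig(hidden_size=6, epochs=2, batch_size=2)
        a = fit_gru(X, Y, config=cfg, seed=9)
        b = fit_gru(X, Y, config=cfg, seed=9)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_training_reduces_loss(self):
        rng = np.random.default_rng(5)
        w = rng.standard_normal(3)
        X = [rng.standard_normal((3, 80)) for _ in range(6)]
        Y = [w @ x for x in X]
        cfg = GRUConfig(hidden_size=8, epochs=15, batch_size=3,
                        learning_rate=0.01, l2=0.0)
        dec = fit_gru(X, Y, config=cfg, seed=0)
        rs = [pearson(dec.forward(x), y) for x, y in zip(X, Y)]
        assert np.mean(rs) > 0.5


class TestPredict:
    def test_linear_one_hot(self):
        X = np.random.default_rng(0).standard_normal((4, 20))
        dec = LinearDecoder("ols", 0.0, np.array([0.0, 1.0, 0.0, 0.0]), 0.0)
        assert np.allclose(predict(dec, X), X[1])

    def test_linear_matches_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((4, 20))
        w = rng.standard_normal(4)
        dec = LinearDecoder("ridge", 1.0, w, 0.7)
        assert np.allclose(predict(dec, ComponentSeries(X)), w @ X + 0.7,
                           atol=1e-12)

    def test_gru_zero_weights(self):
        dec = GRUDecoder(2, hidden_size=3, seed=0)
        for k in dec.params:
            dec.params[k][...] = 0.0
        assert np.allclose(predict(dec, np.ones((2, 10))), 0.0)

    def test_dimension_mismatch(self):
        dec = LinearDecoder("ols", 0.0, np.zeros(3), 0.0)
        with pytest.raises(ValueError, match="mismatch"):
            predict(dec, np.zeros((4, 10)))


@pytest.fixture(scope="module")
def decoding_cohort(geom_small, atlas_small, profiles):
    trials, truth = generate_cohort(
        geom_small, atlas_small, profiles, [5, 5, 5, 5], T=256,
        noise_sd_fmri=1.0, noise_sd_pupil=0.2, seed=17,
    )
    return trials, truth


class TestCrossval:
    def test_fold_sizes(self, decoding_cohort):
        trials, _ = decoding_cohort
        spec = ModelSpec(method="ridge", n_components=10, alpha=10.0)
        res = crossval(trials[:16], spec, n_folds=4, seed=0)
        assert len(res.cv_scores) == 16
        ids = [s.trial_id for s in res.cv_scores]
        assert len(set(ids)) == 16

    def test_noise_free_ridge_near_perfect(self, geom_small, atlas_small,
                                           profiles):
        # single planted state: one shared coupling, exactly linearly decodable
        trials, _ = generate_cohort(
            geom_small, atlas_small, profiles[:1], [12], T=256,
            noise_sd_fmri=0.0, noise_sd_pupil=0.0, seed=19,
        )
        spec = ModelSpec(method="ridge", n_components=6, alpha=1e-6)
        res = crossval(trials, spec, n_folds=4, seed=0)
        assert res.mean_cv() >= 0.99

    def test_shuffled_null_bounded(self, decoding_cohort):
        trials, _ = decoding_cohort
        rng = np.random.default_rng(23)
        null_trials = []
        perm = rng.permutation(len(trials))
        for t, j in zip(trials, perm):
            other = trials[j].pupil if j != 0 else trials[-1].pupil
            null_trials.append(Trial(t.subject_id, t.fmri,
                                     rng.standard_normal(t.n_frames),
                                     tr=t.tr, geometry=t.geometry))
        spec = ModelSpec(method="ridge", n_components=10, alpha=100.0)
        res = crossval(null_trials[:12], spec, n_folds=4, seed=0)
        T = null_trials[0].n_frames
        assert abs(res.mean_cv()) <= 2 / np.sqrt(T) + 0.1

    def test_leakage_rejected(self, decoding_cohort):
        trials, _ = decoding_cohort
        with pytest.raises(ValueError, match="leakage"):
            crossval(trials[:8], ModelSpec(method="template"),
                     test_trials=trials[:2])

    def test_no_leakage_from_test_pupil(self, decoding_cohort, geom_small):
        trials, _ = decoding_cohort
        train, test = trials[:8], trials[8:10]
        spec = ModelSpec(method="ridge", n_components=5, alpha=10.0)
        res1 = crossval(train, spec, n_folds=2, test_trials=test, seed=0)
        scrambled = [Trial(t.subject_id, t.fmri,
                           t.pupil[::-1].copy(), tr=t.tr, geometry=geom_small)
                     for t in test]
        res2 = crossval(train, spec, n_folds=2, test_trials=scrambled, seed=0)
        cv1 = {s.trial_id: s.r for s in res1.cv_scores}
        cv2 = {s.trial_id: s.r for s in res2.cv_scores}
        assert cv1 == cv2  # training untouched by test pupil


class TestShiftSweep:
    def test_zero_lag_cohort(self, decoding_cohort):
        trials, _ = decoding_cohort
        spec = ModelSpec(method="ridge", n_components=8, alpha=50.0)
        scores = shift_sweep(trials[:12], [-3, 0, 3], spec, n_folds=3, seed=0)
        assert max(scores, key=scores.get) == 0

    def test_planted_lag_recovered(self, geom_small, atlas_small, profiles):
        trials, _ = generate_cohort(
            geom_small, atlas_small, profiles, [3, 3, 3, 3], T=256,
            noise_sd_fmri=0.5, noise_sd_pupil=0.1, seed=29,
            pupil_lag_frames=3,
        )
        spec = ModelSpec(method="ridge", n_components=8, alpha=50.0)
        scores = shift_sweep(trials, [0, 1, 2, 3, 4, 5], spec, n_folds=3, seed=0)
        assert max(scores, key=scores.get) == 3

    def test_zero_shift_equals_plain_crossval(self, decoding_cohort):
        trials, _ = decoding_cohort
        spec = ModelSpec(method="ridge", n_components=5, alpha=10.0)
        sweep = shift_sweep(trials[:8], [0], spec, n_folds=2, seed=0)
        plain = crossval(trials[:8], spec, n_folds=2, seed=0)
        assert sweep[0] == pytest.approx(plain.mean_cv(), abs=1e-12)


class TestComponentCountSweep:
    def test_runs_and_keys(self, decoding_cohort):
        trials, _ = decoding_cohort
        spec = ModelSpec(method="ridge", alpha=50.0)
        out = component_count_sweep(trials[:8], [2, 6], spec, n_folds=2, seed=0)
        assert set(out) == {2, 6}


class TestCompareMethods:
    def test_identical_sets(self):
        a = [0.1, 0.5, 0.3, 0.7]
        t, p = compare_methods(a, a)
        assert t == 0.0 and p == 1.0

    def test_constant_difference_degenerate(self):
        a = np.array([0.1, 0.5, 0.3])
        with pytest.warns(UserWarning, match="degenerate"):
            t, p = compare_methods(a + 0.2, a)
        assert math.isinf(t) and t > 0 and p == 0.0

    def test_five_pair_hand_t(self):
        a = np.array([0.5, 0.6, 0.4, 0.7, 0.55])
        b = np.array([0.45, 0.5, 0.42, 0.6, 0.5])
        d = a - b
        n = 5
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(n))
        t, p = compare_methods(a, b)
        assert t == pytest.approx(t_hand, abs=1e-12)
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), n - 1), abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="3"):
            compare_methods([0.1, 0.2], [0.2, 0.3])
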