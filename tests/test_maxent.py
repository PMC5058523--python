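import numpy as np
import pytest
from scipy import stats

from snailrisk import (FeatureSpec, GridStack, LandscapeSpec, OccurrenceSet,
                       TruthModel, fit, gen_env_stack, jackknife_gains,
                       percent_contribution, permutation_importance, predict,
                       replicate_evaluate, response_curve, sample_background,
                       sample_occurrences, true_suitability)
from snailrisk.maxent import predict_cells

from conftest import make_grid


@pytest.fixture(scope="module")
def small_stack():
    spec = LandscapeSpec(nrows=40, ncols=40, n_vars=3, smoothing_radius=2,
                         seed=10)
    return gen_env_stack(spec)


@pytest.fixture(scope="module")
def fitted(landscape100, strong_presences):
    bg = sample_background(landscape100, 5000, seed=2)
    return fit(strong_presences, bg, landscape100), bg


class TestSampleBackground:
    def test_uniform_full_draw_covers_every_cell(self, small_stack):
        n = small_stack.data_cells().size
        bg = sample_background(small_stack, n, seed=0)
        assert np.array_equal(np.sort(bg), small_stack.data_cells())

    def test_zero_bias_region_excluded(self, small_stack):
        bias_vals = np.ones((40, 40))
        bias_vals[:, 20:] = 0.0
        bias = small_stack.ref.with_values(bias_vals)
        bg = sample_background(small_stack, 200, bias=bias, seed=1)
        cols = bg % 40
        assert np.all(cols < 20)

    def test_biased_share_within_sampling_error(self, small_stack):
        bias_vals = np.ones((40, 40))
        bias_vals[:, :20] = 3.0  # 3:1 left:right
        bias = small_stack.ref.with_values(bias_vals)
        bg = sample_background(small_stack, 400, bias=bias, seed=3)
        left = np.mean(bg % 40 < 20)
        se = np.sqrt(0.75 * 0.25 / 400)
        assert abs(left - 0.75) < 3 * se + 0.05  # finite-pop slack

    def test_oversized_request_rejected(self, small_stack):
        with pytest.raises(ValueError):
            sample_background(small_stack, 10**6, seed=0)


class TestFit:
    def test_heavy_regularization_flattens_model(self, small_stack):
        truth = TruthModel({"env1": (2.0, 0.0)})
        surf = true_suitability(small_stack, truth)
        occ = sample_occurrences(surf, 100, seed=4)
        bg = sample_background(small_stack, 1000, seed=5)
        model = fit(occ, bg, small_stack, reg_beta=1000.0)
        assert np.allclose(model.lambdas, 0.0, atol=1e-8)
        pred = predict(model, small_stack, output="raw")
        vals = pred.values[small_stack.mask]
        assert np.allclose(vals, vals[0])

    def test_recovers_generating_surface(self, landscape100,
                                         strong_truth_surface, fitted):
        model, _ = fitted
        pred = predict(model, landscape100)
        m = landscape100.mask
        rho = stats.spearmanr(pred.values[m],
                              strong_truth_surface.values[m]).statistic
        assert rho > 0.9

    def test_duplicate_presences_collapse(self, small_stack):
        truth = TruthModel({"env1": (2.0, 0.0)})
        surf = true_suitability(small_stack, truth)
        occ = sample_occurrences(surf, 50, seed=6)
        dup = OccurrenceSet(occ.species, occ.points + occ.points[:10])
        bg = sample_background(small_stack, 800, seed=7)
        a = fit(occ, bg, small_stack)
        b = fit(dup, bg, small_stack)
        assert np.allclose(a.lambdas, b.lambdas)

    def test_convexity_runs_from_random_starts_agree(self, small_stack):
        truth = TruthModel({"env1": (2.0, 0.0), "env2": (0.0, -1.0)})
        surf = true_suitability(small_stack, truth)
        occ = sample_occurrences(surf, 120, seed=8)
        bg = sample_background(small_stack, 1000, seed=9)
        k = len(FeatureSpec().build_terms(small_stack.names))
        m0 = fit(occ, bg, small_stack,
                 lam0=np.random.default_rng(0).normal(scale=0.5, size=k))
        m1 = fit(occ, bg, small_stack,
                 lam0=np.random.default_rng(1).normal(scale=0.5, size=k))
        assert m0.objective == pytest.approx(m1.objective, rel=1e-6)
        assert np.allclose(m0.lambdas, m1.lambdas, atol=1e-3)

    def test_too_few_presences_rejected(self, small_stack):
        occ = OccurrenceSet("s", [small_stack.ref.cell_center(0, 0)] * 10)
        bg = sample_background(small_stack, 100, seed=0)
        with pytest.raises(ValueError, match="presence"):
            fit(occ, bg, small_stack)


class TestPredict:
    def test_raw_normalizes_over_background(self, landscape100, fitted):
        model, bg = fitted
        raw = predict_cells(model, landscape100, bg, output="raw")
        assert raw.sum() == pytest.approx(1.0, abs=1e-6)

    def test_logistic_bounded(self, landscape100, fitted):
        model, _ = fitted
        pred = predict(model, landscape100)
        vals = pred.values[landscape100.mask]
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_monotone_model_rank_matches_layer(self, small_stack):
        truth = TruthModel({"env1": (3.0, 0.0)})
        surf = true_suitability(small_stack, truth)
        occ = sample_occurrences(surf, 150, seed=11)
        bg = sample_background(small_stack, 1200, seed=12)
        model = fit(occ, bg, small_stack.subset(["env1"]),
                    spec=FeatureSpec(types=("linear",)))
        pred = predict(model, small_stack.subset(["env1"]))
        m = small_stack.mask
        rho = stats.spearmanr(pred.values[m],
                              small_stack["env1"].values[m]).statistic
        assert abs(rho) > 0.999

    def test_missing_layer_rejected(self, landscape100, fitted):
        model, _ = fitted
        partial = landscape100.subset(["env1", "env2"])
        with pytest.raises(ValueError, match="missing"):
            predict(model, partial)


class TestReplicateEvaluate:
    def test_single_replicate_summary_has_zero_sd(self, small_stack):
        truth = TruthModel({"env1": (3.0, 0.0)})
        surf = true_suitability(small_stack, truth)
        occ = sample_occurrences(surf, 100, seed=13)
        ev = replicate_evaluate(occ, small_stack, n_replicates=1, seed=14,
                                background_n=800)
        assert len(ev.per_replicate) == 1
        assert (ev.summary.loc["std"] == 0).all()

    def test_null_presences_calibrate_to_half(self, small_stack):
        flat = small_stack.ref.with_values(
            np.full((40, 40), 0.5))
        occ = sample_occurrences(flat, 120, seed=15)
        ev = replicate_evaluate(occ, small_stack, n_replicates=10, seed=16,
                                background_n=800)
        assert 0.4 <= ev.per_replicate["auc_test"].mean() <= 0.6


class TestImportanceDiagnostics:
    def test_contribution_sums_to_100(self, fitted):
        model, _ = fitted
        pc = percent_contribution(model)
        assert pc["percent_contribution"].sum() == pytest.approx(100.0,
                                                                 abs=1e-6)

    def test_single_variable_model_gets_full_contribution(self, small_stack):
        truth = TruthModel({"env1": (3.0, 0.0)})
        surf = true_suitability(small_stack, truth)
        occ = sample_occurrences(surf, 100, seed=17)
        bg = sample_background(small_stack, 800, seed=18)
        model = fit(occ, bg, small_stack.subset(["env1"]))
        pc = percent_contribution(model)
        assert pc["percent_contribution"].iloc[0] == pytest.approx(100.0)

    def test_active_variables_dominate_contribution(self, fitted):
        model, _ = fitted
        pc = percent_contribution(model).set_index("variable")
        active = pc.loc[["env1", "env2"], "percent_contribution"].min()
        inactive = pc.loc[["env3", "env4", "env5"],
                          "percent_contribution"].max()
        assert active > inactive

    def test_permutation_importance_sums_to_100(self, landscape100,
                                                strong_presences, fitted):
        model, bg = fitted
        pi = permutation_importance(model, strong_presences, bg,
                                    landscape100, seed=1)
        assert pi["permutation_importance"].sum() == pytest.approx(
            100.0, abs=1e-6)

    def test_inactive_below_active(self, landscape100, strong_presences,
                                   fitted):
        model, bg = fitted
        pi = permutation_importance(model, strong_presences, bg,
                                    landscape100, seed=2)
        pi = pi.set_index("variable")["permutation_importance"]
        assert pi[["env1", "env2"]].min() > pi[["env3", "env4",
                                                "env5"]].max()


@pytest.fixture(scope="module")
def jk(small_stack):
    truth = TruthModel({"env1": (3.0, 0.0)})
    surf = true_suitability(small_stack, truth)
    occ = sample_occurrences(surf, 150, seed=19)
    return jackknife_gains(occ, small_stack, seed=20, background_n=800)


class TestJackknife:
    def test_gains_nonnegative(self, jk):
        assert (jk["gain_only"] >= 0).all()
        assert (jk["gain_without"] >= 0).all()

    def test_informative_variable_alone_approaches_full_gain(self, jk):
        full = jk.attrs["full_gain"]
        only = jk.set_index("variable").loc["env1", "gain_only"]
        assert only >= 0.9 * full

    def test_excluding_uninformative_variable_keeps_gain(self, jk):
        full = jk.attrs["full_gain"]
        without = jk.set_index("variable").loc["env3", "gain_without"]
        assert without >= 0.95 * full

    def test_single_variable_stack_rejected(self, small_stack):
        occ = sample_occurrences(
            true_suitability(small_stack, TruthModel({"env1": (2.0, 0.0)})),
            50, seed=21)
        with pytest.raises(ValueError):
            jackknife_gains(occ, small_stack.subset(["env1"]))


class TestResponseCurve:
    def test_linear_positive_model_monotone_increasing(self, small_stack):
        truth = TruthModel({"env1": (3.0, 0.0)})
        surf = true_suitability(small_stack, truth)
        occ = sample_occurrences(surf, 150, seed=22)
        bg = sample_background(small_stack, 800, seed=23)
        model = fit(occ, bg, small_stack.subset(["env1"]),
                    spec=FeatureSpec(types=("linear",)))
        rc = response_curve(model, small_stack, "env1", n_points=50)
        assert np.all(np.diff(rc["logistic"]) >= 0)

    def test_quadratic_model_unimodal_with_vertex_oracle(self, small_stack):
        # plant an optimum at env1 = 0.5 and check the fitted curve peaks
        # near the analytic vertex -b1/(2*b2) of its own coefficients
        truth = TruthModel({"env1": (3.0, -3.0)})
        surf = true_suitability(small_stack, truth)
        occ = sample_occurrences(surf, 200, seed=24)
        bg = sample_background(small_stack, 1000, seed=25)
        model = fit(occ, bg, small_stack.subset(["env1"]),
                    spec=FeatureSpec(types=("linear", "quadratic")))
        rc = response_curve(model, small_stack, "env1", n_points=201)
        # recover raw-space coefficients from the standardized lambdas
        lam = dict(zip(model.feature_names, model.lambdas))
        b1 = lam["env1"] / model.scales[0]
        b2 = lam["env1^2"] / model.scales[1]
        assert b2 < 0
        vertex = -b1 / (2 * b2)
        peak = rc["value"].iloc[int(np.argmax(rc["logistic"].to_numpy()))]
        span = rc["value"].iloc[-1] - rc["value"].iloc[0]
        assert abs(peak - vertex) < 0.05 * span

    def test_unknown_variable_rejected(self, fitted, landscape100):
        model, _ = fitted
        with pytest.raises(ValueError):
            response_curve(model, landscape100, "nope")
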