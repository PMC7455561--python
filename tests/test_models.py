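import numpy as np
import pandas as pd
import pytest

import sdmniche as sn
from sdmniche.models import ModelSpec, fit_model, predict_suitability, response_curve


def null_tables(n_train=400, n_test=1000, seed=0):
    """Presence and background drawn from the same distribution."""
    rng = np.random.default_rng(seed)
    cols = ["a", "b"]
    mk = lambda n: pd.DataFrame(rng.standard_normal((n, 2)), columns=cols)
    return mk(n_train), mk(n_train), mk(n_test), mk(n_test)


class TestFitPredictContract:
    @pytest.mark.parametrize("alg", sn.ALGORITHMS)
    def test_predictions_bounded_and_deterministic(self, alg, training_tables,
                                                   fast_hyperparameters):
        spec = ModelSpec(alg, fast_hyperparameters.get(alg, {}), rng_seed=1)
        m = fit_model(spec, training_tables["train"],
                      training_tables["background"])
        p1 = m.predict_table(training_tables["test"])
        p2 = m.predict_table(training_tables["test"])
        assert p1.min() >= 0.0 and p1.max() <= 1.0
        np.testing.assert_array_equal(p1, p2)

    @pytest.mark.parametrize("alg", sn.ALGORITHMS)
    def test_refit_same_seed_reproduces(self, alg, training_tables,
                                        fast_hyperparameters):
        spec = ModelSpec(alg, fast_hyperparameters.get(alg, {}), rng_seed=1)
        a = fit_model(spec, training_tables["train"],
                      training_tables["background"])
        b = fit_model(spec, training_tables["train"],
                      training_tables["background"])
        np.testing.assert_allclose(a.predict_table(training_tables["test"]),
                                   b.predict_table(training_tables["test"]))

    @pytest.mark.parametrize("alg", ["glm", "gam", "maxent"])
    def test_row_order_invariance_of_deterministic_fits(self, alg,
                                                        training_tables):
        train = training_tables["train"]
        bg = training_tables["background"]
        shuffled = train.sample(frac=1.0, random_state=3)
        a = fit_model(ModelSpec(alg, rng_seed=1), train, bg)
        b = fit_model(ModelSpec(alg, rng_seed=1), shuffled, bg)
        np.testing.assert_allclose(a.predict_table(training_tables["test"]),
                                   b.predict_table(training_tables["test"]),
                                   atol=1e-5)

    def test_constant_predictor_dropped(self, training_tables, caplog):
        train = training_tables["train"].copy()
        bg = training_tables["background"].copy()
        train["flat"] = 1.0
        bg["flat"] = 1.0
        with caplog.at_level("WARNING"):
            m = fit_model(ModelSpec("glm"), train, bg)
        assert "flat" not in m.predictors

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"a": np.arange(5.0)})
        with pytest.raises(ValueError, match="at least 10"):
            fit_model(ModelSpec("glm"), df, df)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            ModelSpec("neural-net")


class TestNullAndSeparableData:
    @pytest.mark.parametrize("alg", sn.ALGORITHMS)
    def test_null_data_auc_near_half(self, alg, fast_hyperparameters):
        """Labels independent of predictors: held-out AUC within 0.5 +/- 0.05."""
        ptr, btr, pte, bte = null_tables(seed=10)
        m = fit_model(ModelSpec(alg, fast_hyperparameters.get(alg, {}),
                                rng_seed=2), ptr, btr)
        a = sn.auc(m.predict_table(pte), m.predict_table(bte))
        assert a == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("alg", sn.ALGORITHMS)
    def test_separable_species_auc_high(self, alg, training_tables):
        """A narrow-niche species is recovered at held-out AUC >= 0.9."""
        m = fit_model(ModelSpec(alg, rng_seed=4), training_tables["train"],
                      training_tables["background"])
        a = sn.auc(m.predict_table(training_tables["test"]),
                   m.predict_table(training_tables["background"]))
        assert a >= 0.9


class TestGlmSpecifics:
    def test_gaussian_niche_yields_interior_optimum(self, training_tables):
        m = fit_model(ModelSpec("glm"), training_tables["train"],
                      training_tables["background"])
        curve = response_curve(m, "bio12")
        lo, hi = m.training_range["bio12"]
        span = hi - lo
        assert lo + 0.05 * span < curve.peak < hi - 0.05 * span
        # concave around the peak: suitability falls toward both range ends
        assert curve.suitability[0] < curve.suitability.max()
        assert curve.suitability[-1] < curve.suitability.max()

    def test_duplicated_training_rows_leave_predictions_unchanged(
            self, training_tables):
        train = training_tables["train"]
        bg = training_tables["background"]
        a = fit_model(ModelSpec("glm"), train, bg)
        b = fit_model(ModelSpec("glm"),
                      pd.concat([train, train], ignore_index=True),
                      pd.concat([bg, bg], ignore_index=True))
        np.testing.assert_allclose(a.predict_table(training_tables["test"]),
                                   b.predict_table(training_tables["test"]),
                                   atol=1e-4)


class TestMaxent:
    def test_background_density_normalizes(self, training_tables):
        m = fit_model(ModelSpec("maxent", rng_seed=1),
                      training_tables["train"], training_tables["background"])
        Z = (training_tables["background"][m.predictors].to_numpy()
             - m.center) / m.scale
        q = m._impl.background_density(Z)
        assert q.sum() == pytest.approx(1.0, abs=1e-6)

    def test_simple_features_below_presence_threshold(self, training_tables):
        few = training_tables["train"].iloc[:40]
        m = fit_model(ModelSpec("maxent", rng_seed=1), few,
                      training_tables["background"])
        assert not m._impl.use_complex


class TestResponseCurve:
    def test_zero_coefficient_gives_flat_curve(self, training_tables):
        m = fit_model(ModelSpec("glm"), training_tables["train"],
                      training_tables["background"])
        # zero out the focal predictor's linear and quadratic coefficients
        j = m.predictors.index("bio6")
        p = len(m.predictors)
        m._impl.coef_[0, j] = 0.0
        m._impl.coef_[0, p + j] = 0.0
        curve = response_curve(m, "bio6")
        assert np.ptp(curve.suitability) == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_vertex_location(self, training_tables):
        """With logit b0 + b1 z + b2 z^2 (b2<0), the peak sits at -b1/(2 b2)."""
        m = fit_model(ModelSpec("glm"), training_tables["train"],
                      training_tables["background"])
        j = m.predictors.index("bio12")
        p = len(m.predictors)
        m._impl.coef_[0, :] = 0.0
        b1, b2 = 1.0, -0.8
        m._impl.coef_[0, j] = b1
        m._impl.coef_[0, p + j] = b2
        curve = response_curve(m, "bio12", grid_size=200)
        z_star = -b1 / (2 * b2)
        x_star = m.center[j] + m.scale[j] * z_star
        step = curve.grid[1] - curve.grid[0]
        assert abs(curve.peak - x_star) <= step

    def test_unknown_predictor_rejected(self, training_tables):
        m = fit_model(ModelSpec("glm"), training_tables["train"],
                      training_tables["background"])
        with pytest.raises(KeyError):
            response_curve(m, "nope")


class TestPredictSuitability:
    def test_raster_path_equals_table_path(self, small_stack, training_tables):
        m = fit_model(ModelSpec("glm"), training_tables["train"],
                      training_tables["background"])
        smap = predict_suitability(m, small_stack)
        ok = small_stack.grid.valid
        table = pd.DataFrame(
            {p: small_stack[p].values[ok] for p in m.predictors})
        np.testing.assert_allclose(smap.grid.values[ok],
                                   m.predict_table(table))

    def test_masked_cells_stay_masked(self, training_tables, grid_factory):
        m = fit_model(ModelSpec("glm"), training_tables["train"],
                      training_tables["background"])
        mask = np.zeros((50, 50), dtype=bool)
        mask[3, 3] = True
        layers = {p: grid_factory(np.full((50, 50), v), mask=mask)
                  for p, v in m.training_mean.items()}
        smap = predict_suitability(m, sn.PredictorStack(layers))
        assert smap.grid.mask[3, 3]

    def test_missing_layer_rejected(self, training_tables, grid_factory):
        m = fit_model(ModelSpec("glm"), training_tables["train"],
                      training_tables["background"])
        stack = sn.PredictorStack({"bio5": grid_factory(np.ones((50, 50)))})
        with pytest.raises(KeyError, match="lacks"):
            predict_suitability(m, stack)


def test_model_archive_roundtrip(tmp_path, training_tables):
    m = fit_model(ModelSpec("maxent", rng_seed=1), training_tables["train"],
                  training_tables["background"])
    path = tmp_path / "model.pkl"
    sn.save_model(m, path)
    back = sn.load_model(path)
    np.testing.assert_array_equal(back.predict_table(training_tables["test"]),
                                  m.predict_table(training_tables["test"]))
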