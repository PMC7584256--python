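"""The effect decomposition: closed forms, oracles, additivity."""

import dataclasses
import logging

import numpy as np
import pytest
from scipy.special import expit

from mltve.effects import (ExposureStep, average_effects, effect_grid,
                           level1_effects, level2_effects,
                           system_effect_summaries)
from mltve.exceptions import ConfigurationError
from mltve.models import fit_system
from mltve.simulate import (Sim1Config, Sim2Config, sim2_transforms,
                            true_system)


@pytest.fixture(scope="module")
def sim1_true():
    return true_system(Sim1Config(seed=5))


@pytest.fixture(scope="module")
def sim2_true():
    return true_system(Sim2Config(seed=6))


@pytest.fixture(scope="module")
def sim1_fit(sim1_data):
    return fit_system(sim1_data)


@pytest.fixture(scope="module")
def sim2_fit(sim2_data):
    return fit_system(sim2_data, sim2_transforms())


class TestLinearClosedForms:
    def test_product_of_coefficients_level1(self, sim1_true):
        """Linear identity system: IE1 = 0.8 x 0.59, DE1 = 0.39 at every record."""
        c = level1_effects(sim1_true, "x1")
        np.testing.assert_allclose(c.de, 0.39, atol=1e-12)
        np.testing.assert_allclose(c.ie["m1"], 0.8 * 0.59, atol=1e-12)
        np.testing.assert_allclose(c.te, 0.39 + 0.472, atol=1e-12)

    def test_constant_direct_effect_nonlinear_design(self, sim2_true):
        c = level1_effects(sim2_true, "x1")
        np.testing.assert_allclose(c.de, 0.98, atol=1e-12)

    def test_level2_indirect_through_level1_mediator(self, sim2_true):
        c = level2_effects(sim2_true, "x2")
        np.testing.assert_allclose(c.ie["m"], 1.2 * 0.98, atol=1e-12)

    def test_zero_outcome_path_zeroes_ie(self):
        sys0 = true_system(Sim1Config(beta3=0.0, seed=5))
        c = level1_effects(sys0, "x1")
        np.testing.assert_allclose(c.ie["m1"], 0.0, atol=1e-15)
        np.testing.assert_allclose(c.te, c.de, atol=1e-15)

    def test_fitted_linear_system_matches_product_of_coefficients(self, sim1_fit):
        """On a fitted all-identity system the decomposition must equal the
        classic product-of-coefficients computation from the coefficients."""
        alpha = sim1_fit.mediator_models["m1"].exposure_coefficients["x1"][0]
        beta3 = sim1_fit.outcome_model.coefficients["m1"][0]
        beta1 = sim1_fit.outcome_model.coefficients["x1"][0]
        c = level1_effects(sim1_fit, "x1")
        np.testing.assert_allclose(c.ie["m1"], alpha * beta3, atol=1e-8)
        np.testing.assert_allclose(c.de, beta1, atol=1e-8)


class TestAdditivity:
    @pytest.mark.parametrize("which", ["sim1", "sim2"])
    def test_te_equals_de_plus_ie_everywhere(self, which, sim1_fit, sim2_fit):
        system = sim1_fit if which == "sim1" else sim2_fit
        for e in system.dataset.roles.exposures_l1:
            c = level1_effects(system, e)
            np.testing.assert_allclose(c.te, c.de + sum(c.ie.values()), atol=1e-10)
            s = average_effects(c)
            assert s.ate == pytest.approx(s.ade + sum(s.aie.values()), abs=1e-10)
        for e in system.dataset.roles.exposures_l2:
            c = level2_effects(system, e)
            np.testing.assert_allclose(c.te, c.de + sum(c.ie.values()), atol=1e-10)

    def test_zeroing_one_mediator_path_touches_only_its_ie(self, sim1_fit):
        before = level2_effects(sim1_fit, "x2")
        out2 = dataclasses.replace(
            sim1_fit.outcome_model,
            coefficients={**sim1_fit.outcome_model.coefficients, "m1": np.array([0.0])})
        system2 = dataclasses.replace(sim1_fit, outcome_model=out2)
        after = level2_effects(system2, "x2")
        np.testing.assert_allclose(after.ie["m1"], 0.0, atol=1e-15)
        np.testing.assert_allclose(after.ie["m2"], before.ie["m2"], atol=1e-12)
        np.testing.assert_allclose(after.de, before.de, atol=1e-12)


class TestNumericOracles:
    def test_logistic_ie_matches_composition_derivative(self, sim1_fit):
        """IE through the logistic group-level third-variable equals the
        numeric derivative of b4 * expit(a0 + a1 x) at each group's x."""
        mm = sim1_fit.mediator_models["m2"]
        a0, a1 = mm.intercept, mm.exposure_coefficients["x2"][0]
        b4 = sim1_fit.outcome_model.coefficients["m2"][0]
        x = sim1_fit.dataset.group_level("x2")
        h = 1e-6
        fd = b4 * (expit(a0 + a1 * (x + h)) - expit(a0 + a1 * (x - h))) / (2 * h)
        c = level2_effects(sim1_fit, "x2")
        np.testing.assert_allclose(c.ie["m2"], fd, atol=1e-6)

    def test_total_effect_matches_full_composition_derivative(self, sim2_fit):
        """Differentiating the fitted composition E[Y](x) with the mediator
        propagated through its fitted model reproduces TE1 at random points
        (identity links), verifying the closed forms against the definitions."""
        system = sim2_fit
        mm = system.mediator_models["m"]
        out = system.outcome_model
        tr_out = system.design.outcome["f1e"]["x1"].transform
        tr_med = system.design.mediator["m"]["f1ke1"]["x1"].transform

        def h(x):
            mu = (tr_med.values(x) @ mm.exposure_coefficients["x1"])  # + const, drops out
            return (tr_out.values(x) @ out.coefficients["x1"]
                    + out.coefficients["m"][0] * mu)

        rng = np.random.default_rng(3)
        xs = rng.uniform(-1.2, 1.2, 20)
        eps = 1e-6
        fd = (h(xs + eps) - h(xs - eps)) / (2 * eps)
        te = effect_grid(system, "x1", xs, step=ExposureStep("x1", "continuous")).te
        np.testing.assert_allclose(te, fd, rtol=1e-4)


class TestAverages:
    def test_constant_curves_average_to_constants(self, sim1_true):
        s = average_effects(level1_effects(sim1_true, "x1"))
        assert s.ade == pytest.approx(0.39, abs=1e-12)
        assert s.aie["m1"] == pytest.approx(0.472, abs=1e-12)
        assert s.relative_effects["de"] == pytest.approx(0.39 / 0.862, abs=1e-10)
        assert sum(s.relative_effects.values()) == pytest.approx(1.0, abs=1e-10)

    def test_linear_in_x_curve_averages_arithmetically(self, sim2_true):
        c = level1_effects(sim2_true, "x1")
        x = sim2_true.dataset.column("x1")
        # IE1(x) = 0.98 (1.2 + 2.4 x), so TE1 averages to 0.98 + 1.176 + 2.352 mean(x)
        expected = 0.98 + 0.98 * (1.2 + 2.4 * x.mean())
        assert average_effects(c).ate == pytest.approx(expected, abs=1e-10)

    def test_zero_total_effect_has_undefined_relative_effects(self):
        sys0 = true_system(Sim1Config(beta1=0.0, beta3=0.0, seed=5))
        s = average_effects(level1_effects(sys0, "x1"))
        assert s.ate == pytest.approx(0.0, abs=1e-12)
        assert s.relative_effects is None


class TestEffectGrid:
    def test_reciprocal_direct_effect_on_grid(self, sim2_true):
        c = effect_grid(sim2_true, "x2", [1.0, 2.0, 4.0])
        np.testing.assert_allclose(c.de, [0.98, 0.49, 0.245], atol=1e-12)

    def test_linear_system_constant_on_any_grid(self, sim1_true):
        c = effect_grid(sim1_true, "x1", [0.0, 1.0], step=ExposureStep("x1", "discrete"))
        assert np.ptp(c.te) == pytest.approx(0.0, abs=1e-12)

    def test_empty_grid_rejected(self, sim1_true):
        with pytest.raises(ConfigurationError):
            effect_grid(sim1_true, "x2", [])

    def test_extrapolation_warns_but_computes(self, sim2_true, caplog):
        xmax = sim2_true.dataset.group_level("x2").max()
        with caplog.at_level(logging.WARNING, logger="mltve.effects"):
            c = effect_grid(sim2_true, "x2", [xmax + 5.0])
        assert np.isfinite(c.te).all()
        assert any("beyond the observed range" in r.message for r in caplog.records)


class TestContracts:
    def test_level_mismatch_rejected(self, sim1_true):
        with pytest.raises(ConfigurationError):
            level1_effects(sim1_true, "x2")
        with pytest.raises(ConfigurationError):
            level2_effects(sim1_true, "x1")

    def test_binary_exposure_uses_unit_step(self, sim2_true):
        # forcing a discrete step on the quadratic path changes IE1:
        # unit difference of (x, x^2) is (1, 2x + 1), not (1, 2x)
        cont = level1_effects(sim2_true, "x1", ExposureStep("x1", "continuous"))
        disc = level1_effects(sim2_true, "x1", ExposureStep("x1", "discrete"))
        x = sim2_true.dataset.column("x1")
        np.testing.assert_allclose(disc.ie["m"] - cont.ie["m"], 0.98 * 1.2, atol=1e-10)
        np.testing.assert_allclose(cont.ie["m"], 0.98 * (1.2 + 2.4 * x), atol=1e-10)

    def test_flat_summary_component_names(self, sim1_fit):
        keys = set(system_effect_summaries(sim1_fit))
        assert keys == {"te1", "de1", "ie1:m1", "te2", "de2", "ie2.1:m1", "ie2.2:m2"}
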