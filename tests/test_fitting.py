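import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aneumech import (
    CoefficientSet,
    FitOptions,
    GeneratorConfig,
    Model,
    TensileCurve,
    design_matrix,
    fit_model,
    generate_curve,
    linear_part,
    nrmse,
    tables,
    uniaxial_stress,
)
from aneumech.errors import DomainError, UndefinedNormalizationError, ValidationError
from aneumech.fitting import constraint_matrix

from conftest import max_rel_err, reference_curve

NO_CONSTRAINTS = FitOptions(enforce_stability=False, enforce_linear_part=False)


def is_feasible(coeffs: CoefficientSet, options: FitOptions = FitOptions()) -> bool:
    g, _ = constraint_matrix(coeffs.model, options)
    return g.shape[0] == 0 or bool(np.all(g @ np.asarray(coeffs.coefficients) >= -1e-8))


class TestDesignMatrix:
    def test_neo_hookean_hand_values(self):
        mat = design_matrix(Model.NEO_HOOKEAN, (1.0, 2.0))
        assert mat.shape == (2, 1)
        assert mat[:, 0] == pytest.approx([0.0, 3.5])

    @pytest.mark.parametrize("model", list(Model))
    def test_column_count(self, model):
        assert design_matrix(model, np.linspace(1, 2, 5)).shape == (5, model.n_coeffs)

    def test_yeoh_first_column_is_neo_hookean(self):
        lam = np.linspace(1.0, 3.0, 9)
        assert design_matrix(Model.YEOH, lam)[:, 0] == pytest.approx(
            design_matrix(Model.NEO_HOOKEAN, lam)[:, 0]
        )

    @pytest.mark.parametrize("model", list(Model))
    def test_product_equals_model_stress(self, model):
        rng = np.random.default_rng(7)
        lam = np.linspace(1.0, 2.5, 11)
        for _ in range(5):
            coeffs = tuple(rng.normal(0, 0.5, model.n_coeffs))
            cs = CoefficientSet(model, coeffs)
            product = design_matrix(model, lam) @ np.asarray(coeffs)
            assert product == pytest.approx(uniaxial_stress(cs, lam), abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            design_matrix(Model.MR3, (0.0, 1.0))


class TestNrmse:
    def test_perfect_prediction(self):
        assert nrmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_value(self):
        assert nrmse([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(
            np.sqrt(1.0 / 3.0) / 2.0
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(UndefinedNormalizationError):
            nrmse([1.0, -1.0], [0.0, 0.0])

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            nrmse([1.0], [1.0, 2.0])


class TestParameterRecovery:
    @pytest.mark.parametrize(
        "sid,model,tol",
        [
            ("K2", Model.NEO_HOOKEAN, 1e-6),
            ("Z", Model.YEOH, 1e-4),
            ("V", Model.MR3, 1e-3),
            ("Z", Model.MR5, 1e-3),
        ],
    )
    def test_published_rows(self, sid, model, tol):
        truth = tables.reference_coefficients(sid, model)
        result = fit_model(reference_curve(sid, model), model)
        assert max_rel_err(result.coefficients.coefficients, truth.coefficients) < tol
        assert result.nrmse < 1e-6

    def test_every_feasible_published_row(self, aneurysm_ids):
        options = FitOptions()
        for sid in aneurysm_ids:
            for model in Model:
                truth = tables.reference_coefficients(sid, model)
                if not is_feasible(truth, options):
                    continue
                result = fit_model(reference_curve(sid, model), model, options)
                tol = 1e-6 if model is Model.NEO_HOOKEAN else 1e-3
                err = max_rel_err(result.coefficients.coefficients, truth.coefficients)
                assert err < tol, (sid, model, err)

    def test_noise_robustness_neo_hookean(self):
        truth = 0.0615
        errors = []
        sigma_max = uniaxial_stress(
            CoefficientSet(Model.NEO_HOOKEAN, (truth,)), 1.81725
        )
        for seed in range(200):
            config = GeneratorConfig(
                coefficients=CoefficientSet(Model.NEO_HOOKEAN, (truth,)),
                lambda_max=1.81725,
                n_points=200,
                noise_sd=0.01 * sigma_max,
                seed=seed,
            )
            result = fit_model(generate_curve(config), Model.NEO_HOOKEAN)
            errors.append(abs(result.coefficients[0] - truth) / truth)
        assert np.median(errors) < 0.05


class TestConstrainedFit:
    def test_k1_mr5_linear_part_constraint_activates(self):
        curve = reference_curve("K1", Model.MR5)
        result = fit_model(curve, Model.MR5)
        assert "linear_part>=0" in result.active_constraints
        assert linear_part(result.coefficients) >= -1e-8
        assert result.nrmse > 0

    def test_k1_mr5_beats_random_feasible_points(self):
        curve = reference_curve("K1", Model.MR5)
        options = FitOptions()
        result = fit_model(curve, Model.MR5, options)
        g, _ = constraint_matrix(Model.MR5, options)
        a = design_matrix(Model.MR5, curve.stretch)
        x_opt = np.asarray(result.coefficients.coefficients)
        rng = np.random.default_rng(11)
        tried = 0
        while tried < 2000:
            x = x_opt + rng.normal(0, 0.02, 5)
            if np.all(g @ x >= 0):
                tried += 1
                assert np.sum((a @ x - curve.stress_MPa) ** 2) >= result.residual_ss - 1e-12

    def test_monotone_residual_when_relaxing(self):
        curve = reference_curve("K1", Model.MR5)
        constrained = fit_model(curve, Model.MR5, FitOptions())
        relaxed = fit_model(curve, Model.MR5, NO_CONSTRAINTS)
        assert relaxed.residual_ss <= constrained.residual_ss + 1e-15

    def test_too_few_points(self):
        curve = TensileCurve(np.array([1.0, 1.5]), np.array([0.0, 0.5]))
        with pytest.raises(ValidationError):
            fit_model(curve, Model.MR3)

    def test_deterministic(self):
        curve = reference_curve("K1", Model.MR5)
        r1 = fit_model(curve, Model.MR5)
        r2 = fit_model(curve, Model.MR5)
        assert r1.coefficients.coefficients == r2.coefficients.coefficients


class TestGridOracle:
    """Constrained optimum must beat every feasible point of a brute-force
    coefficient grid (small instances, <= 3 coefficients)."""

    def _grid_best(self, a, b, g, centers, pitch, steps=7):
        axes = [c + pitch * np.arange(-steps, steps + 1) for c in centers]
        best = np.inf
        for point in itertools.product(*axes):
            x = np.asarray(point)
            if g.shape[0] and not np.all(g @ x >= 0):
                continue
            best = min(best, float(np.sum((a @ x - b) ** 2)))
        return best

    def test_neo_hookean_negative_trend(self):
        # decreasing data pulls C1 negative; constraint clamps it at zero
        lam = np.linspace(1.0, 2.0, 12)
        curve = TensileCurve(lam, -0.1 * (lam - 1.0))
        options = FitOptions()
        result = fit_model(curve, Model.NEO_HOOKEAN, options)
        assert result.coefficients[0] == pytest.approx(0.0, abs=1e-9)
        assert result.active_constraints == ("linear_part>=0",)
        unconstrained = fit_model(curve, Model.NEO_HOOKEAN, NO_CONSTRAINTS)
        assert unconstrained.coefficients[0] < 0

    @pytest.mark.parametrize("model", [Model.YEOH, Model.MR3])
    def test_constrained_fit_beats_grid(self, model):
        rng = np.random.default_rng(5)
        lam = np.linspace(1.0, 1.8, 25)
        # data that the feasible set cannot fit perfectly
        sig = 0.05 * (lam - 1.0) - 0.2 * (lam - 1.0) ** 2 + rng.normal(0, 0.002, lam.size)
        curve = TensileCurve(lam, sig)
        options = FitOptions()
        result = fit_model(curve, model, options)
        g, _ = constraint_matrix(model, options)
        a = design_matrix(model, lam)
        # grid pitch 0.005 around the solver optimum, 7 steps per side
        best_grid = self._grid_best(
            a, curve.stress_MPa, g, result.coefficients.coefficients, pitch=0.005
        )
        assert result.residual_ss <= best_grid + 1e-12


@given(
    st.lists(st.floats(0.01, 1.0), min_size=4, max_size=8, unique=True),
    st.floats(0.01, 0.5),
)
@settings(max_examples=25, deadline=None)
def test_fit_reproduces_exact_neo_hookean_data(strains, c1):
    lam = np.sort(1.0 + np.asarray(strains))
    cs = CoefficientSet(Model.NEO_HOOKEAN, (c1,))
    curve = TensileCurve(lam, uniaxial_stress(cs, lam))
    result = fit_model(curve, Model.NEO_HOOKEAN)
    assert result.coefficients[0] == pytest.approx(c1, rel=1e-9)
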