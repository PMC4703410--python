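"""Unit and property tests for the two-parameter constitutive surface and
its Model/Results fitting machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liverrheo.constitutive import (
    CompressionShearModel,
    ConstitutiveParams,
    ModelShape,
    axial_stress_model,
    fit_params,
    loss_modulus_model,
    predict_protocol,
    softening_factor,
    storage_modulus_model,
    youngs_modulus_model,
)
from liverrheo.exceptions import IdentifiabilityError, ValidationError
from liverrheo.phantom import CONDITION_PRESETS

PARAMS = ConstitutiveParams(C1=1000.0, C2=250.0)
SHAPE = ModelShape()


class TestAxialStress:
    def test_zero_strain_reference_state(self):
        assert axial_stress_model(0.0, PARAMS, SHAPE) == 0.0

    def test_direct_evaluation_at_quarter_compression(self):
        # C2 (e^{b*0.25} - 1) with b=8 -> 250 (e^2 - 1)
        expected = 250.0 * (math.e**2 - 1.0)
        assert axial_stress_model(-0.25, PARAMS, SHAPE) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(1597.2, abs=0.1)

    def test_tension_response_is_bounded_by_minus_c2(self):
        assert axial_stress_model(5.0, PARAMS, SHAPE) == pytest.approx(
            -PARAMS.C2, rel=1e-9
        )

    @given(lam=st.floats(-0.4, 0.4))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_in_lam(self, lam):
        eps = 1e-4
        assert axial_stress_model(lam, PARAMS, SHAPE) > axial_stress_model(
            lam + eps, PARAMS, SHAPE
        )


class TestYoungsModulus:
    def test_derivative_at_origin_is_b_times_c2(self):
        assert youngs_modulus_model(0.0, PARAMS, SHAPE) == pytest.approx(
            SHAPE.b * PARAMS.C2
        )

    def test_analytic_stiffening_ratio_e_squared(self):
        ratio = youngs_modulus_model(-0.25, PARAMS, SHAPE) / youngs_modulus_model(
            0.0, PARAMS, SHAPE
        )
        assert ratio == pytest.approx(math.e**2, rel=1e-12)

    def test_matches_finite_difference_of_stress(self):
        # E = -d sigma/d lam, central difference oracle
        for lam in (-0.25, -0.1, 0.0, 0.1, 0.2):
            h = 1e-6
            fd = -(
                axial_stress_model(lam + h, PARAMS, SHAPE)
                - axial_stress_model(lam - h, PARAMS, SHAPE)
            ) / (2 * h)
            assert youngs_modulus_model(lam, PARAMS, SHAPE) == pytest.approx(
                fd, rel=1e-6
            )


class TestStorageModulus:
    def test_low_strain_zero_compression_is_c1(self):
        assert storage_modulus_model(1e-9, 0.0, PARAMS, SHAPE) == pytest.approx(
            PARAMS.C1, rel=1e-6
        )

    def test_affine_in_axial_stress_at_fixed_low_gamma(self):
        # on the low-strain plateau G' = C1 + m*sigma to high accuracy
        lams = np.array([0.0, -0.10, -0.15, -0.20, -0.25])
        sig = axial_stress_model(lams, PARAMS, SHAPE)
        gp = storage_modulus_model(0.02, lams, PARAMS, SHAPE)
        expected = PARAMS.C1 + SHAPE.m * sig
        assert np.allclose(gp, expected, rtol=2e-3)

    def test_half_point_at_effective_softening_strain(self):
        lam = -0.15
        sig = float(axial_stress_model(lam, PARAMS, SHAPE))
        gamma_eff = SHAPE.gamma_c * (1 + sig / SHAPE.sigma_ref)
        plateau = PARAMS.C1 + SHAPE.m * sig
        assert storage_modulus_model(gamma_eff, lam, PARAMS, SHAPE) == pytest.approx(
            plateau / 2.0, rel=1e-12
        )

    def test_loss_modulus_is_fixed_fraction(self):
        gp = storage_modulus_model(0.1, -0.2, PARAMS, SHAPE)
        gpp = loss_modulus_model(0.1, -0.2, PARAMS, SHAPE)
        assert gpp == pytest.approx(SHAPE.tan_delta * gp, rel=1e-12)

    @given(
        lam=st.floats(-0.3, -0.01),
        gamma=st.floats(0.01, 0.5),
    )
    @settings(max_examples=80, deadline=None)
    def test_compression_stiffening_everywhere(self, lam, gamma):
        assert storage_modulus_model(gamma, lam, PARAMS, SHAPE) > (
            storage_modulus_model(gamma, 0.0, PARAMS, SHAPE)
        )

    def test_tension_softening(self):
        assert storage_modulus_model(0.02, 0.20, PARAMS, SHAPE) < (
            storage_modulus_model(0.02, 0.0, PARAMS, SHAPE)
        )
        assert youngs_modulus_model(0.20, PARAMS, SHAPE) < youngs_modulus_model(
            0.0, PARAMS, SHAPE
        )

    def test_shear_softening_strictly_decreasing(self):
        g = np.linspace(0.01, 0.5, 40)
        gp = storage_modulus_model(g, 0.0, PARAMS, SHAPE)
        assert np.all(np.diff(gp) < 0)

    def test_softening_flattens_under_compression(self):
        # end-to-start ratio closer to 1 when compressed
        def end_ratio(lam):
            return storage_modulus_model(0.45, lam, PARAMS, SHAPE) / (
                storage_modulus_model(0.01, lam, PARAMS, SHAPE)
            )

        assert end_ratio(-0.25) > end_ratio(0.0)

    def test_softening_disabled_gives_flat_sweeps(self):
        shape = ModelShape(softening_enabled=False)
        g = np.linspace(0.01, 0.5, 10)
        gp = storage_modulus_model(g, 0.0, PARAMS, shape)
        assert np.allclose(gp, gp[0])

    def test_e_over_g_stays_at_most_tenfold_on_presets(self):
        for preset in CONDITION_PRESETS.values():
            p = ConstitutiveParams(preset["C1"], preset["C2"])
            sh = ModelShape(
                softening_enabled=preset.get("softening_enabled", True)
            )
            for lam in np.linspace(-0.25, 0.0, 11):
                e = float(youngs_modulus_model(lam, p, sh))
                gp = float(storage_modulus_model(0.02, lam, p, sh))
                assert e <= 10.0 * gp


class TestValidation:
    def test_nonpositive_c1_rejected(self):
        with pytest.raises(ValidationError):
            ConstitutiveParams(C1=-5.0, C2=10.0)

    def test_negative_c2_rejected(self):
        with pytest.raises(ValidationError):
            ConstitutiveParams(C1=100.0, C2=-1.0)

    def test_bad_shape_rejected(self):
        with pytest.raises(ValidationError):
            ModelShape(gamma_c=0.0)


class TestPredictProtocol:
    def test_lambda_grid_gives_five_row_table(self):
        tab = predict_protocol(PARAMS, SHAPE)
        assert len(tab) == 5
        assert set(tab["lam"]) == {0.0, -0.10, -0.15, -0.20, -0.25}

    def test_predictions_reproduce_surface_pointwise(self):
        tab = predict_protocol(PARAMS, SHAPE, gamma_grid=[0.02, 0.2])
        direct = storage_modulus_model(
            tab["gamma0"].to_numpy(), tab["lam"].to_numpy(), PARAMS, SHAPE
        )
        assert np.allclose(tab["Gp_act_pa"], direct, rtol=1e-14)

    def test_signs_of_stiffening_and_softening(self):
        tab = predict_protocol(PARAMS, SHAPE, gamma_grid=[0.02])
        tab = tab.sort_values("lam")  # most compressed first
        assert tab["Gp_act_pa"].is_monotonic_decreasing
        sweep = predict_protocol(
            PARAMS, SHAPE, lam_levels=[0.0], gamma_grid=np.linspace(0.01, 0.5, 11)
        )
        assert sweep["Gp_act_pa"].is_monotonic_decreasing


class TestFitting:
    def _tables(self, params, gamma_grid=(0.01, 0.05, 0.2, 0.4)):
        tab = predict_protocol(params, SHAPE, gamma_grid=gamma_grid)
        return tab

    def test_noiseless_round_trip_is_exact(self):
        tab = self._tables(PARAMS)
        model = CompressionShearModel(
            tab["Gp_act_pa"], tab["gamma0"], tab["lam"],
            tab["sigma_act_pa"], tab["lam"],
        )
        res = model.fit()
        assert res.params.C1 == pytest.approx(PARAMS.C1, rel=1e-6)
        assert res.params.C2 == pytest.approx(PARAMS.C2, rel=1e-6)
        assert res.converged

    def test_fit_params_wrapper_on_sweep_table(self):
        tab = self._tables(ConstitutiveParams(2000.0, 500.0))
        params, diag = fit_params(tab)
        assert params.C1 == pytest.approx(2000.0, rel=1e-5)
        assert params.C2 == pytest.approx(500.0, rel=1e-5)
        assert diag["converged"] and diag["n_points"] == len(tab) + 5

    def test_single_axial_level_raises_identifiability_error(self):
        tab = predict_protocol(
            PARAMS, SHAPE, lam_levels=[0.0], gamma_grid=[0.01, 0.1, 0.3]
        )
        with pytest.raises(IdentifiabilityError):
            CompressionShearModel(tab["Gp_act_pa"], tab["gamma0"], tab["lam"])

    def test_all_zero_gprime_rejected(self):
        with pytest.raises(ValidationError):
            CompressionShearModel(
                [0.0, 0.0, 0.0],
                [0.01, 0.1, 0.3],
                [0.0, -0.1, -0.2],
            )

    def test_summary_contains_estimates(self):
        tab = self._tables(PARAMS)
        res = CompressionShearModel.from_records(tab).fit()
        text = res.summary()
        assert "C1" in text and "C2" in text and "Converged" in text
        assert res.bse["C1"] >= 0.0
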