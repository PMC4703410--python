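"""Synthetic rheometer: determinism, closure, noise scaling and protocol
structure."""

import numpy as np
import pytest

from liverrheo.constitutive import storage_modulus_model
from liverrheo.exceptions import ValidationError
from liverrheo.oscillation import extract_sweep
from liverrheo.phantom import make_phantom
from liverrheo.protocol import ProtocolSpec
from liverrheo.simulate import (
    simulate_compression_series,
    simulate_reversibility_cycles,
    simulate_strain_sweep,
    simulate_stress_relaxation,
    simulate_time_sweep,
)


class TestTimeSweep:
    def test_noiseless_extraction_returns_surface_exactly(self, quiet_phantom):
        params, shape = quiet_phantom.constitutive()
        rec = extract_sweep(simulate_time_sweep(quiet_phantom))[-1]
        expected = float(storage_modulus_model(0.02, 0.0, params, shape))
        assert rec.Gp_meas == pytest.approx(expected, rel=1e-10)
        assert rec.Gpp_meas == pytest.approx(0.2 * expected, rel=1e-10)

    def test_same_seed_bit_identical_traces(self, normal_phantom):
        a = simulate_time_sweep(normal_phantom)
        b = simulate_time_sweep(normal_phantom)
        assert a.data.equals(b.data)
        assert a.metadata == b.metadata

    def test_compression_raises_stress_amplitude(self, quiet_phantom):
        flat = simulate_time_sweep(quiet_phantom, lam=0.0)
        comp = simulate_time_sweep(quiet_phantom, lam=-0.25)
        # measured amplitude: corrected modulus rises faster than the
        # (1+lam)^2 reporting factor shrinks it at these presets
        assert np.mean(np.abs(comp.shear_stress)) > np.mean(
            np.abs(flat.shear_stress)
        )

    def test_gap_tracks_axial_strain(self, quiet_phantom):
        comp = simulate_time_sweep(quiet_phantom, lam=-0.25)
        assert np.allclose(comp.gap, quiet_phantom.height * 0.75)
        tens = simulate_time_sweep(quiet_phantom, lam=0.20)
        assert np.allclose(tens.gap, quiet_phantom.height * 1.20)

    def test_invalid_frequency_rejected(self, quiet_phantom):
        with pytest.raises(ValidationError):
            ProtocolSpec.time_sweep(omega=0.0)


class TestStrainSweep:
    def test_noiseless_gprime_strictly_decreasing(self, quiet_phantom):
        recs = extract_sweep(simulate_strain_sweep(quiet_phantom))
        gp = [r.Gp_meas for r in recs]
        assert all(a > b for a, b in zip(gp, gp[1:]))

    def test_decellularized_sweep_flat(self, quiet_decel_phantom):
        recs = extract_sweep(simulate_strain_sweep(quiet_decel_phantom))
        gp = np.array([r.Gp_meas for r in recs])
        assert np.allclose(gp, gp[0], rtol=1e-9)

    def test_empty_strain_grid_rejected(self):
        with pytest.raises(ValidationError):
            ProtocolSpec.strain_sweep(grid=())


class TestCompressionSeries:
    def test_default_levels_give_five_compression_states(self, quiet_phantom):
        traces = simulate_compression_series(quiet_phantom)
        lams = {t.metadata["lam"] for t in traces}
        assert lams == {0.0, -0.10, -0.15, -0.20, -0.25}
        kinds = [t.metadata["segment_kind"] for t in traces]
        assert kinds == ["time_sweep", "strain_sweep"] * 5

    def test_tension_levels_increase_gap(self, quiet_phantom):
        proto = ProtocolSpec.tension_series()
        traces = simulate_compression_series(quiet_phantom, protocol=proto)
        gaps = {t.metadata["lam"]: t.gap[0] for t in traces}
        h = quiet_phantom.height
        assert gaps[0.10] == pytest.approx(1.10 * h)
        assert gaps[0.20] == pytest.approx(1.20 * h)

    def test_normal_force_near_equilibrium_at_120s(self, quiet_phantom):
        """After the axial step the Prony transient has decayed at 120 s:
        the corrected axial stress equals the surface's equilibrium value
        within 2%."""
        from liverrheo.constitutive import axial_stress_model
        from liverrheo.corrections import correct_axial_stress, preload_stress

        params, shape = quiet_phantom.constitutive()
        trace = simulate_time_sweep(quiet_phantom, lam=-0.25)
        rec = extract_sweep(trace)[-1]
        sigma_eq = float(axial_stress_model(-0.25, params, shape))
        sigma_act = float(correct_axial_stress(rec.sigma_meas, -0.25))
        sigma_net = sigma_act - preload_stress(10.0, quiet_phantom.diameter)
        assert sigma_net == pytest.approx(sigma_eq, rel=0.02)


class TestStressRelaxation:
    def test_diameter_invariance_of_normalized_curves(self, quiet_phantom):
        # preload_g=0 isolates the relaxation kinetics of the deformation
        # stress; the preload offset itself scales with 1/area by definition
        for mode in ("compression_25", "shear_25"):
            a = simulate_stress_relaxation(quiet_phantom, 8.0, mode, 300.0,
                                           preload_g=0.0)
            b = simulate_stress_relaxation(quiet_phantom, 20.0, mode, 300.0,
                                           preload_g=0.0)
            if mode == "compression_25":
                sa = a.normal_force / a.normal_force[0]
                sb = b.normal_force / b.normal_force[0]
            else:
                sa = a.shear_stress / a.shear_stress[0]
                sb = b.shear_stress / b.shear_stress[0]
            assert np.allclose(sa, sb, rtol=1e-12)

    def test_long_time_limit_is_equilibrium_fraction_of_initial(self, quiet_phantom):
        tr = simulate_stress_relaxation(quiet_phantom, 20.0, "shear_25", 1200.0)
        ratio = tr.shear_stress[-1] / tr.shear_stress[0]
        assert ratio == pytest.approx(quiet_phantom.equilibrium_fraction, rel=1e-6)

    def test_zero_duration_rejected(self, quiet_phantom):
        with pytest.raises(ValidationError):
            simulate_stress_relaxation(quiet_phantom, duration=0.0)

    def test_unknown_mode_rejected(self, quiet_phantom):
        with pytest.raises(ValidationError):
            simulate_stress_relaxation(quiet_phantom, mode="torsion")


class TestReversibility:
    def test_three_cycles_give_three_up_and_three_down(self, quiet_phantom):
        traces = simulate_reversibility_cycles(quiet_phantom, 3)
        assert len(traces) == 6
        dirs = [t.metadata["direction"] for t in traces]
        assert dirs == ["up", "down"] * 3

    def test_one_time_stiffening_then_stable(self, quiet_phantom):
        traces = simulate_reversibility_cycles(quiet_phantom, 3)
        low_gp = {}
        for tr in traces:
            if tr.metadata["direction"] != "up":
                continue
            recs = extract_sweep(tr)
            low_gp[tr.metadata["cycle"]] = min(
                recs, key=lambda r: r.gamma0
            ).Gp_meas
        assert low_gp[2] / low_gp[1] == pytest.approx(1.05, rel=1e-9)
        assert low_gp[3] / low_gp[2] == pytest.approx(1.0, rel=1e-9)
        assert low_gp[2] >= low_gp[1]

    def test_invalid_cycle_count_rejected(self, quiet_phantom):
        with pytest.raises(ValidationError):
            simulate_reversibility_cycles(quiet_phantom, 0)


class TestNoiseModel:
    def test_extracted_gprime_cv_matches_noise_cv(self):
        """Sample CV of repeated extracted G' approaches the configured
        noise CV (one multiplicative factor per measurement plateau)."""
        ph = make_phantom("normal", {"noise_cv": 0.05}, seed=3)
        values = []
        k = 0
        while len(values) < 200:
            trace = simulate_time_sweep(ph, rng=ph.rng(stream=100 + k))
            values.extend(r.Gp_meas for r in extract_sweep(trace))
            k += 1
        values = np.array(values[:200])
        cv = values.std(ddof=1) / values.mean()
        assert cv == pytest.approx(0.05, rel=0.20)

    def test_loss_ratio_immune_to_amplitude_noise(self, normal_phantom):
        recs = extract_sweep(simulate_time_sweep(normal_phantom))
        ratios = [r.Gpp_meas / r.Gp_meas for r in recs]
        assert np.allclose(ratios, 0.2, rtol=1e-9)
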