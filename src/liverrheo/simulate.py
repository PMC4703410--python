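"""Synthetic rheometer: seeded, noisy traces for every protocol segment.

The generator is a lumped-sample instrument emulator.  For each measurement
plateau it evaluates the phantom's constitutive surface at the active
(shear amplitude, axial strain), converts the *actual* moduli and axial
stress into the *measured* values the instrument would report against the
reference geometry (the exact inverse of the geometric corrections, so that
extraction followed by correction closes on the generating surface), and
writes out sinusoidal waveforms:

    stress(t) = f * gamma0 * (G'_meas sin(omega t') + G''_meas cos(omega t'))

with ``f`` a log-normal noise factor of coefficient of variation
``noise_cv`` drawn once per plateau (so both moduli and their ratio behave
like repeat measurements).  The normal-force channel carries the preload
offset plus the equilibrium axial stress of the surface, approached through
a two-mode Prony transient after each axial step, plus additive Gaussian
transducer noise.  Stress-relaxation kinetics are by construction
independent of punch diameter: the emulator encodes a tissue whose global
poroelastic (size-dependent) relaxation is negligible.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict

import numpy as np
import pandas as pd

from .constitutive import axial_stress_model, storage_modulus_model
from .corrections import preload_stress
from .exceptions import ValidationError
from .io import RheometerTrace
from .phantom import TissuePhantom
from .protocol import ProtocolSpec

__all__ = [
    "simulate_time_sweep",
    "simulate_strain_sweep",
    "simulate_compression_series",
    "simulate_stress_relaxation",
    "simulate_reversibility_cycles",
]

#: Samples per oscillation period within a measurement plateau.
POINTS_PER_CYCLE = 64
#: Oscillation periods recorded per measurement plateau.
CYCLES_PER_WINDOW = 2


def _jsonable(obj) -> dict:
    return json.loads(json.dumps(obj))


def _phantom_meta(phantom: TissuePhantom) -> dict:
    return _jsonable(asdict(phantom))


def _protocol_meta(protocol: ProtocolSpec) -> dict:
    return _jsonable(asdict(protocol))


def _relax_multiplier(phantom: TissuePhantom, t_since_step):
    """Normal-force transient: 1 + sum_i (g_i/g_inf) exp(-t/tau_i).

    Multiplies the equilibrium axial stress; tends to 1 as t -> inf and to
    1/g_inf immediately after the step.
    """
    t = np.asarray(t_since_step, dtype=float)
    g_inf = phantom.equilibrium_fraction
    out = np.ones_like(t)
    for g_i, tau in zip(phantom.relax_fractions, phantom.relax_times):
        out = out + (g_i / g_inf) * np.exp(-t / tau)
    return out


def _prony_relaxation(phantom: TissuePhantom, t):
    """Normalized relaxation function R(t) = g_inf + sum g_i exp(-t/tau_i)."""
    t = np.asarray(t, dtype=float)
    out = np.full_like(t, phantom.equilibrium_fraction)
    for g_i, tau in zip(phantom.relax_fractions, phantom.relax_times):
        out = out + g_i * np.exp(-t / tau)
    return out


def _measured_moduli(phantom: TissuePhantom, gamma0: float, lam: float,
                     modulus_factor: float = 1.0) -> tuple[float, float]:
    """Actual surface moduli mapped to what the instrument reports."""
    params, shape = phantom.constitutive()
    gp_act = float(storage_modulus_model(gamma0, lam, params, shape))
    gp_act *= modulus_factor
    area_corr = (1.0 + lam) ** 2
    return gp_act / area_corr, phantom.loss_ratio * gp_act / area_corr


def _normal_force(phantom: TissuePhantom, lam: float, t_since_step,
                  preload_g: float):
    """Raw normal-force channel, N (before additive noise).

    The true axial stress is the preload offset plus the surface's
    equilibrium stress scaled by the Prony transient; the instrument reading
    is the measured (reference-geometry) stress times the reference area.
    """
    params, shape = phantom.constitutive()
    sigma_true = (
        preload_stress(preload_g, phantom.diameter)
        + float(axial_stress_model(lam, params, shape))
        * _relax_multiplier(phantom, t_since_step)
    )
    sigma_meas = sigma_true / (1.0 + lam) ** 2
    area0 = math.pi * (phantom.diameter / 2.0 * 1e-3) ** 2
    return sigma_meas * area0


def _noise_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean log-normal multiplicative factor with the given CV."""
    s2 = math.log1p(cv * cv)
    return float(rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2)))


def _windows(starts, omega: float):
    period = 2.0 * math.pi / omega
    n = CYCLES_PER_WINDOW * POINTS_PER_CYCLE
    dt = period / POINTS_PER_CYCLE
    return [(float(t0), t0 + np.arange(n) * dt) for t0 in starts]


def _build_trace(phantom, protocol, plateaus, lam, t_since_step0,
                 rng, kind, extra_meta=None, modulus_factor=1.0):
    """Assemble a trace from a list of (t_start, gamma0) plateaus."""
    omega = protocol.shear_frequency
    t_parts, strain_parts, stress_parts, force_parts = [], [], [], []
    segments = []
    idx = 0
    for t0, gamma0 in plateaus:
        _, t = _windows([t0], omega)[0]
        theta = omega * (t - t0)
        gp_m, gpp_m = _measured_moduli(phantom, gamma0, lam, modulus_factor)
        f = _noise_factor(rng, phantom.noise_cv)
        strain = gamma0 * np.sin(theta)
        stress = f * gamma0 * (gp_m * np.sin(theta) + gpp_m * np.cos(theta))
        force = _normal_force(phantom, lam, t_since_step0 + t, protocol.preload_mass)
        force = force + rng.normal(0.0, phantom.normal_force_sd, size=t.size)
        segments.append({
            "start": idx, "stop": idx + t.size, "gamma0": gamma0,
            "omega": omega, "lam": lam, "t_label": t0,
        })
        idx += t.size
        t_parts.append(t)
        strain_parts.append(strain)
        stress_parts.append(stress)
        force_parts.append(force)
    time = np.concatenate(t_parts)
    df = pd.DataFrame({
        "time_s": time,
        "shear_strain": np.concatenate(strain_parts),
        "shear_stress_pa": np.concatenate(stress_parts),
        "normal_force_n": np.concatenate(force_parts),
        "gap_mm": np.full(time.size, phantom.height * (1.0 + lam)),
    })
    meta = {
        "phantom": _phantom_meta(phantom),
        "protocol": _protocol_meta(protocol),
        "segment_kind": kind,
        "lam": lam,
        "segments": segments,
    }
    if extra_meta:
        meta.update(_jsonable(extra_meta))
    return RheometerTrace(df, meta)


def simulate_time_sweep(phantom: TissuePhantom,
                        protocol: ProtocolSpec | None = None,
                        lam: float = 0.0,
                        rng: np.random.Generator | None = None,
                        t_since_step0: float = 0.0) -> RheometerTrace:
    """Dynamic time sweep: fixed amplitude, one plateau every
    ``sample_interval`` from t = 0 through t = duration (inclusive).

    ``t_since_step0`` is the time already elapsed since the axial step when
    the sweep starts; the default 0 means the step happens at the start of
    the sweep, so the final plateau approximates the equilibrium axial
    stress.
    """
    protocol = protocol or ProtocolSpec.time_sweep()
    if protocol.segment != "time_sweep":
        raise ValidationError("protocol.segment must be 'time_sweep'")
    if rng is None:
        rng = phantom.rng(stream=1)
    gamma0 = protocol.shear_strain_grid[0]
    n_plateaus = int(round(protocol.duration / protocol.sample_interval)) + 1
    starts = [k * protocol.sample_interval for k in range(n_plateaus)]
    plateaus = [(t0, gamma0) for t0 in starts]
    return _build_trace(phantom, protocol, plateaus, float(lam),
                        t_since_step0, rng, "time_sweep")


def simulate_strain_sweep(phantom: TissuePhantom,
                          protocol: ProtocolSpec | None = None,
                          lam: float = 0.0,
                          rng: np.random.Generator | None = None,
                          t_since_step0: float = 0.0,
                          kind: str = "strain_sweep",
                          extra_meta: dict | None = None,
                          modulus_factor: float = 1.0) -> RheometerTrace:
    """Dynamic amplitude sweep over the protocol's shear-strain grid."""
    protocol = protocol or ProtocolSpec.strain_sweep()
    if protocol.segment not in ("strain_sweep", "reversibility"):
        raise ValidationError(
            "protocol.segment must be 'strain_sweep' or 'reversibility'"
        )
    if rng is None:
        rng = phantom.rng(stream=2)
    plateaus = [(k * protocol.sample_interval, g)
                for k, g in enumerate(protocol.shear_strain_grid)]
    return _build_trace(phantom, protocol, plateaus, float(lam),
                        t_since_step0, rng, kind, extra_meta, modulus_factor)


def simulate_compression_series(
    phantom: TissuePhantom,
    protocol: ProtocolSpec | None = None,
    strain_protocol: ProtocolSpec | None = None,
    rng: np.random.Generator | None = None,
) -> list[RheometerTrace]:
    """One time sweep plus one amplitude sweep per axial level, in protocol
    order (default levels 0/-10/-15/-20/-25%).

    Each axial step happens at the start of that level's time sweep; the
    normal-force channel then relaxes toward the equilibrium axial stress
    with the phantom's Prony spectrum, so the final time-sweep plateau
    (120 s after the step) approximates equilibrium.  The amplitude sweep
    follows the time sweep at each level.
    """
    protocol = protocol or ProtocolSpec.time_sweep()
    base_strain = strain_protocol or ProtocolSpec.strain_sweep()
    if rng is None:
        rng = phantom.rng(stream=3)
    traces = []
    for lam in protocol.axial_strain_levels:
        traces.append(simulate_time_sweep(phantom, protocol, lam=lam, rng=rng))
        t_after = protocol.duration + 2.0 * protocol.sample_interval
        traces.append(
            simulate_strain_sweep(phantom, base_strain, lam=lam, rng=rng,
                                  t_since_step0=t_after)
        )
    return traces


def simulate_stress_relaxation(phantom: TissuePhantom,
                               diameter: float | None = None,
                               mode: str = "compression_25",
                               duration: float = 1200.0,
                               sample_interval: float = 1.0,
                               rng: np.random.Generator | None = None,
                               preload_g: float = 10.0) -> RheometerTrace:
    """Step-strain stress relaxation, recorded for ``duration`` seconds.

    ``mode`` is ``compression_25`` (25% axial compression step; signal on the
    normal-force channel) or ``shear_25`` (25% shear step; signal on the
    shear-stress channel).  Relaxation kinetics are identical for any punch
    diameter — the emulated tissue relaxes by intrinsic viscoelasticity, not
    by size-dependent fluid flux.
    """
    if mode not in ("compression_25", "shear_25"):
        raise ValidationError(f"unknown relaxation mode {mode!r}")
    if not duration > 0:
        raise ValidationError("duration must be > 0")
    if rng is None:
        rng = phantom.rng(stream=4)
    diameter = phantom.diameter if diameter is None else float(diameter)
    if not diameter > 0:
        raise ValidationError("diameter must be > 0")
    t = np.arange(0.0, duration + sample_interval / 2.0, sample_interval)
    params, shape = phantom.constitutive()
    area0 = math.pi * (diameter / 2.0 * 1e-3) ** 2
    relax = _prony_relaxation(phantom, t)
    noise = np.array([_noise_factor(rng, phantom.noise_cv) for _ in t])
    if mode == "compression_25":
        lam = -0.25
        sigma0 = float(axial_stress_model(lam, params, shape))
        # instantaneous response sigma0/g_inf decaying to equilibrium sigma0
        sigma_true = preload_stress(preload_g, diameter) + sigma0 * (
            relax / phantom.equilibrium_fraction
        )
        force = sigma_true / (1.0 + lam) ** 2 * area0 * noise
        force = force + rng.normal(0.0, phantom.normal_force_sd, size=t.size)
        strain = np.zeros_like(t)
        stress = np.zeros_like(t)
        gap = phantom.height * (1.0 + lam)
    else:
        lam = 0.0
        gamma = 0.25
        g0 = float(storage_modulus_model(gamma, 0.0, params, shape))
        stress = gamma * g0 * (relax / phantom.equilibrium_fraction) * noise
        strain = np.full_like(t, gamma)
        force = np.full_like(t, preload_stress(preload_g, diameter) * area0)
        force = force + rng.normal(0.0, phantom.normal_force_sd, size=t.size)
        gap = phantom.height
    df = pd.DataFrame({
        "time_s": t,
        "shear_strain": strain,
        "shear_stress_pa": stress,
        "normal_force_n": force,
        "gap_mm": np.full(t.size, gap),
    })
    meta = {
        "phantom": _phantom_meta(phantom),
        "segment_kind": "relaxation",
        "mode": mode,
        "lam": lam,
        "diameter_mm": diameter,
        "preload_g": preload_g,
    }
    return RheometerTrace(df, meta)


def simulate_reversibility_cycles(phantom: TissuePhantom,
                                  n_cycles: int = 3,
                                  rng: np.random.Generator | None = None
                                  ) -> list[RheometerTrace]:
    """Alternating up (1 -> 45%) and down (50 -> 5%) amplitude sweeps at zero
    axial strain, ``n_cycles`` of each.

    A one-time stiffening factor (default 1.05) is applied after the first
    cycle and never again, emulating slight consolidation on first loading;
    subsequent cycles are statistically identical, i.e. the protocol causes
    no progressive damage.
    """
    if not isinstance(n_cycles, int) or n_cycles < 1:
        raise ValidationError("n_cycles must be a positive integer")
    if rng is None:
        rng = phantom.rng(stream=5)
    from .protocol import DOWN_CYCLE_GRID, UP_CYCLE_GRID

    up = ProtocolSpec.reversibility()
    down = up.with_(shear_strain_grid=DOWN_CYCLE_GRID,
                    duration=len(DOWN_CYCLE_GRID) * up.sample_interval)
    traces = []
    for cycle in range(1, n_cycles + 1):
        factor = 1.0 if cycle == 1 else phantom.first_cycle_stiffening
        for proto, direction in ((up, "up"), (down, "down")):
            traces.append(
                simulate_strain_sweep(
                    phantom, proto, lam=0.0, rng=rng, kind="reversibility",
                    extra_meta={"cycle": cycle, "direction": direction},
                    modulus_factor=factor,
                )
            )
    return traces
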