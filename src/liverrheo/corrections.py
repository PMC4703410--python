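"""Geometric corrections and unit conversions for parallel-plate rheometry
under superposed uniaxial strain.

When a cylindrical sample is compressed or stretched between the platens its
cross-section changes (volume is conserved), so the moduli and axial stress
reported by the instrument against the reference geometry must be corrected.
With axial engineering strain ``lam = (h - h0)/h0`` (compression negative):

    G'_actual   = G'_measured   * (1 + lam)**2
    G''_actual  = G''_measured  * (1 + lam)**2
    sigma_actual = sigma_measured * (1 + lam)**2

The quadratic exponent is applied to the axial stress as well as to the
moduli; the exponent is exposed as an argument for sensitivity analysis.
All corrections are the identity at ``lam = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .oscillation import SweepRecord

__all__ = [
    "STANDARD_GRAVITY",
    "PA_PER_MMHG",
    "correct_storage_modulus",
    "uncorrect_storage_modulus",
    "correct_loss_modulus",
    "correct_axial_stress",
    "uncorrect_axial_stress",
    "pa_to_mmhg",
    "mmhg_to_pa",
    "preload_stress",
    "CorrectedRecord",
    "correct_record",
]

#: Standard acceleration of gravity, m s^-2 (conventional value).
STANDARD_GRAVITY = 9.80665
#: Conventional conversion constant, Pa per mm Hg.
PA_PER_MMHG = 133.322


def _check_lam(lam) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= -1) or np.any(lam >= 1):
        raise ValidationError(f"axial strain must lie in (-1, 1), got {lam}")
    return lam


def _area_factor(lam, exponent: float) -> np.ndarray:
    return (1.0 + _check_lam(lam)) ** exponent


def correct_storage_modulus(Gp_meas, lam, exponent: float = 2.0):
    """G'_actual = G'_measured * (1+lam)**2."""
    return np.asarray(Gp_meas, dtype=float) * _area_factor(lam, exponent)


def uncorrect_storage_modulus(Gp_act, lam, exponent: float = 2.0):
    """Inverse of :func:`correct_storage_modulus` (exposed for closure tests
    and for emulating what the instrument would have reported)."""
    return np.asarray(Gp_act, dtype=float) / _area_factor(lam, exponent)


def correct_loss_modulus(Gpp_meas, lam, exponent: float = 2.0):
    """G''_actual = G''_measured * (1+lam)**2 (same form as for G')."""
    return np.asarray(Gpp_meas, dtype=float) * _area_factor(lam, exponent)


def correct_axial_stress(sigma_meas, lam, exponent: float = 2.0):
    """sigma_actual = sigma_measured * (1+lam)**2."""
    return np.asarray(sigma_meas, dtype=float) * _area_factor(lam, exponent)


def uncorrect_axial_stress(sigma_act, lam, exponent: float = 2.0):
    """Inverse of :func:`correct_axial_stress`."""
    return np.asarray(sigma_act, dtype=float) / _area_factor(lam, exponent)


def pa_to_mmhg(pa):
    """Convert pascal to millimetres of mercury (1 mm Hg = 133.322 Pa)."""
    return np.asarray(pa, dtype=float) / PA_PER_MMHG


def mmhg_to_pa(mmhg):
    """Convert millimetres of mercury to pascal."""
    return np.asarray(mmhg, dtype=float) * PA_PER_MMHG


def preload_stress(mass_g: float, diameter_mm: float) -> float:
    """Axial stress (Pa) produced by a gram-weight preload on a circular
    sample: sigma = m g0 / (pi (d/2)^2).

    A 10 g preload on a 20 mm punch gives 312.2 Pa (~300 Pa at one
    significant figure).
    """
    if not np.isfinite(mass_g) or mass_g < 0:
        raise ValidationError(f"preload mass must be finite and >= 0, got {mass_g}")
    if not diameter_mm > 0:
        raise ValidationError(f"diameter must be > 0, got {diameter_mm}")
    area = math.pi * (diameter_mm / 2.0 * 1e-3) ** 2
    return mass_g * 1e-3 * STANDARD_GRAVITY / area


@dataclass(frozen=True)
class CorrectedRecord:
    """A sweep record with geometry-corrected quantities attached.

    Carries both the measured (``*_meas``) and corrected (``*_act``) values so
    that corrections remain auditable in the output tables.
    """

    gamma0: float
    omega: float
    lam: float
    Gp_meas: float
    Gpp_meas: float
    normal_force: float
    sigma_meas: float
    t_elapsed: float
    Gp_act: float
    Gpp_act: float
    sigma_act: float
    sigma_mmhg: float


def correct_record(rec: SweepRecord, exponent: float = 2.0) -> CorrectedRecord:
    """Apply all geometric corrections to one :class:`SweepRecord`."""
    gp = float(correct_storage_modulus(rec.Gp_meas, rec.lam, exponent))
    gpp = float(correct_loss_modulus(rec.Gpp_meas, rec.lam, exponent))
    sig = float(correct_axial_stress(rec.sigma_meas, rec.lam, exponent))
    return CorrectedRecord(
        gamma0=rec.gamma0,
        omega=rec.omega,
        lam=rec.lam,
        Gp_meas=rec.Gp_meas,
        Gpp_meas=rec.Gpp_meas,
        normal_force=rec.normal_force,
        sigma_meas=rec.sigma_meas,
        t_elapsed=rec.t_elapsed,
        Gp_act=gp,
        Gpp_act=gpp,
        sigma_act=sig,
        sigma_mmhg=float(pa_to_mmhg(sig)),
    )
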