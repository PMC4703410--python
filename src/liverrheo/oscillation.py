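"""First-harmonic analysis of oscillatory rheometer traces.

Reproduces what instrument software reports: for each measurement plateau
(fixed shear amplitude, frequency and axial strain) the stress waveform is
projected onto the first harmonic of the imposed strain, giving the measured
storage and loss moduli, and the normal-force channel is averaged into an
uncorrected axial stress.  Only first-harmonic moduli are computed; no
large-amplitude higher-harmonic decomposition is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientDataError, StructureError, ValidationError

__all__ = [
    "SweepRecord",
    "fit_harmonics",
    "extract_sweep",
    "normal_force_to_stress",
    "contact_area",
]

#: Reference platen/punch diameter used when a trace carries no geometry, mm.
DEFAULT_DIAMETER_MM = 20.0


@dataclass(frozen=True)
class SweepRecord:
    """One (shear amplitude, axial strain) measurement, before correction.

    Attributes
    ----------
    gamma0 : float
        Fitted shear-strain amplitude (dimensionless).
    omega : float
        Oscillation frequency, rad/s.
    lam : float
        Axial engineering strain (signed; compression negative).
    Gp_meas, Gpp_meas : float
        Measured storage and loss moduli, Pa (uncorrected).
    normal_force : float
        Normal force averaged over the tail of the plateau, N.
    sigma_meas : float
        ``normal_force`` divided by the reference sample area, Pa
        (uncorrected).
    t_elapsed : float
        Time of the plateau start relative to the protocol segment start, s.
    """

    gamma0: float
    omega: float
    lam: float
    Gp_meas: float
    Gpp_meas: float
    normal_force: float
    sigma_meas: float
    t_elapsed: float


def fit_harmonics(time, strain_signal, stress_signal, omega):
    """Project an oscillatory stress onto the first harmonic of the strain.

    The strain channel is fitted first (amplitude and phase), then the stress
    is decomposed relative to the strain phase: the in-phase coefficient
    divided by the strain amplitude is G', the quadrature coefficient is G''.
    Fitting the strain phase rather than assuming it makes the result
    invariant to cropping or global time shifts of the trace.

    Parameters
    ----------
    time, strain_signal, stress_signal : array_like
        Sampled waveforms; at least one full period of data is required.
    omega : float
        Angular frequency of the imposed oscillation, rad/s.

    Returns
    -------
    (Gp, Gpp) : tuple of float
        Measured storage and loss moduli, Pa.
    """
    if not omega > 0:
        raise ValidationError(f"omega must be > 0, got {omega}")
    t = np.asarray(time, dtype=float)
    strain = np.asarray(strain_signal, dtype=float)
    stress = np.asarray(stress_signal, dtype=float)
    if not (t.shape == strain.shape == stress.shape):
        raise ValidationError("time, strain and stress must have equal length")
    if t.size < 4 or (t[-1] - t[0]) < 2.0 * math.pi / omega * (1.0 - 1e-9):
        raise InsufficientDataError(
            "need at least one full oscillation period of samples"
        )
    design = np.column_stack([np.sin(omega * t), np.cos(omega * t)])
    (a, b), *_ = np.linalg.lstsq(design, strain, rcond=None)
    gamma0 = math.hypot(a, b)
    if gamma0 < 1e-12:
        raise ValidationError("strain amplitude is zero; moduli undefined")
    (p, q), *_ = np.linalg.lstsq(design, stress, rcond=None)
    in_phase = (p * a + q * b) / gamma0
    quadrature = (q * a - p * b) / gamma0
    return in_phase / gamma0, quadrature / gamma0


def contact_area(diameter_mm: float, lam: float = 0.0) -> float:
    """Sample/platen contact area in m^2 under volume conservation.

    A cylinder of reference diameter ``d`` compressed (or stretched) to axial
    strain ``lam`` keeps its volume, so the contact area scales as
    ``A(lam) = A0 / (1 + lam)``.
    """
    if not diameter_mm > 0:
        raise ValidationError(f"diameter must be > 0, got {diameter_mm}")
    if lam <= -1:
        raise ValidationError(f"axial strain must be > -1, got {lam}")
    a0 = math.pi * (diameter_mm / 2.0 * 1e-3) ** 2
    return a0 / (1.0 + lam)


def normal_force_to_stress(force_n, diameter_mm: float):
    """Uncorrected axial stress: force divided by the reference sample area.

    sigma = F / (pi (d/2)^2), SI units (Pa).
    """
    force = np.asarray(force_n, dtype=float)
    if not np.all(np.isfinite(force)):
        raise ValidationError("normal force must be finite")
    if not diameter_mm > 0:
        raise ValidationError(f"diameter must be > 0, got {diameter_mm}")
    area = math.pi * (diameter_mm / 2.0 * 1e-3) ** 2
    return force / area


def _segments_from_metadata(trace) -> list[dict] | None:
    segs = trace.metadata.get("segments")
    if not segs:
        return None
    return [dict(s) for s in segs]


def _segments_by_time_gaps(trace, omega: float) -> list[dict]:
    """Fallback segmentation: split where the sampling interval jumps, then
    verify each candidate piece is an amplitude plateau (1% tolerance)."""
    t = trace.time
    dt = np.diff(t)
    med = np.median(dt)
    cuts = np.flatnonzero(dt > 1.5 * med) + 1
    bounds = [0, *cuts.tolist(), t.size]
    segments = []
    strain = trace.shear_strain
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        if i1 - i0 < 4:
            raise StructureError(
                f"cannot segment trace: fragment at t={t[i0]:.6g} s too short"
            )
        half = (i0 + i1) // 2
        amp_a = np.max(np.abs(strain[i0:half]))
        amp_b = np.max(np.abs(strain[half:i1]))
        ref = max(amp_a, amp_b)
        if ref > 0 and abs(amp_a - amp_b) / ref > 0.02:
            raise StructureError(
                f"cannot segment trace: strain amplitude is not a plateau "
                f"at t={t[half]:.6g} s"
            )
        segments.append({"start": int(i0), "stop": int(i1), "omega": omega,
                         "lam": trace.metadata.get("lam", 0.0),
                         "t_label": float(t[i0])})
    return segments


def extract_sweep(trace, diameter_mm: float | None = None,
                  omega: float | None = None,
                  tail_fraction: float = 0.1) -> list[SweepRecord]:
    """Split a trace into measurement plateaus and fit moduli per plateau.

    Segment boundaries come from the trace metadata when present (the normal
    path for machine-generated traces); otherwise plateaus are recovered from
    jumps in the sampling grid and checked for constant strain amplitude.
    The normal force attached to each record is the mean over the final
    ``tail_fraction`` of the plateau's samples, i.e. the most relaxed value.

    Parameters
    ----------
    trace : liverrheo.io.RheometerTrace
    diameter_mm : float, optional
        Reference punch diameter; defaults to the trace metadata, then 20 mm.
    omega : float, optional
        Frequency for the metadata-free fallback path.

    Returns
    -------
    list of SweepRecord
    """
    if diameter_mm is None:
        diameter_mm = trace.metadata.get("phantom", {}).get(
            "diameter", trace.metadata.get("diameter_mm", DEFAULT_DIAMETER_MM)
        )
    segments = _segments_from_metadata(trace)
    if segments is None:
        if omega is None:
            raise StructureError(
                "trace has no segment metadata; supply omega for fallback "
                "segmentation"
            )
        segments = _segments_by_time_gaps(trace, omega)
    records = []
    for seg in segments:
        i0, i1 = int(seg["start"]), int(seg["stop"])
        w = float(seg.get("omega", omega if omega is not None else 0.0))
        t = trace.time[i0:i1]
        gp, gpp = fit_harmonics(
            t, trace.shear_strain[i0:i1], trace.shear_stress[i0:i1], w
        )
        design = np.column_stack([np.sin(w * t), np.cos(w * t)])
        (a, b), *_ = np.linalg.lstsq(design, trace.shear_strain[i0:i1], rcond=None)
        gamma0 = math.hypot(a, b)
        n_tail = max(1, int(math.ceil(tail_fraction * (i1 - i0))))
        force = float(np.mean(trace.normal_force[i1 - n_tail:i1]))
        records.append(
            SweepRecord(
                gamma0=gamma0,
                omega=w,
                lam=float(seg.get("lam", 0.0)),
                Gp_meas=float(gp),
                Gpp_meas=float(gpp),
                normal_force=force,
                sigma_meas=float(normal_force_to_stress(force, diameter_mm)),
                t_elapsed=float(seg.get("t_label", t[0])),
            )
        )
    return records
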