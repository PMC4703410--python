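"""Two-parameter constitutive surface for soft tissue under combined shear and
axial strain, with a statsmodels-style Model/Results pair for fitting it.

The surface captures three phenomena seen in parallel-plate rheometry of whole
liver (and of other highly cellular soft tissues):

* **compression stiffening** — the shear storage modulus G' rises with
  uniaxial compression, approximately linearly in the axial (compressive)
  stress;
* **tension softening** — G' and the tangent Young's modulus E fall slightly
  under uniaxial tension;
* **shear strain softening** — G' falls with increasing oscillatory shear
  amplitude, and the softening curve flattens under compression.

Only two quantities are material parameters fitted per sample:

* ``C1`` (Pa) — the baseline low-strain shear storage modulus at zero axial
  strain;
* ``C2`` (Pa) — the scale of the axial nonlinearity.

With axial engineering strain ``lam`` (negative in compression) and shear
strain amplitude ``gamma``, the surface is

.. math::

    \\sigma(\\lambda) = C_2\\,(e^{-b\\lambda} - 1), \\qquad
    E(\\lambda) = -\\frac{d\\sigma}{d\\lambda} = C_2\\,b\\,e^{-b\\lambda},

.. math::

    G'(\\gamma, \\lambda) = \\bigl[C_1 + m\\,\\sigma(\\lambda)\\bigr]\\,
    s(\\gamma, \\lambda), \\qquad
    s = \\frac{1}{1 + (\\gamma/\\gamma_{\\rm eff})^{n}}, \\quad
    \\gamma_{\\rm eff} = \\gamma_c\\Bigl(1 +
        \\frac{\\max(\\sigma, 0)}{\\sigma_{\\rm ref}}\\Bigr),

with compressive axial stress taken positive, so that G' is exactly affine in
the axial stress at fixed shear amplitude.  The loss modulus is modelled as a
fixed fraction of G' (``G'' = tan_delta * G'``).  The remaining shape
constants (:class:`ModelShape`) are fixed configuration, not fitted, which
preserves the two-parameter structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import (
    FitConvergenceError,
    IdentifiabilityError,
    ValidationError,
)

__all__ = [
    "ConstitutiveParams",
    "ModelShape",
    "axial_stress_model",
    "youngs_modulus_model",
    "softening_factor",
    "storage_modulus_model",
    "loss_modulus_model",
    "predict_protocol",
    "CompressionShearModel",
    "CompressionShearResults",
    "fit_params",
]

DEFAULT_COMPRESSION_LEVELS = (0.0, -0.10, -0.15, -0.20, -0.25)
DEFAULT_TENSION_LEVELS = (0.10, 0.20)
DEFAULT_STRAIN_GRID = (
    0.01, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50,
)


@dataclass(frozen=True)
class ConstitutiveParams:
    """The two fitted material parameters.

    Parameters
    ----------
    C1 : float
        Baseline low-strain shear storage modulus at zero axial strain, Pa.
        Must be positive.
    C2 : float
        Axial nonlinearity scale, Pa.  Must be non-negative; ``C2 = 0``
        switches off the axial response entirely (no compression stiffening,
        zero axial stress at every strain).
    """

    C1: float
    C2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.C1) and self.C1 > 0):
            raise ValidationError(f"C1 must be finite and > 0, got {self.C1}")
        if not (np.isfinite(self.C2) and self.C2 >= 0):
            raise ValidationError(f"C2 must be finite and >= 0, got {self.C2}")


@dataclass(frozen=True)
class ModelShape:
    """Fixed shape constants of the constitutive surface.

    These are configuration, not fitted quantities; they set the functional
    shape shared by all samples while ``(C1, C2)`` carry the per-sample
    material information.

    Attributes
    ----------
    b : float
        Axial exponential rate (dimensionless).  Sets how fast the axial
        stress grows with compression; ``E(0) = b * C2``.
    m : float
        Slope of G' against axial stress (Pa/Pa, dimensionless).
    gamma_c : float
        Shear-softening half-strain scale at zero compression: at
        ``gamma = gamma_c`` the modulus has fallen to half its plateau.
    n_soft : float
        Softening sharpness (Hill exponent).  The default of 3 puts the 1-2%
        amplitudes on a genuine low-strain plateau (softening < 0.1% there),
        so the standard 2% reference readout is an unbiased estimate of the
        plateau modulus and the compression curve at 2% is affine in the
        axial stress to high accuracy.
    sigma_ref : float
        Axial-stress scale (Pa) over which compression flattens the softening
        curve (raises the effective half-strain).
    tan_delta : float
        Loss tangent G''/G'; the loss modulus is modelled as proportional to
        the storage modulus.
    softening_enabled : bool
        When False the softening factor is identically 1 (flat amplitude
        sweeps); used for decellularized scaffolds, whose softening is
        abolished along with the cellular phase.
    cell_fraction_doc : float
        Documentation constant: approximate cellular volume fraction of the
        tissue the defaults were tuned for.  Not used in any computation.
    """

    b: float = 8.0
    m: float = 0.8
    gamma_c: float = 0.22
    n_soft: float = 3.0
    sigma_ref: float = 4000.0
    tan_delta: float = 0.2
    softening_enabled: bool = True
    cell_fraction_doc: float = 0.85

    def __post_init__(self) -> None:
        for name in ("b", "gamma_c", "n_soft", "sigma_ref"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.m < 0:
            raise ValidationError("m must be >= 0")
        if not 0 <= self.tan_delta < 1:
            raise ValidationError("tan_delta must be in [0, 1)")


def axial_stress_model(lam, params: ConstitutiveParams, shape: ModelShape | None = None):
    """Equilibrium axial stress sigma(lam) in Pa, compressive stress positive.

    ``sigma(0) = 0``; the response is smooth, monotone decreasing in ``lam``
    (so increasing in compression magnitude) and bounded by ``-C2`` in the
    tension limit.
    """
    shape = shape or ModelShape()
    lam = np.asarray(lam, dtype=float)
    return params.C2 * (np.exp(-shape.b * lam) - 1.0)


def youngs_modulus_model(lam, params: ConstitutiveParams, shape: ModelShape | None = None):
    """Tangent Young's modulus E(lam) = -d sigma/d lam = C2 * b * exp(-b*lam), Pa."""
    shape = shape or ModelShape()
    lam = np.asarray(lam, dtype=float)
    return params.C2 * shape.b * np.exp(-shape.b * lam)


def softening_factor(gamma, lam, params: ConstitutiveParams, shape: ModelShape | None = None):
    """Shear strain-softening factor s(gamma, lam) in (0, 1].

    A Hill-type decay in the shear amplitude whose half-strain scale grows
    with compressive axial stress, so softening curves are flatter (less
    steep) under compression.  Identically 1 when softening is disabled.
    """
    shape = shape or ModelShape()
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma < 0):
        raise ValidationError("shear strain amplitude must be >= 0")
    if not shape.softening_enabled:
        return np.ones_like(np.broadcast_arrays(gamma, np.asarray(lam, float))[0])
    sigma = np.maximum(axial_stress_model(lam, params, shape), 0.0)
    gamma_eff = shape.gamma_c * (1.0 + sigma / shape.sigma_ref)
    return 1.0 / (1.0 + (gamma / gamma_eff) ** shape.n_soft)


def storage_modulus_model(gamma, lam, params: ConstitutiveParams, shape: ModelShape | None = None):
    """Shear storage modulus G'(gamma, lam), Pa."""
    shape = shape or ModelShape()
    sigma = axial_stress_model(lam, params, shape)
    return (params.C1 + shape.m * sigma) * softening_factor(gamma, lam, params, shape)


def loss_modulus_model(gamma, lam, params: ConstitutiveParams, shape: ModelShape | None = None):
    """Shear loss modulus G'' = tan_delta * G', Pa."""
    shape = shape or ModelShape()
    return shape.tan_delta * storage_modulus_model(gamma, lam, params, shape)


def predict_protocol(
    params: ConstitutiveParams,
    shape: ModelShape | None = None,
    lam_levels=DEFAULT_COMPRESSION_LEVELS,
    gamma_grid=(0.02,),
) -> pd.DataFrame:
    """Deterministic sweep-table predictions on a protocol grid.

    Returns a tidy table with one row per (gamma0, lam) combination and the
    same value columns as a corrected sweep table:
    ``gamma0, lam, Gp_act_pa, Gpp_act_pa, sigma_act_pa, E_act_pa``.
    """
    shape = shape or ModelShape()
    lam_levels = np.atleast_1d(np.asarray(lam_levels, dtype=float))
    gamma_grid = np.atleast_1d(np.asarray(gamma_grid, dtype=float))
    lam2, gam2 = np.meshgrid(lam_levels, gamma_grid, indexing="ij")
    lam_flat, gam_flat = lam2.ravel(), gam2.ravel()
    return pd.DataFrame(
        {
            "gamma0": gam_flat,
            "lam": lam_flat,
            "Gp_act_pa": storage_modulus_model(gam_flat, lam_flat, params, shape),
            "Gpp_act_pa": loss_modulus_model(gam_flat, lam_flat, params, shape),
            "sigma_act_pa": axial_stress_model(lam_flat, params, shape),
            "E_act_pa": youngs_modulus_model(lam_flat, params, shape),
        }
    )


@dataclass
class FitConfig:
    """Options for the nonlinear least-squares fit."""

    n_starts: int = 3
    c1_bounds: tuple = (1e-6, 1e6)
    c2_bounds: tuple = (0.0, 1e6)
    weight_floor_pa: float = 1.0  # floor on |observed| in relative weighting
    xtol: float = 1e-12
    ftol: float = 1e-12


class CompressionShearModel:
    """Two-parameter constitutive model bound to corrected sweep data.

    The observations are (i) corrected storage moduli ``Gp`` measured at shear
    amplitudes ``gamma`` under axial strains ``lam`` and, optionally, (ii)
    corrected equilibrium axial stresses ``sigma_axial`` at axial strains
    ``sigma_lam``.  ``fit()`` estimates ``(C1, C2)`` by bounded nonlinear
    least squares on the joint relative residuals, with the shape constants
    held fixed, and returns a :class:`CompressionShearResults`.

    Parameters
    ----------
    gprime : array_like
        Observed corrected storage moduli, Pa.
    gamma : array_like
        Shear strain amplitudes of the G' observations (dimensionless).
    lam : array_like
        Axial strains of the G' observations (signed; compression negative).
    sigma_axial, sigma_lam : array_like, optional
        Observed corrected axial stresses (Pa, net of preload, compressive
        positive) and their axial strains.
    shape : ModelShape, optional
    fit_config : FitConfig, optional

    Examples
    --------
    >>> from liverrheo.constitutive import (CompressionShearModel,
    ...     ConstitutiveParams, predict_protocol)
    >>> truth = ConstitutiveParams(C1=1000.0, C2=250.0)
    >>> tab = predict_protocol(truth, gamma_grid=[0.01, 0.05, 0.2])
    >>> model = CompressionShearModel(tab["Gp_act_pa"], tab["gamma0"],
    ...     tab["lam"], tab["sigma_act_pa"], tab["lam"])
    >>> res = model.fit()
    >>> round(res.params.C1), round(res.params.C2)
    (1000, 250)
    """

    def __init__(
        self,
        gprime,
        gamma,
        lam,
        sigma_axial=None,
        sigma_lam=None,
        shape: ModelShape | None = None,
        fit_config: FitConfig | None = None,
    ):
        self.shape = shape or ModelShape()
        self.fit_config = fit_config or FitConfig()
        self.gprime = np.atleast_1d(np.asarray(gprime, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
        self.lam = np.atleast_1d(np.asarray(lam, dtype=float))
        if not self.gprime.shape == self.gamma.shape == self.lam.shape:
            raise ValidationError("gprime, gamma and lam must have equal length")
        if self.gprime.size == 0:
            raise ValidationError("no G' observations")
        if not np.all(np.isfinite(self.gprime)):
            raise ValidationError("non-finite G' observation")
        if np.all(self.gprime == 0):
            raise ValidationError("all G' observations are zero")
        if np.any(self.gprime < 0):
            raise ValidationError("negative G' observation")
        if sigma_axial is None:
            self.sigma_axial = np.empty(0)
            self.sigma_lam = np.empty(0)
        else:
            self.sigma_axial = np.atleast_1d(np.asarray(sigma_axial, dtype=float))
            self.sigma_lam = np.atleast_1d(np.asarray(sigma_lam, dtype=float))
            if self.sigma_axial.shape != self.sigma_lam.shape:
                raise ValidationError("sigma_axial and sigma_lam must match")
        all_lam = np.concatenate([self.lam, self.sigma_lam])
        if np.unique(np.round(all_lam, 9)).size < 2:
            raise IdentifiabilityError(
                "C2 is not identifiable from a single axial-strain level; "
                "provide >= 2 levels"
            )
        if np.unique(np.round(self.gamma, 9)).size < 3:
            raise ValidationError("need >= 3 distinct shear amplitudes")

    # -- construction from pipeline output ---------------------------------
    @classmethod
    def from_records(
        cls,
        records,
        shape: ModelShape | None = None,
        preload_pa: float = 0.0,
        fit_config: FitConfig | None = None,
    ) -> "CompressionShearModel":
        """Build from a corrected sweep table.

        ``records`` is a DataFrame with columns ``gamma0, lam, Gp_act_pa`` and
        optionally ``sigma_act_pa`` (or a list of objects with the matching
        attributes, e.g. :class:`liverrheo.corrections.CorrectedRecord`).
        ``preload_pa`` is subtracted from the axial stresses so they estimate
        the deformation stress sigma(lam); one (mean) stress observation is
        kept per distinct axial level.
        """
        if not isinstance(records, pd.DataFrame):
            records = pd.DataFrame(
                {
                    "gamma0": [r.gamma0 for r in records],
                    "lam": [r.lam for r in records],
                    "Gp_act_pa": [r.Gp_act for r in records],
                    "sigma_act_pa": [r.sigma_act for r in records],
                }
            )
        sig = None
        sig_lam = None
        if "sigma_act_pa" in records.columns:
            per_level = (
                records.groupby(np.round(records["lam"], 9))["sigma_act_pa"]
                .mean()
                .reset_index()
            )
            sig = per_level["sigma_act_pa"].to_numpy() - preload_pa
            sig_lam = per_level["lam"].to_numpy()
        return cls(
            records["Gp_act_pa"],
            records["gamma0"],
            records["lam"],
            sig,
            sig_lam,
            shape=shape,
            fit_config=fit_config,
        )

    # -- prediction ---------------------------------------------------------
    def predict(self, params: ConstitutiveParams, gamma=None, lam=None):
        """Model G' on the observation grid (default) or a supplied grid."""
        gamma = self.gamma if gamma is None else np.asarray(gamma, float)
        lam = self.lam if lam is None else np.asarray(lam, float)
        return storage_modulus_model(gamma, lam, params, self.shape)

    # -- fitting ------------------------------------------------------------
    def _residuals(self, x: np.ndarray) -> np.ndarray:
        params = ConstitutiveParams(C1=max(x[0], 1e-9), C2=max(x[1], 0.0))
        w_g = np.abs(self.gprime) + self.fit_config.weight_floor_pa
        res_g = (self.predict(params) - self.gprime) / w_g
        if self.sigma_axial.size:
            w_s = np.abs(self.sigma_axial) + self.fit_config.weight_floor_pa
            res_s = (
                axial_stress_model(self.sigma_lam, params, self.shape)
                - self.sigma_axial
            ) / w_s
            return np.concatenate([res_g, res_s])
        return res_g

    def _start_points(self) -> list[np.ndarray]:
        # C1 guess: lowest-amplitude G' at the axial level closest to zero
        i0 = np.argmin(np.abs(self.lam) * 10 + self.gamma)
        c1_0 = float(np.clip(self.gprime[i0], *self.fit_config.c1_bounds))
        # C2 guess: invert sigma(lam) at the deepest compression, falling back
        # to the G'-stiffening span when no stress data are available
        lam_min = float(np.min(np.concatenate([self.lam, self.sigma_lam])))
        denom = math.expm1(-self.shape.b * lam_min)
        if self.sigma_axial.size and denom > 0:
            sig_deep = float(self.sigma_axial[np.argmin(self.sigma_lam)])
            c2_0 = max(sig_deep, 0.0) / denom
        elif denom > 0 and self.shape.m > 0:
            span = float(np.max(self.gprime) - c1_0)
            c2_0 = max(span, 0.0) / (self.shape.m * denom)
        else:
            c2_0 = c1_0 / 4.0
        c2_0 = float(np.clip(c2_0, *self.fit_config.c2_bounds))
        base = np.array([c1_0, max(c2_0, 1.0)])
        return [base, base * 0.5, base * 2.0][: self.fit_config.n_starts]

    def fit(self) -> "CompressionShearResults":
        """Estimate (C1, C2) by bounded nonlinear least squares.

        Runs a small multi-start (data-driven initial guesses scaled by
        {1, 0.5, 2}) because joint convexity is not guaranteed, and keeps the
        best converged solution.
        """
        cfg = self.fit_config
        lo = np.array([cfg.c1_bounds[0], cfg.c2_bounds[0]])
        hi = np.array([cfg.c1_bounds[1], cfg.c2_bounds[1]])
        best = None
        for x0 in self._start_points():
            x0 = np.clip(x0, lo + 1e-12, hi)
            sol = least_squares(
                self._residuals, x0, bounds=(lo, hi), method="trf",
                xtol=cfg.xtol, ftol=cfg.ftol,
            )
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise FitConvergenceError(
                "constitutive fit failed to converge from all start points"
            )
        params = ConstitutiveParams(C1=float(best.x[0]), C2=float(best.x[1]))
        return CompressionShearResults(self, params, best)


class CompressionShearResults:
    """Fit results: estimates, standard errors, diagnostics and predictions.

    Attributes
    ----------
    params : ConstitutiveParams
        Point estimates of (C1, C2).
    bse : dict
        Approximate standard errors from the Gauss-Newton covariance
        ``s^2 (J'J)^{-1}`` of the weighted residuals (NaN when the problem has
        no residual degrees of freedom).
    resid : ndarray
        Weighted residual vector at the solution.
    converged : bool
    nobs : int
    """

    def __init__(self, model: CompressionShearModel, params: ConstitutiveParams, sol):
        self.model = model
        self.params = params
        self.converged = bool(sol.success)
        self.resid = sol.fun
        self.cost = float(sol.cost)
        self.nobs = int(sol.fun.size)
        dof = max(self.nobs - 2, 0)
        if dof > 0:
            s2 = 2.0 * self.cost / dof
            jtj = sol.jac.T @ sol.jac
            try:
                cov = s2 * np.linalg.inv(jtj)
                se = np.sqrt(np.clip(np.diag(cov), 0, None))
            except np.linalg.LinAlgError:
                se = np.array([np.nan, np.nan])
        else:
            se = np.array([np.nan, np.nan])
        self.bse = {"C1": float(se[0]), "C2": float(se[1])}

    @property
    def resid_norm(self) -> float:
        return float(np.linalg.norm(self.resid))

    @property
    def diagnostics(self) -> dict:
        return {
            "residual": self.resid_norm,
            "converged": self.converged,
            "n_points": self.nobs,
        }

    def predict(self, gamma, lam):
        return self.model.predict(self.params, gamma, lam)

    def predict_protocol(self, lam_levels=DEFAULT_COMPRESSION_LEVELS,
                         gamma_grid=(0.02,)) -> pd.DataFrame:
        return predict_protocol(self.params, self.model.shape, lam_levels, gamma_grid)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        sh = self.model.shape
        lines = [
            "Compression-shear constitutive model fit",
            "=" * 56,
            f"{'N obs':<28}{self.nobs:>10d}",
            f"{'Converged':<28}{str(self.converged):>10}",
            f"{'Weighted resid. norm':<28}{self.resid_norm:>10.4g}",
            "-" * 56,
            f"{'param':<8}{'estimate (Pa)':>16}{'std err (Pa)':>16}",
            f"{'C1':<8}{self.params.C1:>16.4f}{self.bse['C1']:>16.4g}",
            f"{'C2':<8}{self.params.C2:>16.4f}{self.bse['C2']:>16.4g}",
            "-" * 56,
            (f"shape: b={sh.b:g} m={sh.m:g} gamma_c={sh.gamma_c:g} "
             f"n={sh.n_soft:g} sigma_ref={sh.sigma_ref:g} Pa "
             f"tan_delta={sh.tan_delta:g}"),
            "=" * 56,
        ]
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Convenience plot: observed vs fitted G' against shear amplitude,
        one line per axial level."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        for lv in np.unique(np.round(m.lam, 9)):
            sel = np.isclose(m.lam, lv)
            order = np.argsort(m.gamma[sel])
            g = m.gamma[sel][order]
            ax.plot(g, m.gprime[sel][order], "o", label=f"data lam={lv:+.2f}")
            ax.plot(g, self.predict(g, np.full_like(g, lv)), "-")
        ax.set_xlabel("shear strain amplitude")
        ax.set_ylabel("G' (Pa)")
        ax.legend(fontsize="small")
        return ax


def fit_params(sweep_tables, shape: ModelShape | None = None,
               fit_config: FitConfig | None = None, preload_pa: float = 0.0):
    """Functional wrapper: fit (C1, C2) from a corrected sweep table.

    Returns ``(ConstitutiveParams, diagnostics dict)``.
    """
    model = CompressionShearModel.from_records(
        sweep_tables, shape=shape, preload_pa=preload_pa, fit_config=fit_config
    )
    res = model.fit()
    return res.params, res.diagnostics
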