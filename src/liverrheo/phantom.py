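"""Tissue phantoms: ground-truth mechanical parameter sets for simulated
liver samples.

A :class:`TissuePhantom` bundles everything the synthetic rheometer needs to
emit data for one sample: the constitutive parameters (C1, C2) and shape
constants, the loss ratio, a two-mode Prony relaxation spectrum, the noise
model, the punch geometry and a seed.  The preset table encodes ordinal
condition phenotypes — progressive fibrosis raises both C1 and C2,
glycosaminoglycan digestion (amylase) and integrin blockade (VLO4) suppress
compression stiffening (low C2 at normal C1), permeabilization barely changes
anything, and decellularization removes ~90% of the baseline modulus along
with compression stiffening and shear softening.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from .constitutive import ConstitutiveParams, ModelShape
from .exceptions import ConfigurationError, ValidationError

__all__ = ["TissuePhantom", "CONDITION_PRESETS", "make_phantom"]

#: Default slice-height range accepted for phantoms, mm.
HEIGHT_RANGE_MM = (3.05, 5.6)

#: Condition presets: (C1 Pa, C2 Pa, softening enabled).
CONDITION_PRESETS: dict[str, dict] = {
    "normal": {"C1": 1000.0, "C2": 250.0},
    "ccl4_2wk": {"C1": 2000.0, "C2": 500.0},
    "ccl4_6wk": {"C1": 4000.0, "C2": 1200.0},
    "amylase": {"C1": 1000.0, "C2": 80.0},
    "vlo4": {"C1": 1000.0, "C2": 90.0},
    "permeabilized": {"C1": 850.0, "C2": 230.0},
    "decellularized": {"C1": 100.0, "C2": 2.0, "softening_enabled": False},
}


@dataclass(frozen=True)
class TissuePhantom:
    """Generative ground truth for one simulated sample.

    Attributes
    ----------
    condition_label : str
        One of the preset condition names.
    C1, C2 : float
        Constitutive parameters, Pa (see :mod:`liverrheo.constitutive`).
    loss_ratio : float
        Target G''/G' in [0, 1).
    relax_fractions : tuple of float
        Prony weights of the transient relaxation modes; their sum must be
        < 1 so a positive equilibrium fraction remains.
    relax_times : tuple of float
        Prony time constants, s.
    noise_cv : float
        Coefficient of variation of the multiplicative (log-normal) noise on
        the oscillatory stress amplitude, per measurement plateau.
    normal_force_sd : float
        SD of the additive Gaussian transducer noise on the normal-force
        channel, N.
    diameter : float
        Punch diameter, mm.
    height : float
        Unloaded slice height, mm.
    seed : int
        Seed for all randomness attached to this phantom.
    first_cycle_stiffening : float
        One-time modulus multiplier applied after the first reversibility
        cycle.
    shape : ModelShape
        Fixed shape constants of the generating constitutive surface
        (``tan_delta`` is overridden by ``loss_ratio``).
    """

    condition_label: str
    C1: float
    C2: float
    loss_ratio: float = 0.2
    relax_fractions: tuple = (0.25, 0.15)
    relax_times: tuple = (8.0, 25.0)
    noise_cv: float = 0.05
    normal_force_sd: float = 0.01
    diameter: float = 20.0
    height: float = 4.0
    seed: int = 0
    first_cycle_stiffening: float = 1.05
    shape: ModelShape = field(default_factory=ModelShape)

    def __post_init__(self) -> None:
        if not self.C1 > 0:
            raise ValidationError(f"C1 must be > 0, got {self.C1}")
        if self.C2 < 0:
            raise ValidationError(f"C2 must be >= 0, got {self.C2}")
        if not 0 <= self.loss_ratio < 1:
            raise ValidationError("loss_ratio must lie in [0, 1)")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.normal_force_sd < 0:
            raise ValidationError("normal_force_sd must be >= 0")
        fr = tuple(float(f) for f in self.relax_fractions)
        tm = tuple(float(t) for t in self.relax_times)
        if len(fr) != len(tm):
            raise ValidationError("relax_fractions and relax_times must match")
        if any(f < 0 for f in fr) or sum(fr) >= 1:
            raise ValidationError(
                "relax_fractions must be >= 0 and sum to < 1 "
                "(a positive equilibrium fraction must remain)"
            )
        if any(not t > 0 for t in tm):
            raise ValidationError("relax_times must be > 0")
        if not self.diameter > 0:
            raise ValidationError("diameter must be > 0")
        lo, hi = HEIGHT_RANGE_MM
        if not lo <= self.height <= hi:
            raise ValidationError(
                f"height must lie in [{lo}, {hi}] mm, got {self.height}"
            )
        if not self.first_cycle_stiffening > 0:
            raise ValidationError("first_cycle_stiffening must be > 0")
        object.__setattr__(self, "relax_fractions", fr)
        object.__setattr__(self, "relax_times", tm)

    # ---- derived views ----------------------------------------------------
    def constitutive(self) -> tuple[ConstitutiveParams, ModelShape]:
        """The (params, shape) pair of the generating surface, with the
        phantom's loss ratio substituted for the shape's loss tangent."""
        params = ConstitutiveParams(C1=self.C1, C2=self.C2)
        shape = replace(self.shape, tan_delta=self.loss_ratio)
        return params, shape

    @property
    def equilibrium_fraction(self) -> float:
        return 1.0 - sum(self.relax_fractions)

    def rng(self, stream: int = 0) -> np.random.Generator:
        """A deterministic generator derived from the phantom seed; distinct
        ``stream`` values give independent streams."""
        return np.random.default_rng(np.random.SeedSequence(
            entropy=int(self.seed), spawn_key=(int(stream),)
        ))

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        return d


def make_phantom(condition_label: str, overrides: dict | None = None,
                 seed: int = 0) -> TissuePhantom:
    """Build a phantom from the condition preset table.

    Parameters
    ----------
    condition_label : str
        A key of :data:`CONDITION_PRESETS`.
    overrides : dict, optional
        Field overrides; keys must be declared :class:`TissuePhantom` fields
        (or ``softening_enabled``, forwarded to the shape).  Values violating
        an invariant raise :class:`~liverrheo.exceptions.ValidationError`.
    seed : int
        Phantom seed; the same (label, overrides, seed) always yields an
        identical phantom.
    """
    if condition_label not in CONDITION_PRESETS:
        raise ConfigurationError(
            f"unknown condition {condition_label!r}; valid labels: "
            f"{sorted(CONDITION_PRESETS)}"
        )
    preset = dict(CONDITION_PRESETS[condition_label])
    softening = preset.pop("softening_enabled", True)
    kw = {"condition_label": condition_label, "seed": int(seed), **preset}
    overrides = dict(overrides or {})
    if "softening_enabled" in overrides:
        softening = bool(overrides.pop("softening_enabled"))
    shape = overrides.pop("shape", None)
    if shape is None:
        shape = ModelShape(softening_enabled=softening)
    valid = {f.name for f in fields(TissuePhantom)}
    unknown = set(overrides) - valid
    if unknown:
        raise ConfigurationError(
            f"unknown phantom override(s): {sorted(unknown)}"
        )
    kw.update(overrides)
    kw["shape"] = shape
    return TissuePhantom(**kw)
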