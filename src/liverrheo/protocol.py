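"""Measurement protocol descriptions.

A :class:`ProtocolSpec` describes one protocol segment the way the rheometer
is programmed: which kind of sweep, at what frequency, over which shear-strain
grid and axial-strain levels, for how long and how often.  The default
constructors encode the standard whole-organ protocol: a 120 s time sweep at
2% strain and 1 rad/s sampled every 20 s, an amplitude sweep from 1% to 50%
at 10 rad/s, compression levels of 0/-10/-15/-20/-25%, tension levels of
+10/+20%, a 1200 s stress-relaxation hold, and three up/down reversibility
cycles, all under a 10 g preload.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .exceptions import ValidationError

__all__ = ["ProtocolSpec", "SEGMENT_KINDS"]

SEGMENT_KINDS = ("time_sweep", "strain_sweep", "relaxation", "reversibility")

DEFAULT_STRAIN_SWEEP_GRID = (
    0.01, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50,
)
UP_CYCLE_GRID = (0.01, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45)
DOWN_CYCLE_GRID = (0.50, 0.45, 0.40, 0.35, 0.30, 0.25, 0.20, 0.15, 0.10, 0.05)
DEFAULT_COMPRESSION_LEVELS = (0.0, -0.10, -0.15, -0.20, -0.25)
DEFAULT_TENSION_LEVELS = (0.0, 0.10, 0.20)


@dataclass(frozen=True)
class ProtocolSpec:
    """One protocol segment.

    Attributes
    ----------
    segment : str
        One of ``time_sweep``, ``strain_sweep``, ``relaxation``,
        ``reversibility``.
    shear_frequency : float
        Oscillation frequency, rad/s.
    shear_strain_grid : tuple of float
        Shear-strain amplitudes visited, as fractions in (0, 0.55].  A time
        sweep uses a single amplitude.
    axial_strain_levels : tuple of float
        Signed axial engineering strains (compression negative), each in
        (-1, +1).  Protocol percentages are converted to signed fractions at
        this boundary.
    duration : float
        Segment duration, s.
    sample_interval : float
        Spacing between measurement plateaus, s.
    preload_mass : float
        Preload, grams.
    """

    segment: str
    shear_frequency: float = 1.0
    shear_strain_grid: tuple = (0.02,)
    axial_strain_levels: tuple = (0.0,)
    duration: float = 120.0
    sample_interval: float = 20.0
    preload_mass: float = 10.0

    def __post_init__(self) -> None:
        if self.segment not in SEGMENT_KINDS:
            raise ValidationError(
                f"segment must be one of {SEGMENT_KINDS}, got {self.segment!r}"
            )
        if not self.shear_frequency > 0:
            raise ValidationError("shear_frequency must be > 0")
        grid = tuple(float(g) for g in self.shear_strain_grid)
        if len(grid) == 0:
            raise ValidationError("shear_strain_grid must not be empty")
        if any(not 0 < g <= 0.55 for g in grid):
            raise ValidationError("shear strain amplitudes must lie in (0, 0.55]")
        levels = tuple(float(v) for v in self.axial_strain_levels)
        if any(not -1 < v < 1 for v in levels):
            raise ValidationError("axial strain levels must lie in (-1, +1)")
        if self.duration < 0:
            raise ValidationError("duration must be >= 0")
        if not self.sample_interval > 0:
            raise ValidationError("sample_interval must be > 0")
        if self.preload_mass < 0:
            raise ValidationError("preload_mass must be >= 0")
        object.__setattr__(self, "shear_strain_grid", grid)
        object.__setattr__(self, "axial_strain_levels", levels)

    # ---- default protocol segments ---------------------------------------
    @classmethod
    def time_sweep(cls, gamma0: float = 0.02, omega: float = 1.0,
                   duration: float = 120.0, interval: float = 20.0,
                   axial_levels=DEFAULT_COMPRESSION_LEVELS,
                   preload_mass: float = 10.0) -> "ProtocolSpec":
        """2% strain, 1 rad/s, 120 s, one plateau every 20 s."""
        return cls("time_sweep", omega, (gamma0,), tuple(axial_levels),
                   duration, interval, preload_mass)

    @classmethod
    def strain_sweep(cls, grid=DEFAULT_STRAIN_SWEEP_GRID, omega: float = 10.0,
                     interval: float = 5.0,
                     axial_levels=DEFAULT_COMPRESSION_LEVELS,
                     preload_mass: float = 10.0) -> "ProtocolSpec":
        """Amplitude sweep 1% -> 50% at 10 rad/s.

        The exact amplitude grid is configurable; the default visits
        {1, 5, 10, ..., 50}%.
        """
        grid = tuple(grid)
        return cls("strain_sweep", omega, grid, tuple(axial_levels),
                   len(grid) * interval, interval, preload_mass)

    @classmethod
    def tension_series(cls, **kw) -> "ProtocolSpec":
        """Time-sweep protocol over the tension levels 0/+10/+20%."""
        return cls.time_sweep(axial_levels=DEFAULT_TENSION_LEVELS, **kw)

    @classmethod
    def relaxation(cls, duration: float = 1200.0, interval: float = 1.0,
                   preload_mass: float = 10.0) -> "ProtocolSpec":
        """Step strain held for 1200 s."""
        if not duration > 0:
            raise ValidationError("relaxation duration must be > 0")
        return cls("relaxation", 1.0, (0.25,), (0.0,), duration, interval,
                   preload_mass)

    @classmethod
    def reversibility(cls, omega: float = 10.0, interval: float = 5.0,
                      preload_mass: float = 10.0) -> "ProtocolSpec":
        """One up (1 -> 45%) or down (50 -> 5%) reversibility sweep."""
        return cls("reversibility", omega, UP_CYCLE_GRID, (0.0,),
                   len(UP_CYCLE_GRID) * interval, interval, preload_mass)

    def with_(self, **changes) -> "ProtocolSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)
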