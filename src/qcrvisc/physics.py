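"""Physics of a thickness-shear quartz crystal resonator under Newtonian liquid load.

A quartz crystal resonator (QCR) driven near its series resonance responds to a
semi-infinite Newtonian liquid with a frequency down-shift that follows the
Kanazawa-Gordon relation

    delta_f = -n * f0**(3/2) * sqrt(rho_L * eta_L / (pi * rho_q * G_q))

where ``rho_L`` and ``eta_L`` are the density and dynamic viscosity of the
liquid and ``rho_q``, ``G_q`` are the density and shear modulus of quartz.
Because the relation is algebraic, the viscosity of the load can be recovered
from a measured frequency shift once a fluid density is assumed.  Energy
dissipation into the liquid simultaneously broadens the conductance peak; the
half-bandwidth shift ``delta_gamma`` equals ``|delta_f|`` for an ideal
Newtonian load and deviates from it for viscoelastic fluids, which this module
represents with an empirical ``viscoelastic_ratio``.

All computation here is in SI units (Hz, kg m^-3, Pa s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "QuartzConstants",
    "LiquidLoad",
    "ConductanceSweep",
    "DEFAULT_QUARTZ",
    "SYNOVIAL_FLUID_DENSITY",
    "kanazawa_frequency_shift",
    "invert_viscosity",
    "expected_bandwidth_shift",
    "calibrate_density",
    "lorentzian_conductance",
    "simulate_sweep",
]


@dataclass(frozen=True)
class QuartzConstants:
    """Fixed physical parameters of an AT-cut quartz resonator.

    Parameters
    ----------
    f0
        Fundamental series resonance frequency in Hz.
    rho_q
        Density of quartz in kg m^-3.
    G_q
        Shear modulus of quartz in N m^-2.
    n
        Overtone number (odd positive integer; 1 = fundamental).
    """

    f0: float = 1.0e7
    rho_q: float = 2648.0
    G_q: float = 2.947e10
    n: int = 1

    def __post_init__(self) -> None:
        if not (self.f0 > 0 and self.rho_q > 0 and self.G_q > 0):
            raise ValueError("f0, rho_q and G_q must be strictly positive")
        if not (isinstance(self.n, (int, np.integer)) and self.n > 0 and self.n % 2 == 1):
            raise ValueError(f"overtone number must be an odd positive integer, got {self.n!r}")


DEFAULT_QUARTZ = QuartzConstants()

#: Assumed synovial-fluid density (kg m^-3) used when inverting a frequency
#: shift to a viscosity.  Calibrated once with :func:`calibrate_density` as the
#: single density that reconciles the reference EDTA inflammatory-class mean
#: frequency shift (-3665.36 Hz) with its mean viscosity (3.46 mPa s); no
#: single density reconciles all four published (delta_f, eta) class means
#: (implied values span roughly 930-970 kg m^-3), so this is a documented
#: calibration constant, not ground truth.
SYNOVIAL_FLUID_DENSITY = 951.9


@dataclass(frozen=True)
class LiquidLoad:
    """A Newtonian (or mildly viscoelastic) semi-infinite liquid load.

    ``viscoelastic_ratio`` is the dimensionless ratio delta_gamma / |delta_f|;
    1.0 corresponds to an ideal Newtonian semi-infinite liquid.
    """

    rho_L: float
    eta_L: float
    viscoelastic_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.rho_L <= 0:
            raise ValueError(f"fluid density must be positive, got {self.rho_L}")
        if self.eta_L <= 0:
            raise ValueError(f"fluid viscosity must be positive, got {self.eta_L}")
        if self.viscoelastic_ratio <= 0:
            raise ValueError("viscoelastic_ratio must be positive")


@dataclass(frozen=True)
class ConductanceSweep:
    """One conductance acquisition: a frequency grid and conductance values.

    ``condition`` tags whether the crystal was unloaded ("air") or carried a
    sample ("loaded"); ``source`` is an optional free-form identity used in
    error messages.
    """

    frequencies: np.ndarray
    conductance: np.ndarray
    condition: str = "loaded"
    source: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequencies, dtype=float)
        cond = np.asarray(self.conductance, dtype=float)
        object.__setattr__(self, "frequencies", freq)
        object.__setattr__(self, "conductance", cond)
        if freq.ndim != 1 or cond.ndim != 1 or freq.size != cond.size:
            raise ValueError("frequencies and conductance must be 1-D arrays of equal length")
        if freq.size < 3:
            raise ValueError("a conductance sweep needs at least 3 points")
        if not np.all(np.diff(freq) > 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not np.all(np.isfinite(freq)):
            raise ValueError("frequency grid contains non-finite values")
        if not np.all(np.isfinite(cond)) or np.any(cond < 0):
            raise ValueError("conductance values must be finite and non-negative")
        if self.condition not in ("air", "loaded"):
            raise ValueError(f"condition must be 'air' or 'loaded', got {self.condition!r}")

    def __len__(self) -> int:  # pragma: no cover - trivial
        return int(self.frequencies.size)


def kanazawa_frequency_shift(load: LiquidLoad, quartz: QuartzConstants = DEFAULT_QUARTZ) -> float:
    """Frequency shift (Hz, negative) of a resonator loaded by a Newtonian liquid."""
    return -quartz.n * quartz.f0 ** 1.5 * math.sqrt(
        load.rho_L * load.eta_L / (math.pi * quartz.rho_q * quartz.G_q)
    )


def invert_viscosity(
    delta_f: float, rho_L: float, quartz: QuartzConstants = DEFAULT_QUARTZ
) -> float:
    """Dynamic viscosity (Pa s) implied by a measured frequency shift.

    Algebraic inversion of the Kanazawa relation:
    ``eta = delta_f**2 * pi * rho_q * G_q / (n**2 * f0**3 * rho_L)``.
    """
    if delta_f == 0:
        raise ValueError("cannot invert a zero frequency shift to a viscosity")
    if rho_L <= 0:
        raise ValueError(f"fluid density must be positive, got {rho_L}")
    return (
        delta_f**2
        * math.pi
        * quartz.rho_q
        * quartz.G_q
        / (quartz.n**2 * quartz.f0**3 * rho_L)
    )


def expected_bandwidth_shift(load: LiquidLoad, quartz: QuartzConstants = DEFAULT_QUARTZ) -> float:
    """Half-bandwidth shift delta_gamma (Hz, positive) for a liquid load.

    Modelled as ``viscoelastic_ratio * |delta_f|``; equal to ``-delta_f``
    exactly in the Newtonian small-load limit (ratio = 1).
    """
    return load.viscoelastic_ratio * abs(kanazawa_frequency_shift(load, quartz))


def calibrate_density(
    delta_f: float,
    eta: float,
    quartz: QuartzConstants = DEFAULT_QUARTZ,
    lo: float = 800.0,
    hi: float = 1100.0,
    step: float = 0.1,
) -> float:
    """Brute-force the fluid density that reconciles a (delta_f, eta) pair.

    Scans densities on ``[lo, hi]`` with resolution ``step`` and returns the
    one whose inverted viscosity best matches ``eta``.  Used once to fix
    :data:`SYNOVIAL_FLUID_DENSITY`.
    """
    grid = np.arange(lo, hi + step / 2, step)
    errs = np.array([abs(invert_viscosity(delta_f, float(r), quartz) - eta) for r in grid])
    return float(grid[int(np.argmin(errs))])


def lorentzian_conductance(
    f: np.ndarray | float, fs: float, gamma: float, g_max: float
) -> np.ndarray | float:
    """Near-resonance conductance of a series resonant branch.

    ``G(f) = g_max / (1 + ((f - fs) / gamma)**2)``, the standard Lorentzian
    approximation; ``gamma`` is the half-bandwidth at half-maximum, so
    ``G(fs +/- gamma) = g_max / 2`` exactly.
    """
    x = (np.asarray(f, dtype=float) - fs) / gamma
    return g_max / (1.0 + x * x)


def simulate_sweep(
    fs: float,
    gamma: float,
    g_max: float,
    grid: np.ndarray | None = None,
    *,
    span_halfwidths: float = 6.0,
    n_points: int = 500,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    condition: str = "loaded",
    source: str | None = None,
) -> ConductanceSweep:
    """Generate an idealized (optionally noisy) conductance sweep.

    Parameters
    ----------
    fs, gamma, g_max
        Series resonance frequency (Hz), half-bandwidth at half-maximum (Hz)
        and peak conductance (S) of the simulated resonance.
    grid
        Frequency grid; defaults to ``n_points`` points spanning
        ``fs +/- span_halfwidths * gamma``.  The grid must cover at least
        ``fs +/- 3 * gamma`` so both half-maximum crossings are estimable.
    noise_sd
        Additive Gaussian noise, expressed relative to the peak conductance.
    """
    if gamma <= 0:
        raise ValueError(f"half-bandwidth must be positive, got {gamma}")
    if g_max <= 0:
        raise ValueError(f"peak conductance must be positive, got {g_max}")
    if grid is None:
        grid = np.linspace(fs - span_halfwidths * gamma, fs + span_halfwidths * gamma, n_points)
    grid = np.asarray(grid, dtype=float)
    if grid[0] > fs - 3 * gamma or grid[-1] < fs + 3 * gamma:
        raise ValueError(
            "frequency grid must span fs +/- 3*gamma; the half-bandwidth would "
            "otherwise be inestimable"
        )
    cond = np.asarray(lorentzian_conductance(grid, fs, gamma, g_max), dtype=float)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        cond = cond + noise_sd * g_max * rng.standard_normal(grid.size)
        cond = np.clip(cond, 0.0, None)
    return ConductanceSweep(grid, cond, condition=condition, source=source)
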