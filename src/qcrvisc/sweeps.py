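"""Resonance estimation from conductance sweeps and feature extraction.

Turns raw conductance curves into the three viscosity-linked features used
throughout the package:

* ``delta_f``   - series-resonance frequency shift loaded vs air (Hz, < 0),
* ``delta_gamma`` - half-bandwidth shift loaded vs air (Hz, > 0),
* ``eta``       - dynamic viscosity (Pa s) obtained from ``delta_f`` by the
  Kanazawa inversion with an assumed fluid density.

The resonance frequency is taken as the abscissa of the conductance maximum,
refined below the grid step by a three-point parabola; the half-bandwidth is
half the distance between the two half-maximum crossings, each located by
linear interpolation between the bracketing grid points.  Argmax alone would
quantize ``delta_f`` to the sweep step, which is far coarser than the Hz-scale
differences that matter here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .physics import (
    DEFAULT_QUARTZ,
    SYNOVIAL_FLUID_DENSITY,
    ConductanceSweep,
    QuartzConstants,
    invert_viscosity,
)

__all__ = [
    "ResonanceEstimate",
    "FeatureTriple",
    "PeakTruncatedError",
    "BandwidthTruncatedError",
    "locate_resonance",
    "compute_shifts",
    "featurize_pair",
    "featurize_batch",
    "write_sweep_csv",
    "read_sweep_csv",
    "FEATURE_TABLE_COLUMNS",
    "write_feature_table",
    "read_feature_table",
]

#: Canonical feature-table schema shared by the generator, the extractor and
#: the statistics/classification stages.
FEATURE_TABLE_COLUMNS = [
    "sample_id",
    "tube",
    "label",
    "repeat",
    "point",
    "delta_f_hz",
    "delta_gamma_hz",
    "eta_mpas",
]


class PeakTruncatedError(ValueError):
    """The conductance maximum lies on a grid boundary; fs is inestimable."""


class BandwidthTruncatedError(ValueError):
    """A half-maximum crossing lies outside the sweep; gamma is inestimable."""


@dataclass(frozen=True)
class ResonanceEstimate:
    """Series resonance frequency, half-bandwidth and peak conductance."""

    fs: float
    gamma: float
    g_max: float

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"half-bandwidth must be positive, got {self.gamma}")


@dataclass(frozen=True)
class FeatureTriple:
    """The three per-acquisition features (SI units: Hz, Hz, Pa s)."""

    delta_f: float
    delta_gamma: float
    eta: float


def locate_resonance(
    sweep: ConductanceSweep, peak_fit_fraction: float = 0.95
) -> ResonanceEstimate:
    """Estimate (fs, gamma, g_max) from one conductance sweep.

    The parabola is fitted to the contiguous run of points around the grid
    maximum whose conductance exceeds ``peak_fit_fraction`` of it (at least
    the three points around the maximum).  Averaging over the whole peak cap
    keeps the sub-grid refinement useful when the grid is much finer than
    the peak and the point-to-point curvature drops below the noise.

    Raises
    ------
    BandwidthTruncatedError
        If the curve has no half-maximum crossing on either side (including
        the degenerate constant curve).
    PeakTruncatedError
        If the conductance maximum sits on the first or last grid point.
    """
    f = sweep.frequencies
    g = sweep.conductance
    if np.ptp(g) == 0:
        raise BandwidthTruncatedError(
            "bandwidth-truncated: constant conductance curve has no half-maximum crossings"
        )
    i = int(np.argmax(g))
    if i == 0 or i == f.size - 1:
        raise PeakTruncatedError(
            f"peak-truncated: conductance maximum at grid boundary (index {i})"
        )

    # contiguous window around the maximum above the fit threshold; for any
    # curve symmetric about its peak the window is symmetric and the fitted
    # vertex coincides with the symmetry centre exactly
    level = peak_fit_fraction * g[i]
    lo = i
    while lo > 0 and g[lo - 1] >= level:
        lo -= 1
    hi = i
    while hi < f.size - 1 and g[hi + 1] >= level:
        hi += 1
    lo, hi = min(lo, i - 1), max(hi, i + 1)
    coeffs = np.polyfit(f[lo : hi + 1] - f[i], g[lo : hi + 1], 2)
    a, b, c = coeffs
    if a < 0:
        fs = float(f[i] - b / (2 * a))
        g_max = float(c - b * b / (4 * a))
    else:  # locally flat/degenerate: fall back to the grid maximum
        fs = float(f[i])
        g_max = float(g[i])

    half = g_max / 2.0
    left = _crossing(f, g, i, half, direction=-1)
    right = _crossing(f, g, i, half, direction=+1)
    gamma = (right - left) / 2.0
    return ResonanceEstimate(fs=fs, gamma=gamma, g_max=g_max)


def _crossing(f: np.ndarray, g: np.ndarray, i_peak: int, level: float, direction: int) -> float:
    """Linearly interpolated frequency where ``g`` crosses ``level``.

    Walks outward from the peak in ``direction`` (+1 right, -1 left) until the
    curve first drops to or below ``level``.
    """
    j = i_peak
    while True:
        j_next = j + direction
        if j_next < 0 or j_next >= f.size:
            side = "left" if direction < 0 else "right"
            raise BandwidthTruncatedError(
                f"bandwidth-truncated: no half-maximum crossing on the {side} side"
            )
        if g[j_next] <= level:
            break
        j = j_next
    g_hi, g_lo = g[j], g[j_next]
    if g_hi == g_lo:  # flat segment exactly at the level
        return float(f[j_next])
    t = (g_hi - level) / (g_hi - g_lo)
    return float(f[j] + t * (f[j_next] - f[j]))


def compute_shifts(
    loaded: ResonanceEstimate, air: ResonanceEstimate
) -> tuple[float, float]:
    """(delta_f, delta_gamma) of a loaded acquisition relative to its air reference."""
    return loaded.fs - air.fs, loaded.gamma - air.gamma


def featurize_pair(
    loaded: ConductanceSweep,
    air: ConductanceSweep,
    rho_L: float = SYNOVIAL_FLUID_DENSITY,
    quartz: QuartzConstants = DEFAULT_QUARTZ,
) -> FeatureTriple:
    """Extract (delta_f, delta_gamma, eta) from an (air, loaded) sweep pair.

    Extraction errors are re-raised with the identity of the offending sweep
    attached.
    """
    estimates = {}
    for sweep in (loaded, air):
        try:
            estimates[sweep.condition] = locate_resonance(sweep)
        except ValueError as exc:
            ident = sweep.source or sweep.condition
            raise type(exc)(f"{exc} [sweep: {ident}]") from exc
    delta_f, delta_gamma = compute_shifts(estimates["loaded"], estimates["air"])
    eta = invert_viscosity(delta_f, rho_L, quartz)
    return FeatureTriple(delta_f=delta_f, delta_gamma=delta_gamma, eta=eta)


def featurize_batch(
    pairs: list[tuple[ConductanceSweep, ConductanceSweep]],
    rho_L: float = SYNOVIAL_FLUID_DENSITY,
    quartz: QuartzConstants = DEFAULT_QUARTZ,
) -> list[FeatureTriple]:
    """Map :func:`featurize_pair` over (loaded, air) pairs, preserving order."""
    return [featurize_pair(loaded, air, rho_L, quartz) for loaded, air in pairs]


# ---------------------------------------------------------------------------
# File formats: one acquisition per CSV with a JSON sidecar for metadata.
# ---------------------------------------------------------------------------

def write_sweep_csv(path: str | Path, sweep: ConductanceSweep, meta: dict | None = None) -> None:
    """Write ``frequency_hz,conductance_s`` CSV plus a ``.json`` sidecar."""
    path = Path(path)
    pd.DataFrame(
        {"frequency_hz": sweep.frequencies, "conductance_s": sweep.conductance}
    ).to_csv(path, index=False)
    sidecar = {"condition": sweep.condition}
    if sweep.source is not None:
        sidecar["source"] = sweep.source
    if meta:
        sidecar.update(meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_sweep_csv(path: str | Path) -> ConductanceSweep:
    """Read a sweep CSV (and its sidecar, if present) back into memory."""
    path = Path(path)
    df = pd.read_csv(path)
    condition, source = "loaded", None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        condition = meta.get("condition", condition)
        source = meta.get("source")
    return ConductanceSweep(
        df["frequency_hz"].to_numpy(),
        df["conductance_s"].to_numpy(),
        condition=condition,
        source=source,
    )


def write_feature_table(path: str | Path, rows: pd.DataFrame) -> None:
    """Write a measurement-row table using the canonical column order."""
    cols = [c for c in FEATURE_TABLE_COLUMNS if c in rows.columns]
    cols += [c for c in rows.columns if c not in cols]
    rows[cols].to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
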