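"""Synthetic cohorts of quartz-resonator synovial-fluid measurements.

The real study data (two diagnostic classes, two anticoagulant tube types,
3-5 repeated 50-point acquisitions per patient sample) are not deposited, so
this module generates cohorts with the statistical structure the downstream
analysis assumes:

* published per-class feature distributions (mean, SD) for the frequency
  shift ``delta_f``, half-bandwidth shift ``delta_gamma`` and viscosity
  ``eta``, per tube type;
* a hierarchical (between-sample / within-sample) variance split, because
  repeated points from one patient sample cluster tightly around that
  sample's own mean - the property that makes point-level classification far
  easier than the marginal AUCs suggest;
* physical coupling between the three features: ``delta_gamma`` and ``eta``
  are correlated with ``delta_f`` at the strength implied by the bandwidth
  ratio and the (linearised) Kanazawa inversion.  A pure deterministic link
  cannot reproduce all published per-class SDs simultaneously, so each class
  keeps its exact published mean and SD while the link correlations are
  pooled across the two classes of a tube: the classes differ in location
  and scale but share their correlation geometry, so the residual scatter
  around the physics curve carries no artificial class signature.

Feature columns are in reporting units (Hz, Hz, mPa s).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .physics import DEFAULT_QUARTZ, SYNOVIAL_FLUID_DENSITY, QuartzConstants, simulate_sweep
from .sweeps import FEATURE_TABLE_COLUMNS, ConductanceSweep

__all__ = [
    "FeatureStats",
    "ClassStats",
    "CohortConfig",
    "EDTA_CLASS_STATS",
    "HEPARIN_CLASS_STATS",
    "TUBE_DEFAULTS",
    "CLASSES",
    "default_config",
    "link_correlations",
    "generate_cohort",
    "generate_clinical_covariates",
    "emit_raw_sweeps",
    "write_raw_sweeps",
    "write_manifest",
]

CLASSES = ("inflammatory", "infectious")

COVARIATE_COLUMNS = ["wbc_per_mm3", "neutrophils_pct", "glucose_mg_dl", "proteins_g_dl"]


@dataclass(frozen=True)
class FeatureStats:
    """Mean and standard deviation of one feature within one class."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"standard deviation must be positive, got {self.sd}")


@dataclass(frozen=True)
class ClassStats:
    """Per-class distributions: sensor features plus clinical covariates.

    Sensor features are (Hz, Hz, mPa s); covariates are WBC per mm^3,
    neutrophils %, glucose mg/dL and proteins g/dL.
    """

    delta_f: FeatureStats
    delta_gamma: FeatureStats
    eta: FeatureStats
    wbc: FeatureStats
    neutrophils: FeatureStats
    glucose: FeatureStats
    proteins: FeatureStats


def _cs(df, dg, eta, wbc, neut, glu, prot) -> ClassStats:
    return ClassStats(
        delta_f=FeatureStats(*df),
        delta_gamma=FeatureStats(*dg),
        eta=FeatureStats(*eta),
        wbc=FeatureStats(*wbc),
        neutrophils=FeatureStats(*neut),
        glucose=FeatureStats(*glu),
        proteins=FeatureStats(*prot),
    )


#: Published per-class summary statistics (mean, SD) for samples collected in
#: EDTA tubes; generator defaults.
EDTA_CLASS_STATS: dict[str, ClassStats] = {
    "inflammatory": _cs(
        (-3665.36, 135.34), (1787.47, 66.97), (3.46, 0.21),
        (9060.0, 12526.0), (57.28, 36.39), (99.23, 32.11), (3.87, 0.82),
    ),
    "infectious": _cs(
        (-3675.87, 104.57), (1810.47, 53.34), (3.43, 0.30),
        (52575.62, 75126.19), (85.50, 12.43), (64.37, 35.97), (4.15, 0.49),
    ),
}

#: Published per-class summary statistics for lithium-heparin tubes.
HEPARIN_CLASS_STATS: dict[str, ClassStats] = {
    "inflammatory": _cs(
        (-3775.40, 106.55), (1861.21, 95.89), (3.76, 0.31),
        (9032.76, 13478.73), (63.11, 36.80), (99.23, 32.11), (3.87, 0.82),
    ),
    "infectious": _cs(
        (-3812.91, 109.05), (1908.10, 72.09), (3.67, 0.18),
        (57789.28, 79560.83), (84.00, 12.62), (59.57, 35.98), (4.11, 0.52),
    ),
}

#: Study geometry per tube type: sample counts and total measurement rows.
TUBE_DEFAULTS = {
    "edta": {
        "n_inflammatory_samples": 25,
        "n_infectious_samples": 8,
        "target_rows": 4972,
        "class_stats": EDTA_CLASS_STATS,
    },
    "heparin": {
        "n_inflammatory_samples": 21,
        "n_infectious_samples": 7,
        "target_rows": 5248,
        "class_stats": HEPARIN_CLASS_STATS,
    },
}


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of one synthetic cohort.

    ``between_sample_fraction`` is the share of each feature's total variance
    attributed to sample-level (patient-level) effects; the remainder is
    within-sample scatter across repeats and time points.
    ``max_link_correlation`` caps how strongly delta_gamma and eta may be
    coupled to delta_f, so a linked feature never degenerates into a
    deterministic function of the frequency shift.
    """

    tube: str
    n_inflammatory_samples: int
    n_infectious_samples: int
    class_stats: dict[str, ClassStats]
    repeats_range: tuple[int, int] = (3, 5)
    points_per_repeat: int = 50
    between_sample_fraction: float = 0.97
    max_link_correlation: float = 0.98
    density: float = SYNOVIAL_FLUID_DENSITY
    target_rows: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tube not in ("edta", "heparin"):
            raise ValueError(f"tube must be 'edta' or 'heparin', got {self.tube!r}")
        if self.n_inflammatory_samples <= 0 or self.n_infectious_samples <= 0:
            raise ValueError("sample counts must be positive")
        if not (0.0 <= self.between_sample_fraction < 1.0):
            raise ValueError("between_sample_fraction must lie in [0, 1)")
        if not (0.0 < self.max_link_correlation < 1.0):
            raise ValueError("max_link_correlation must lie in (0, 1)")
        if self.points_per_repeat < 1:
            raise ValueError("points_per_repeat must be >= 1")
        lo, hi = self.repeats_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid repeats_range {self.repeats_range}")
        if set(self.class_stats) != set(CLASSES):
            raise ValueError(f"class_stats must have keys {CLASSES}")
        if self.target_rows is not None:
            n = self.n_inflammatory_samples + self.n_infectious_samples
            if self.target_rows < n * self.points_per_repeat:
                raise ValueError(
                    f"target_rows={self.target_rows} is smaller than one repeat per "
                    f"sample ({n} x {self.points_per_repeat})"
                )


def default_config(tube: str, seed: int = 0, **overrides) -> CohortConfig:
    """Cohort configuration reproducing the study geometry for one tube type."""
    base = TUBE_DEFAULTS[tube.lower()]
    kwargs = {"tube": tube.lower(), **base, **overrides}
    return CohortConfig(seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# Row allocation
# ---------------------------------------------------------------------------

def _allocate_rows(config: CohortConfig, rng: np.random.Generator) -> list[int]:
    """Rows per sample honouring the repeat structure and exact target size.

    Every sample gets the minimum number of full repeats; leftover rows are
    distributed as whole extra repeats (capped at the repeat maximum) to
    randomly chosen samples, and any sub-repeat remainder becomes a partial
    repeat on the last sample.  This keeps every sample present at the exact
    total row count (the published totals are not divisible by the repeat
    block size).
    """
    n = config.n_inflammatory_samples + config.n_infectious_samples
    ppr = config.points_per_repeat
    rmin, rmax = config.repeats_range
    if config.target_rows is None:
        reps = rng.integers(rmin, rmax + 1, size=n)
        return [int(r) * ppr for r in reps]

    base = max(1, min(rmin, config.target_rows // (n * ppr)))
    counts = np.full(n, base * ppr, dtype=int)
    remaining = config.target_rows - int(counts.sum())
    n_extra, leftover = divmod(remaining, ppr)
    order = rng.permutation(n)
    k = 0
    for _ in range(n_extra):
        # next sample (in shuffled order) with spare repeat capacity
        tries = 0
        while counts[order[k % n]] >= rmax * ppr and tries < n:
            k += 1
            tries += 1
        counts[order[k % n]] += ppr
        k += 1
    counts[-1] += leftover
    return counts.tolist()


# ---------------------------------------------------------------------------
# Feature model
# ---------------------------------------------------------------------------

def _eta_coefficient(density: float, quartz: QuartzConstants) -> float:
    """C such that eta [mPa s] = C * delta_f[Hz]**2 under the Kanazawa inversion."""
    return (
        math.pi * quartz.rho_q * quartz.G_q / (quartz.n**2 * quartz.f0**3 * density) * 1e3
    )


def link_correlations(config: CohortConfig) -> tuple[float, float]:
    """Class-pooled correlations of (delta_gamma, eta) with |delta_f|.

    For each class, the physics links imply a coupling strength: the
    bandwidth shift is linear in |delta_f| with slope ``mean_dG/|mean_df|``,
    and the Kanazawa inversion is locally linear with slope
    ``2*eta/|delta_f|``.  The implied correlation is the ratio of the
    link-propagated SD to the published SD of the linked feature, capped at
    ``max_link_correlation`` when the link alone would over-disperse the
    feature.  The two classes' values are averaged so that both classes of a
    tube share one correlation geometry (the published SDs are not mutually
    consistent with a deterministic link, and per-class couplings would
    stamp an artificial class signature onto the residual scatter).
    """
    rho_g, rho_e = [], []
    C = _eta_coefficient(config.density, DEFAULT_QUARTZ)
    for lab in CLASSES:
        st = config.class_stats[lab]
        mu_f, sd_f = st.delta_f.mean, st.delta_f.sd
        s_gamma = st.delta_gamma.mean / abs(mu_f) * sd_f
        rho_g.append(min(s_gamma / st.delta_gamma.sd, config.max_link_correlation))
        s_eta = C * math.sqrt(4 * mu_f**2 * sd_f**2 + 2 * sd_f**4)
        rho_e.append(min(s_eta / st.eta.sd, config.max_link_correlation))
    return float(np.mean(rho_g)), float(np.mean(rho_e))


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one cohort as a measurement-row table.

    Each feature is hierarchical Gaussian: sample-level effects carry
    ``between_sample_fraction`` of the variance and within-sample scatter
    the rest, at every correlation stream, so repeated points cluster
    tightly around their sample's mean.  Class means and SDs equal the
    configured values exactly in expectation.  Fully reproducible under
    ``config.seed``; returns the canonical feature-table columns.
    """
    rng = np.random.default_rng([config.seed, 0])
    counts = _allocate_rows(config, rng)
    b = config.between_sample_fraction
    sb, sw = math.sqrt(b), math.sqrt(1.0 - b)
    rho_g, rho_e = link_correlations(config)

    labels = ["inflammatory"] * config.n_inflammatory_samples + [
        "infectious"
    ] * config.n_infectious_samples
    sample_ids = []
    per_class_counter = {c: 0 for c in CLASSES}
    for lab in labels:
        per_class_counter[lab] += 1
        short = "infl" if lab == "inflammatory" else "sept"
        sample_ids.append(f"{config.tube}_{short}_{per_class_counter[lab]:02d}")

    frames = []
    for sid, lab, n_rows in zip(sample_ids, labels, counts):
        st = config.class_stats[lab]

        # three latent streams, each hierarchical: one sample-level draw
        # plus one point-level draw per row
        u = rng.standard_normal(3)
        e = rng.standard_normal((n_rows, 3))
        z_f = sb * u[0] + sw * e[:, 0]
        z_g = -rho_g * z_f + math.sqrt(1.0 - rho_g**2) * (sb * u[1] + sw * e[:, 1])
        z_e = -rho_e * z_f + math.sqrt(1.0 - rho_e**2) * (sb * u[2] + sw * e[:, 2])

        # negative loading on z_f: a more negative frequency shift (larger
        # |delta_f|) means more dissipation and higher apparent viscosity
        delta_f = st.delta_f.mean + st.delta_f.sd * z_f
        delta_gamma = st.delta_gamma.mean + st.delta_gamma.sd * z_g
        eta = st.eta.mean + st.eta.sd * z_e

        ppr = config.points_per_repeat
        idx = np.arange(n_rows)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "tube": config.tube,
                    "label": lab,
                    "repeat": idx // ppr,
                    "point": idx % ppr,
                    "delta_f_hz": delta_f,
                    "delta_gamma_hz": delta_gamma,
                    "eta_mpas": eta,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out[FEATURE_TABLE_COLUMNS]


def generate_clinical_covariates(config: CohortConfig, rows: pd.DataFrame) -> pd.DataFrame:
    """Fill per-sample clinical covariates (constant within each sample).

    WBC is log-normal matched by moments to the configured mean and SD (the
    published SDs exceed the means, which a normal model cannot produce with
    positive counts); neutrophils, glucose and proteins are normals truncated
    to their plausible ranges.
    """
    rng = np.random.default_rng([config.seed, 1])
    out = rows.copy()
    for col in COVARIATE_COLUMNS:
        out[col] = np.nan
    for sid, grp in rows.groupby("sample_id", sort=False):
        st = config.class_stats[grp["label"].iloc[0]]
        m, s = st.wbc.mean, st.wbc.sd
        sigma2 = math.log(1.0 + (s / m) ** 2)
        wbc = float(rng.lognormal(math.log(m) - sigma2 / 2.0, math.sqrt(sigma2)))
        values = {
            "wbc_per_mm3": wbc,
            "neutrophils_pct": _truncated_normal(st.neutrophils, 0.0, 100.0, rng),
            "glucose_mg_dl": _truncated_normal(st.glucose, 0.0, np.inf, rng),
            "proteins_g_dl": _truncated_normal(st.proteins, 1e-6, np.inf, rng),
        }
        for col, val in values.items():
            out.loc[grp.index, col] = val
    return out


def _truncated_normal(
    stats: FeatureStats, lo: float, hi: float, rng: np.random.Generator
) -> float:
    a = (lo - stats.mean) / stats.sd
    b = (hi - stats.mean) / stats.sd
    return float(scipy.stats.truncnorm.rvs(a, b, loc=stats.mean, scale=stats.sd, random_state=rng))


# ---------------------------------------------------------------------------
# Raw-sweep emission (inverse of the extraction stage)
# ---------------------------------------------------------------------------

def emit_raw_sweeps(
    rows: pd.DataFrame,
    quartz: QuartzConstants = DEFAULT_QUARTZ,
    *,
    gamma_air: float = 150.0,
    g_max_air: float = 0.01,
    span_halfwidths: float = 6.0,
    n_points: int = 500,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[int, ConductanceSweep, ConductanceSweep]]:
    """Render each measurement row as an (air, loaded) conductance-sweep pair.

    The air acquisition resonates at the fundamental frequency with a
    configurable high-Q half-bandwidth; the loaded acquisition encodes the
    row's ``delta_f`` and ``delta_gamma``.  Peak conductance scales inversely
    with the bandwidth, as for a series resonant branch with fixed motional
    inductance.  Returns ``(row_position, air_sweep, loaded_sweep)`` triples
    in row order.
    """
    rng = np.random.default_rng([seed, 2])
    pairs = []
    for pos, (_, row) in enumerate(rows.iterrows()):
        ident = f"{row['sample_id']}_r{int(row['repeat'])}_p{int(row['point'])}"
        air = simulate_sweep(
            quartz.f0,
            gamma_air,
            g_max_air,
            span_halfwidths=span_halfwidths,
            n_points=n_points,
            noise_sd=noise_sd,
            rng=rng,
            condition="air",
            source=f"{ident}_air",
        )
        gamma_loaded = gamma_air + float(row["delta_gamma_hz"])
        loaded = simulate_sweep(
            quartz.f0 + float(row["delta_f_hz"]),
            gamma_loaded,
            g_max_air * gamma_air / gamma_loaded,
            span_halfwidths=span_halfwidths,
            n_points=n_points,
            noise_sd=noise_sd,
            rng=rng,
            condition="loaded",
            source=f"{ident}_loaded",
        )
        pairs.append((pos, air, loaded))
    return pairs


def write_raw_sweeps(rows: pd.DataFrame, out_dir: str | Path, **kwargs) -> list[Path]:
    """Write sweep pairs for ``rows`` to ``out_dir`` as CSV + JSON sidecars."""
    from .sweeps import write_sweep_csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for pos, air, loaded in emit_raw_sweeps(rows, **kwargs):
        row = rows.iloc[pos]
        meta = {
            "sample_id": str(row["sample_id"]),
            "tube": str(row["tube"]),
            "label": str(row["label"]),
            "repeat": int(row["repeat"]),
            "point": int(row["point"]),
        }
        for sweep in (air, loaded):
            path = out_dir / f"{sweep.source}.csv"
            write_sweep_csv(path, sweep, meta)
            paths.append(path)
    return paths


def write_manifest(config: CohortConfig, rows: pd.DataFrame, path: str | Path) -> None:
    """Write a JSON manifest: config echo, seed and row counts per class/sample."""
    manifest = {
        "config": dataclasses.asdict(config),
        "n_rows": int(len(rows)),
        "rows_per_class": {k: int(v) for k, v in rows["label"].value_counts().items()},
        "rows_per_sample": {k: int(v) for k, v in rows["sample_id"].value_counts().items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
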