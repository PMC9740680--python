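"""Synthetic cohort generator: geometry, moments, clustering, covariates, sweeps."""

import json

import numpy as np
import pytest

from qcrvisc import cohort, stats
from qcrvisc.cohort import (
    CohortConfig,
    default_config,
    emit_raw_sweeps,
    generate_clinical_covariates,
    generate_cohort,
    link_correlations,
    write_manifest,
)
from qcrvisc.physics import SYNOVIAL_FLUID_DENSITY, invert_viscosity
from qcrvisc.sweeps import featurize_pair

GEOMETRY = {
    # tube: (rows, samples, inflammatory samples, infectious samples)
    "edta": (4972, 33, 25, 8),
    "heparin": (5248, 28, 21, 7),
}


class TestGeometry:
    @pytest.mark.parametrize("tube", ["edta", "heparin"])
    def test_default_cohort_geometry(self, tube):
        rows = generate_cohort(default_config(tube, seed=123))
        n_rows, n_samples, n_infl, n_infect = GEOMETRY[tube]
        assert len(rows) == n_rows
        assert rows["sample_id"].nunique() == n_samples
        per_class = rows.groupby("label")["sample_id"].nunique()
        assert per_class["inflammatory"] == n_infl
        assert per_class["infectious"] == n_infect

    @pytest.mark.parametrize("tube", ["edta", "heparin"])
    def test_repeat_structure_within_bounds(self, tube):
        rows = generate_cohort(default_config(tube, seed=5))
        cfg = default_config(tube)
        reps = rows.groupby("sample_id")["repeat"].nunique()
        # a partial repeat on the last sample may add one beyond the range
        assert reps.min() >= cfg.repeats_range[0]
        assert reps.max() <= cfg.repeats_range[1] + 1
        assert (rows["point"] < cfg.points_per_repeat).all()

    def test_target_rows_too_small_rejected(self):
        with pytest.raises(ValueError, match="target_rows"):
            default_config("edta", target_rows=1000)

    def test_seeded_output_is_byte_identical(self):
        a = generate_cohort(default_config("edta", seed=9)).to_csv(index=False)
        b = generate_cohort(default_config("edta", seed=9)).to_csv(index=False)
        c = generate_cohort(default_config("edta", seed=10)).to_csv(index=False)
        assert a == b
        assert a != c


def _large_config(tube="edta", seed=2, n=2000):
    return default_config(
        tube,
        seed=seed,
        n_inflammatory_samples=n,
        n_infectious_samples=n,
        points_per_repeat=25,
        repeats_range=(1, 1),
        target_rows=None,
    )


class TestStatisticalStructure:
    def test_parameter_recovery_at_1e5_rows(self):
        # pooled per-class moments of a 10^5-row cohort match the configuration
        cfg = _large_config()
        rows = generate_cohort(cfg)
        assert len(rows) == 100_000
        for lab, st in cfg.class_stats.items():
            sub = rows[rows["label"] == lab]
            for col, ref in [
                ("delta_f_hz", st.delta_f),
                ("delta_gamma_hz", st.delta_gamma),
                ("eta_mpas", st.eta),
            ]:
                assert sub[col].mean() == pytest.approx(ref.mean, rel=0.03)
                assert sub[col].std(ddof=1) == pytest.approx(ref.sd, rel=0.03)

    def test_no_clustering_limit_gives_iid_points(self):
        # between-sample variance share -> 0: grouped and pooled SDs agree
        cfg = default_config(
            "edta", seed=3, between_sample_fraction=0.0,
            n_inflammatory_samples=200, n_infectious_samples=200,
            points_per_repeat=50, repeats_range=(1, 1), target_rows=None,
        )
        rows = generate_cohort(cfg)
        sub = rows[rows["label"] == "inflammatory"]
        pooled = sub["delta_f_hz"].std(ddof=1)
        within = sub.groupby("sample_id")["delta_f_hz"].std(ddof=1).mean()
        assert within == pytest.approx(pooled, rel=0.05)

    def test_point_level_auc_matches_binormal_prediction(self):
        # the marginal discriminability of the bandwidth shift is preserved
        cfg = _large_config(seed=4, n=400)
        rows = generate_cohort(cfg)
        expected = stats.binormal_auc(
            cfg.class_stats["inflammatory"].delta_gamma.mean,
            cfg.class_stats["inflammatory"].delta_gamma.sd,
            cfg.class_stats["infectious"].delta_gamma.mean,
            cfg.class_stats["infectious"].delta_gamma.sd,
        )
        roc = stats.roc_auc(
            rows["delta_gamma_hz"], rows["label"], positive="infectious"
        )
        assert roc.auc == pytest.approx(expected, abs=0.05)

    def test_physics_links_orient_the_correlations(self):
        rows = generate_cohort(_large_config(seed=6, n=500))
        sub = rows[rows["label"] == "inflammatory"]
        assert sub["delta_f_hz"].corr(sub["delta_gamma_hz"]) < -0.3
        assert sub["delta_f_hz"].corr(sub["eta_mpas"]) < -0.3
        assert sub["delta_gamma_hz"].corr(sub["eta_mpas"]) > 0.2

    def test_link_correlations_are_capped_and_shared(self):
        cfg = default_config("edta")
        rho_g, rho_e = link_correlations(cfg)
        assert 0 < rho_g <= cfg.max_link_correlation
        assert 0 < rho_e <= cfg.max_link_correlation


class TestClinicalCovariates:
    def test_wbc_lognormal_moment_match(self):
        # mean WBC across many synthetic infectious samples matches the target
        cfg = _large_config(seed=7, n=2000)
        rows = generate_cohort(
            default_config(
                "edta", seed=7, n_inflammatory_samples=2, n_infectious_samples=2000,
                points_per_repeat=1, repeats_range=(1, 1), target_rows=None,
            )
        )
        cov = generate_clinical_covariates(cfg, rows)
        sample_wbc = cov[cov["label"] == "infectious"].groupby("sample_id")[
            "wbc_per_mm3"
        ].first()
        assert sample_wbc.mean() == pytest.approx(52575.62, rel=0.10)

    def test_covariates_in_range_and_constant_within_sample(self, small_cohort):
        cfg = default_config("edta", seed=0)
        cov = generate_clinical_covariates(cfg, small_cohort)
        assert cov["neutrophils_pct"].between(0, 100).all()
        assert (cov["glucose_mg_dl"] >= 0).all()
        assert (cov["proteins_g_dl"] > 0).all()
        assert (cov.groupby("sample_id")[
            ["wbc_per_mm3", "neutrophils_pct", "glucose_mg_dl", "proteins_g_dl"]
        ].nunique() == 1).all().all()


class TestRawSweeps:
    def test_round_trip_through_extraction(self, edta_cohort):
        rows = edta_cohort.head(100)
        pairs = emit_raw_sweeps(rows, seed=1)
        df_err, dg_err, eta_err = [], [], []
        for pos, air, loaded in pairs:
            row = rows.iloc[pos]
            feats = featurize_pair(loaded, air)
            df_err.append(abs(feats.delta_f - row["delta_f_hz"]) / abs(row["delta_f_hz"]))
            dg_err.append(
                abs(feats.delta_gamma - row["delta_gamma_hz"]) / row["delta_gamma_hz"]
            )
            # the sweep encodes eta only through delta_f; compare against the
            # inversion of the row's own frequency shift
            eta_row = invert_viscosity(row["delta_f_hz"], SYNOVIAL_FLUID_DENSITY)
            eta_err.append(abs(feats.eta - eta_row) / eta_row)
        assert np.median(df_err) < 0.02
        assert np.median(dg_err) < 0.02
        assert np.median(eta_err) < 0.02

    def test_noiseless_shift_within_grid_step(self, edta_cohort):
        rows = edta_cohort.head(5)
        for pos, air, loaded in emit_raw_sweeps(rows, noise_sd=0.0, seed=0):
            row = rows.iloc[pos]
            feats = featurize_pair(loaded, air)
            grid_step = np.diff(loaded.frequencies).max()
            assert abs(feats.delta_f - row["delta_f_hz"]) < grid_step

    def test_emission_is_seeded(self, edta_cohort):
        rows = edta_cohort.head(3)
        a = emit_raw_sweeps(rows, noise_sd=0.01, seed=5)
        b = emit_raw_sweeps(rows, noise_sd=0.01, seed=5)
        for (_, air_a, loaded_a), (_, air_b, loaded_b) in zip(a, b):
            np.testing.assert_array_equal(air_a.conductance, air_b.conductance)
            np.testing.assert_array_equal(loaded_a.conductance, loaded_b.conductance)


def test_manifest_contents(tmp_path, small_cohort):
    cfg = default_config("edta", seed=0)
    path = tmp_path / "manifest.json"
    write_manifest(cfg, small_cohort, path)
    manifest = json.loads(path.read_text())
    assert manifest["n_rows"] == len(small_cohort)
    assert manifest["config"]["tube"] == "edta"
    assert sum(manifest["rows_per_class"].values()) == len(small_cohort)
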