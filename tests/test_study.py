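import json
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from osseosurf import phantom
from osseosurf.registration import ICPSettings
from osseosurf.study import (
    POOLED_AREA,
    POST,
    PRE,
    StudyConfig,
    export_report,
    load_report,
    run_reproducibility,
    run_trueness,
)


def _tiny_spec(noise=40.0, seed=0):
    return phantom.face_like_spec(
        semi_axes=(13.0, 15.0, 12.0), spacing=(0.8, 0.8, 0.8),
        psf_fwhm=1.4, noise_sigma=noise, seed=seed,
    )


def _tiny_config(**overrides):
    base = dict(
        settings={"a": _tiny_spec(), "b": _tiny_spec(noise=80.0)},
        n_subjects=2,
        repeats=2,
        repro_area_triangles=300,
        trueness_area_triangles=600,
        reference_triangles=400,
        truth_edge_mm=0.9,
        seed=1,
    )
    base.update(overrides)
    return StudyConfig(**base)


@pytest.fixture(scope="module")
def repro_report():
    return run_reproducibility(_tiny_config())


@pytest.fixture(scope="module")
def trueness_report():
    return run_trueness(_tiny_config())


class TestZeroVariabilityBaseline:
    def test_identical_inputs_give_zero_everywhere(self):
        """No noise and zero threshold spread → repeated segmentations are
        identical: zero MAD/SDAD at both levels and zero movements."""
        cfg = _tiny_config(
            settings={"a": _tiny_spec(noise=0.0)},
            n_subjects=1,
            threshold_spread=0.0,
        )
        report = run_reproducibility(cfg)
        assert np.allclose(report.deviations["mad"], 0.0, atol=1e-12)
        assert np.allclose(report.deviations["sdad"], 0.0, atol=1e-12)
        assert np.allclose(report.movements["value"], 0.0, atol=1e-6)


class TestReproReport:
    def test_every_comparison_present_exactly_once(self, repro_report):
        cfg = repro_report.config
        n_pairs = 1  # repeats=2
        areas = len(cfg.area_anchors) + 1  # + pooled
        expected = len(cfg.settings) * cfg.n_subjects * n_pairs * areas * 2
        assert len(repro_report.deviations) == expected
        key = ["setting", "subject", "pair", "area", "stage"]
        assert not repro_report.deviations.duplicated(subset=key).any()

    def test_movements_recorded_per_pair(self, repro_report):
        cfg = repro_report.config
        assert len(repro_report.movements) == len(cfg.settings) * cfg.n_subjects * 6

    def test_superimposition_reduces_mad(self, repro_report):
        """Level-1 (pre) MAD ≥ Level-3 (post) MAD for ≥ 95% of pairs."""
        piv = repro_report.deviations.pivot_table(
            index=["setting", "subject", "pair", "area"], columns="stage", values="mad"
        )
        ok = piv[PRE] + 1e-9 >= piv[POST]
        assert ok.mean() >= 0.95

    def test_pooled_mad_is_weighted_mean_of_areas(self, repro_report):
        dev = repro_report.deviations
        for key, g in dev.groupby(["setting", "subject", "pair", "stage"]):
            areas = g[g["area"] != POOLED_AREA]
            pooled = g[g["area"] == POOLED_AREA]
            expected = np.average(areas["mad"], weights=areas["n"])
            assert pooled["mad"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_threshold_streams_and_stats_present(self, repro_report):
        thr = repro_report.thresholds
        assert set(thr["stream"]) == {"operator_a", "operator_b"}
        st = repro_report.stat_results
        assert "thresholds" in st and "mad_pre" in st and "mad_post" in st
        assert "pooled" in st["mad_pre"]

    def test_determinism_of_rerun(self):
        cfg = _tiny_config(settings={"a": _tiny_spec()}, n_subjects=1)
        r1 = run_reproducibility(cfg)
        r2 = run_reproducibility(cfg)
        pd.testing.assert_frame_equal(r1.deviations, r2.deviations)
        pd.testing.assert_frame_equal(r1.movements, r2.movements)


class TestTruenessReport:
    def test_noise_free_trueness_bounded_by_half_voxel(self):
        """With no degradation, segmentation-vs-truth MAD stays below half
        the largest voxel dimension (marching-cubes localisation bound)."""
        spec = phantom.face_like_spec(
            semi_axes=(13.0, 15.0, 12.0), spacing=(0.8, 0.8, 0.8),
            psf_fwhm=0.0, noise_sigma=0.0, seed=0,
        )
        cfg = _tiny_config(settings={"clean": spec}, n_subjects=1, threshold_spread=0.0)
        report = run_trueness(cfg)
        assert report.deviations["mad"].max() <= 0.4  # half of 0.8 mm

    def test_trueness_monotone_in_noise(self):
        """Trueness degrades (MAD non-decreasing) across a fixed-seed noise
        ladder 0 → 20 → 40."""
        mads = []
        for noise in (0.0, 20.0, 40.0):
            cfg = _tiny_config(
                settings={"s": _tiny_spec(noise=noise)}, n_subjects=1
            )
            rep = run_trueness(cfg)
            pooled = rep.deviations[rep.deviations["area"] == POOLED_AREA]
            mads.append(pooled["mad"].iloc[0])
        assert mads[0] <= mads[1] + 1e-9
        assert mads[1] <= mads[2] + 1e-9

    def test_structure(self, trueness_report):
        cfg = trueness_report.config
        areas = len(cfg.area_anchors) + 1
        assert len(trueness_report.deviations) == len(cfg.settings) * cfg.n_subjects * areas
        assert (trueness_report.deviations["stage"] == POST).all()


class TestExport:
    def test_round_trip(self, tmp_path, repro_report):
        out = tmp_path / "run"
        export_report(repro_report, out)
        back = load_report(out)
        assert back.kind == "reproducibility"
        got = back.deviations[["setting", "subject", "pair", "area", "stage", "mad"]]
        want = repro_report.deviations[got.columns.tolist()]
        pd.testing.assert_frame_equal(
            got.reset_index(drop=True), want.reset_index(drop=True),
            check_dtype=False,
        )
        assert back.config.as_dict() == repro_report.config.as_dict()

    def test_missing_out_dir_created(self, tmp_path, trueness_report):
        out = tmp_path / "deep" / "run"
        export_report(trueness_report, out)
        assert (out / "manifest.json").exists()
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["kind"] == "trueness"
        assert manifest["config_hash"] == trueness_report.config.config_hash()

    def test_outlier_flags_in_export(self, tmp_path, repro_report):
        out = tmp_path / "flags"
        export_report(repro_report, out)
        dev = pd.read_csv(out / "deviations.csv")
        assert {"outlier_1_5", "outlier_3"} <= set(dev.columns)

    def test_colour_maps_written(self, tmp_path, repro_report):
        out = tmp_path / "maps_run"
        export_report(repro_report, out)
        plys = list((out / "maps").glob("*.ply"))
        pngs = list((out / "maps").glob("*.png"))
        assert plys and pngs


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = _tiny_config()
        p = tmp_path / "study.yaml"
        cfg.to_yaml(p)
        back = StudyConfig.from_yaml(p)
        assert back.as_dict() == cfg.as_dict()
        assert back.settings["a"] == cfg.settings["a"]
        assert back.icp == cfg.icp

    def test_validation(self):
        with pytest.raises(ValueError, match="repeats"):
            _tiny_config(repeats=1)
        with pytest.raises(ValueError, match="settings"):
            StudyConfig(settings={})

    def test_icp_settings_embedded(self):
        cfg = _tiny_config(icp=ICPSettings(iterations=30))
        back = StudyConfig.from_dict(cfg.as_dict())
        assert back.icp.iterations == 30
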