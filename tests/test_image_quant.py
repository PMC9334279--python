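"""Dye-infiltration and tracer-uptake pipelines plus group statistics."""

import numpy as np
import pytest

from tfus.image_quant import (
    FoamScan,
    SectionImage,
    foam_infiltration,
    group_stats,
    paired_t,
    tracer_uptake,
    tukey_critical_value,
    tukey_null_calibration,
)


class TestFoamInfiltration:
    def test_blank_scan_reports_zero(self):
        scan = FoamScan(np.full((50, 50), 255, dtype=np.uint8), 0.5, "front")
        out = foam_infiltration(scan)
        assert out["inlet_diameter_mm"] == 0.0 and out["empty"]

    def test_synthetic_disk_diameter(self):
        img = np.full((100, 100), 230.0)
        yy, xx = np.mgrid[:100, :100]
        img[np.hypot(yy - 50, xx - 50) <= 19.8] = 80.0  # 40 px across
        scan = FoamScan(img, 0.5, "front")
        out = foam_infiltration(scan)
        assert out["inlet_diameter_mm"] == pytest.approx(20.0, rel=0.02)

    def test_half_ellipse_depth(self):
        # 12-pixel-deep region at 0.5 mm/px -> 6 mm
        img = np.full((80, 80), 230.0)
        yy, xx = np.mgrid[:80, :80]
        half = (((yy - 10 + 0.5) / 12.0) ** 2 + ((xx - 40) / 20.0) ** 2 <= 1) & (yy >= 10)
        img[half] = 80.0
        scan = FoamScan(img, 0.5, "mid-section")
        assert foam_infiltration(scan)["depth_mm"] == pytest.approx(6.0, abs=0.25)

    def test_threshold_polarity_configurable(self):
        img = np.full((50, 50), 40.0)
        img[20:30, 20:30] = 250.0  # bright dye on dark foam
        scan = FoamScan(img, 1.0, "front")
        out = foam_infiltration(scan, dark_dye=False, threshold=150)
        assert out["inlet_diameter_mm"] > 0

    def test_largest_component_selected(self):
        img = np.full((100, 100), 230.0)
        img[40:60, 40:60] = 80.0  # 20 px blob
        img[5:8, 5:8] = 80.0  # speck
        out = foam_infiltration(FoamScan(img, 1.0, "front"))
        assert out["inlet_diameter_mm"] == pytest.approx(20 * np.sqrt(2), rel=0.1)


class TestTracerUptake:
    def brain_block(self, block_value=255.0):
        img = np.full((50, 50), 100.0)
        mask = np.ones((50, 50), dtype=bool)
        img[:10, :10] = block_value
        return img, mask

    def test_uniform_background_zero_uptake(self):
        img = np.full((40, 40), 120.0)
        sec = SectionImage(channels={"oa": img}, brain_mask=np.ones((40, 40), bool))
        assert tracer_uptake(sec).percent_uptake["oa"] == 0.0

    def test_block_fraction_recovered(self):
        # 2500-pixel brain, one 10x10 block at 255 over background 100 -> 4%
        img, mask = self.brain_block()
        sec = SectionImage(channels={"oa": img}, brain_mask=mask)
        assert tracer_uptake(sec).percent_uptake["oa"] == pytest.approx(4.0)

    def test_affine_intensity_invariance(self):
        img, mask = self.brain_block()
        a = tracer_uptake(SectionImage(channels={"oa": img}, brain_mask=mask))
        b = tracer_uptake(SectionImage(channels={"oa": 2.0 * img}, brain_mask=mask))
        c = tracer_uptake(SectionImage(channels={"oa": 0.5 * img + 30}, brain_mask=mask))
        assert a.percent_uptake == b.percent_uptake == c.percent_uptake

    def test_empty_brain_mask_rejected(self):
        sec = SectionImage(
            channels={"oa": np.ones((10, 10))}, brain_mask=np.zeros((10, 10), bool)
        )
        with pytest.raises(ValueError):
            tracer_uptake(sec)


class TestGroupStats:
    def test_hand_computed_anova_fixture(self):
        # SS_between = 6, SS_within = 6, df = (2, 6) -> F = 3.0
        gs = group_stats({"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]})
        assert gs.f_statistic == pytest.approx(3.0)
        assert (gs.df_between, gs.df_within) == (2, 6)

    def test_identical_groups_f_zero(self):
        gs = group_stats({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert gs.f_statistic == 0.0

    def test_minimum_group_requirements(self):
        with pytest.raises(ValueError):
            group_stats({"a": [1, 2, 3]})
        with pytest.raises(ValueError):
            group_stats({"a": [1, 2], "b": [3]})

    def test_tukey_detects_separated_group(self):
        gs = group_stats({"a": [0.1, -0.1, 0.0], "b": [0.0, 0.2, -0.2], "c": [5.0, 5.1, 4.9]})
        rej = {
            frozenset((r["group1"], r["group2"])): bool(r["reject"])
            for _, r in gs.tukey.iterrows()
        }
        assert rej[frozenset(("a", "c"))] and rej[frozenset(("b", "c"))]
        assert not rej[frozenset(("a", "b"))]

    def test_paired_t(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        out = paired_t(a, a + 1.0 + 1e-3 * np.array([1, -1, 1, -1]))
        assert out["p"] < 1e-6
        with pytest.raises(ValueError):
            paired_t([1, 2], [1, 2, 3])


class TestTukeyCalibration:
    def test_vectorized_rule_matches_library_decisions(self):
        """The cached-critical-value decision rule used for Monte-Carlo
        calibration agrees with the per-dataset Tukey HSD output."""
        rng = np.random.default_rng(11)
        q_crit = tukey_critical_value(0.05, 3, 15)
        for _ in range(25):
            groups = {k: rng.normal(0, 1, 6) for k in "abc"}
            gs = group_stats(groups)
            lib = bool(np.asarray(gs.tukey["reject"], dtype=bool).any())
            arrs = np.stack([groups[k] for k in "abc"])
            means, msw = arrs.mean(1), arrs.var(1, ddof=1).mean()
            fast = bool((means.max() - means.min()) / np.sqrt(msw / 6) > q_crit)
            assert lib == fast

    def test_family_wise_error_near_nominal(self):
        fwer = tukey_null_calibration(10_000, seed=2)
        assert fwer == pytest.approx(0.05, abs=0.01)
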