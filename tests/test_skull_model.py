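"""HU calibration, resampling and acoustic-property mapping."""

import numpy as np
import pytest

from tfus.skull_model import (
    LABEL_SKULL,
    LABEL_WATER,
    MaterialGrid,
    PropertyMapping,
    build_material_grid,
    calibrate_hu,
    hu_to_properties,
    resample_isotropic,
)
from tfus.sonication import WATER_24C, wavelength
from tfus.synthetic import PhantomSpec, make_phantom_ct, phantom_tube_mask
from tfus.volume import Volume


@pytest.fixture(scope="module")
def phantom():
    spec = PhantomSpec(seed=7, hu_offset=85.0, spacing_mm=0.5)
    return make_phantom_ct(spec), spec


class TestCalibration:
    def test_offset_removed_and_contrast_preserved(self, phantom):
        (ct, labels, truth), spec = phantom
        tube = phantom_tube_mask(ct, truth)
        cal = calibrate_hu(ct, tube)
        assert abs(float(cal.data[tube].mean())) < 1.0
        shell = np.asarray(labels.data) == LABEL_SKULL
        # bone-minus-water offsets survive the affine shift exactly
        contrast_raw = ct.data[shell].mean() - ct.data[tube].mean()
        contrast_cal = cal.data[shell].mean() - cal.data[tube].mean()
        assert contrast_cal == pytest.approx(contrast_raw, rel=1e-5)

    def test_idempotent(self, phantom):
        (ct, _, truth), _ = phantom
        tube = phantom_tube_mask(ct, truth)
        cal = calibrate_hu(ct, tube)
        cal2 = calibrate_hu(cal, tube)
        assert np.allclose(cal.data, cal2.data, atol=1e-3)

    def test_already_calibrated_unchanged(self):
        vol = Volume(np.zeros((4, 4, 4)), (1e-3,) * 3)
        roi = np.ones((4, 4, 4), dtype=bool)
        assert np.allclose(calibrate_hu(vol, roi).data, vol.data)

    def test_empty_roi_rejected(self):
        vol = Volume(np.zeros((4, 4, 4)), (1e-3,) * 3)
        with pytest.raises(ValueError):
            calibrate_hu(vol, np.zeros((4, 4, 4), dtype=bool))


class TestResampling:
    def test_constant_volume_stays_constant(self):
        vol = Volume(np.full((40, 40, 40), 123.0), (17e-6,) * 3)
        out = resample_isotropic(vol, 0.25e-3)
        assert np.allclose(out.data, 123.0)
        assert out.spacing == (0.25e-3,) * 3

    def test_dimensions_scale_with_spacing_ratio(self):
        vol = Volume(np.zeros((100, 80, 60)), (17e-6,) * 3)
        out = resample_isotropic(vol, 0.25e-3)
        expected = tuple(round(n * 17 / 250) for n in (100, 80, 60))
        assert all(abs(a - b) <= 1 for a, b in zip(out.shape, expected))

    def test_thirty_points_per_wavelength(self):
        # 0.25 mm spacing resolves the 7.5 mm wavelength with 30 voxels
        lam = wavelength(200e3, 1500.0)
        assert lam / 0.25e-3 == pytest.approx(30.0)

    def test_upsampling_rejected(self):
        vol = Volume(np.zeros((10, 10, 10)), (0.5e-3,) * 3)
        with pytest.raises(ValueError):
            resample_isotropic(vol, 0.1e-3)


class TestPropertyMapping:
    def test_water_endpoint(self):
        rho, c, a = hu_to_properties(0.0)
        assert (rho, c) == (WATER_24C.density, WATER_24C.sound_speed)
        assert a == 0.0

    def test_cortical_endpoint(self):
        m = PropertyMapping()
        rho, c, a = hu_to_properties(m.hu_max, m)
        assert rho == pytest.approx(m.bone_density)
        assert c == pytest.approx(m.bone_speed)
        assert a == pytest.approx(m.alpha_bone_min)

    def test_density_speed_monotone_in_hu(self):
        hu = np.linspace(0, 2500, 400)
        rho, c, _ = hu_to_properties(hu)
        assert np.all(np.diff(rho) >= -1e-9)
        assert np.all(np.diff(c) >= -1e-9)

    def test_skull_values_bounded_by_endpoints(self):
        m = PropertyMapping()
        hu = np.linspace(m.soft_threshold_hu + 1, m.hu_max, 100)
        rho, c, a = hu_to_properties(hu, m)
        assert np.all((rho >= m.soft.density - 50) & (rho <= m.bone_density))
        assert np.all((c >= m.soft.sound_speed) & (c <= m.bone_speed))
        assert np.all((a >= m.alpha_bone_min) & (a <= m.alpha_bone_max))

    def test_misordered_endpoints_rejected(self):
        with pytest.raises(ValueError):
            PropertyMapping(bone_speed=1000.0)
        with pytest.raises(ValueError):
            PropertyMapping(alpha_bone_max=1.0)


class TestMaterialGrid:
    def test_phantom_skull_dice(self, phantom):
        (ct, labels, truth), _ = phantom
        tube = phantom_tube_mask(ct, truth)
        cal = calibrate_hu(ct, tube)
        mat = build_material_grid(cal, labels=np.asarray(labels.data), frequency=200e3)
        gt = np.asarray(labels.data) == LABEL_SKULL
        pred = mat.tissue_label == LABEL_SKULL
        dice = 2 * (gt & pred).sum() / (gt.sum() + pred.sum())
        assert dice >= 0.95

    def test_water_voxels_carry_water_constants_exactly(self, phantom):
        (ct, labels, truth), _ = phantom
        cal = calibrate_hu(ct, phantom_tube_mask(ct, truth))
        mat = build_material_grid(cal, labels=np.asarray(labels.data))
        w = mat.tissue_label == LABEL_WATER
        assert np.all(mat.density[w] == np.float32(WATER_24C.density))
        assert np.all(mat.sound_speed[w] == np.float32(WATER_24C.sound_speed))
        assert np.all(mat.attenuation[w] == 0.0)

    def test_attenuation_frequency_scaling(self):
        m = PropertyMapping()
        hu = np.full((3, 3, 3), m.hu_max, dtype=np.float32)
        vol = Volume(hu, (0.25e-3,) * 3)
        ref = build_material_grid(vol, m)
        doubled = build_material_grid(vol, m, frequency=2 * m.reference_frequency)
        # bone attenuation scales linearly with frequency by default
        assert np.allclose(doubled.attenuation, 2 * ref.attenuation, rtol=1e-5)

    def test_homogeneous_grid(self):
        mat = MaterialGrid.homogeneous((5, 5, 5), 0.5e-3)
        assert mat.max_sound_speed == pytest.approx(WATER_24C.sound_speed)
        assert np.all(mat.tissue_label == LABEL_WATER)
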