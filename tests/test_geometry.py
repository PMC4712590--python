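"""Resampling, nipple angle, rotation and coronal slicing."""

import numpy as np
import pytest

from rgfbreast import (PhantomSpec, coronal_slices, generate_phantom, nipple_angle,
                       preprocess, resample_isotropic, rotate_about_si)
from rgfbreast.geometry import detect_nipple
from rgfbreast.io import LabeledVolume
from rgfbreast.rgf import subject_region_curves


def _as_volume(ob):
    """Re-wrap an OrientedBreast as a 1 mm LabeledVolume."""
    return LabeledVolume(breast_mask=ob.breast_mask, ft_mask=ob.ft_mask,
                         voxel_spacing_mm=(1.0, 1.0, 1.0),
                         nipple_voxel=ob.nipple_voxel)


def test_identity_resampling_is_a_noop(uniform_phantom_1mm):
    out = resample_isotropic(uniform_phantom_1mm)
    assert np.array_equal(out.breast_mask, uniform_phantom_1mm.breast_mask)
    assert np.array_equal(out.ft_mask, uniform_phantom_1mm.ft_mask)


def test_resampled_ellipsoid_volume_matches_closed_form():
    """A 2 mm solid ellipsoid resampled to 1 mm keeps its analytic volume
    within 5 %."""
    a, b, c = 30.0, 40.0, 25.0
    zz, yy, xx = np.meshgrid(*(np.arange(n) * 2.0 for n in (40, 50, 35)),
                             indexing="ij")
    mask = (((zz - 39) / a) ** 2 + ((yy - 49) / b) ** 2 + ((xx - 34) / c) ** 2) <= 1
    vol = LabeledVolume(breast_mask=mask, voxel_spacing_mm=(2.0, 2.0, 2.0))
    iso = resample_isotropic(vol)
    analytic = 4.0 / 3.0 * np.pi * a * b * c
    assert abs(iso.breast_mask.sum() - analytic) / analytic < 0.05


def test_degenerate_spacing_rejected():
    with pytest.raises(ValueError):
        LabeledVolume(breast_mask=np.ones((3, 3, 3), bool),
                      voxel_spacing_mm=(1.0, 0.0, 1.0))


def test_fc_stable_under_resampling():
    vol = generate_phantom(PhantomSpec(ft_mode="nonsparse", seed=9))
    iso = resample_isotropic(vol)
    assert abs(iso.fibroglandular_composition()
               - vol.fibroglandular_composition()) < 0.02


@pytest.mark.parametrize("offset, tol", [(0.0, 1.0), (30.0, 2.0), (-15.0, 2.0)])
def test_nipple_angle_recovers_phantom_tilt(offset, tol):
    vol = generate_phantom(PhantomSpec(nipple_offset_deg=offset, seed=6))
    iso = resample_isotropic(vol)
    angle = nipple_angle(iso)
    assert angle == pytest.approx(offset, abs=tol)
    assert -90.0 < angle <= 90.0


def test_nipple_autodetection_matches_constructed_landmark():
    vol = generate_phantom(PhantomSpec(nipple_offset_deg=20.0, seed=8))
    iso = resample_isotropic(vol)
    found = np.array(detect_nipple(iso))
    stored = np.array(iso.nipple_voxel)
    assert np.linalg.norm(found - stored) <= 3.0


def test_zero_rotation_is_identity(uniform_phantom_1mm):
    ob = rotate_about_si(uniform_phantom_1mm, 0.0)
    assert np.array_equal(ob.breast_mask, uniform_phantom_1mm.breast_mask)
    assert np.array_equal(ob.ft_mask, uniform_phantom_1mm.ft_mask)


def test_rotation_requires_isotropic_voxels():
    vol = generate_phantom(PhantomSpec(seed=0))  # 2.5 mm slices
    with pytest.raises(ValueError, match="isotropic"):
        rotate_about_si(vol, 10.0)


def test_region_curves_invariant_under_rotation(uniform_phantom_1mm):
    """Rotationally symmetric uniform-FT phantom: tilting the volume by 30
    degrees and correcting it through the preprocess path reproduces the
    region RGF curves (pointwise within 0.1, mean within 0.02)."""
    before = subject_region_curves(preprocess(uniform_phantom_1mm, nipple=None))
    tilted_ob = rotate_about_si(uniform_phantom_1mm, -30.0)
    tilted = _as_volume(tilted_ob)
    after = subject_region_curves(preprocess(tilted, nipple="auto"))
    for region in before:
        delta = after[region].values - before[region].values
        assert np.nanmax(np.abs(delta)) < 0.1, region
        assert abs(np.nanmean(delta)) < 0.02, region


def test_rotation_round_trip_dice(uniform_phantom_1mm):
    ob = rotate_about_si(uniform_phantom_1mm, 30.0)
    back = rotate_about_si(_as_volume(ob), -30.0)
    inter = (back.breast_mask & uniform_phantom_1mm.breast_mask).sum()
    dice = 2.0 * inter / (back.breast_mask.sum()
                          + uniform_phantom_1mm.breast_mask.sum())
    assert dice >= 0.98


def test_rotation_puts_nipple_on_anterior_axis():
    from scipy import ndimage
    vol = generate_phantom(PhantomSpec(nipple_offset_deg=25.0, seed=2))
    ob = preprocess(vol, nipple=None)
    centroid = ndimage.center_of_mass(ob.breast_mask)
    assert abs(ob.nipple_voxel[2] - centroid[2]) <= 2.0


def test_coronal_slices_order_and_subset():
    """~60 slices for a 60 mm anterior extent; chest wall slice is the
    largest; FT stays inside the breast on every slice."""
    vol = generate_phantom(PhantomSpec(seed=1))
    ob = preprocess(vol, nipple=None)
    slices = coronal_slices(ob)
    assert 55 <= len(slices) <= 65
    assert slices[0][0].sum() >= slices[-1][0].sum()
    for breast, ft in slices:
        assert not np.any(ft & ~breast)


def test_preprocess_requires_ft_mask(uniform_phantom_1mm):
    bare = LabeledVolume(breast_mask=uniform_phantom_1mm.breast_mask,
                         voxel_spacing_mm=(1.0, 1.0, 1.0))
    with pytest.raises(ValueError, match="FT mask"):
        preprocess(bare)
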