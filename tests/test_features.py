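"""The 13 RGF features: analytic cases, identities, undefined handling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rgfbreast import PhantomSpec, generate_phantom
from rgfbreast.features import compute_features, features_for_subject
from rgfbreast.geometry import OrientedBreast
from rgfbreast.rgf import RADII, RGFCurve


def _curve(values):
    return RGFCurve(radii=RADII.copy(), values=np.asarray(values, float))


def test_constant_curve():
    f = compute_features(_curve(np.full(100, 0.4)))
    for key in ("f1", "f5", "f6", "f8", "f9", "f11", "f12"):
        assert f[key] == pytest.approx(0.4, abs=1e-12), key
    for key in ("f2", "f3", "f7", "f10", "f13"):
        assert f[key] == pytest.approx(0.0, abs=1e-12), key
    assert f["f4"] == 0.01        # smallest r wins the tie


def test_linear_decreasing_curve_exact_values():
    """RGF(r_k) = 1 - r_k: every feature from independent 100-point arithmetic."""
    f = compute_features(_curve(1.0 - RADII))
    expected = {"f1": 0.495, "f3": -1.0, "f4": 0.01, "f5": 0.0, "f6": 0.99,
                "f7": 0.99, "f8": 0.745, "f9": 0.245, "f10": 0.5, "f11": 0.945,
                "f12": 0.045, "f13": 0.9}
    for key, val in expected.items():
        assert f[key] == pytest.approx(val, abs=1e-12), key


def test_linear_increasing_curve():
    f = compute_features(_curve(RADII.copy()))
    assert f["f3"] == pytest.approx(1.0, abs=1e-12)
    assert f["f4"] == 1.0
    assert f["f10"] == pytest.approx(-0.5, abs=1e-12)


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(0.0, 1.0), min_size=100, max_size=100),
       st.sets(st.integers(0, 99), max_size=10))
def test_difference_identities_and_bounds(values, nan_at):
    """f7, f10, f13 hold exactly; f5 <= f1 <= f6 and f12 <= f11, for any
    curve with at most 10 undefined points."""
    values = np.array(values)
    values[list(nan_at)] = np.nan
    f = compute_features(_curve(values))
    assert f["f7"] == f["f6"] - f["f5"]
    assert f["f10"] == f["f8"] - f["f9"]
    assert f["f13"] == f["f11"] - f["f12"]
    assert f["f5"] <= f["f1"] + 1e-12
    assert f["f1"] <= f["f6"] + 1e-12
    assert f["f12"] <= f["f11"] + 1e-12


@settings(deadline=None, max_examples=30)
@given(st.lists(st.floats(0.0, 1.0), min_size=100, max_size=100))
def test_slope_matches_closed_form(values):
    """OLS slope agrees with the closed-form covariance ratio to 1e-10."""
    v = np.array(values)
    f = compute_features(_curve(v))
    r = RADII
    closed = ((r * v).mean() - r.mean() * v.mean()) / ((r**2).mean() - r.mean() ** 2)
    assert f["f3"] == pytest.approx(closed, abs=1e-10)


def test_too_many_undefined_points_rejected():
    values = np.full(100, 0.5)
    values[:11] = np.nan
    with pytest.raises(ValueError, match="undefined"):
        compute_features(_curve(values))


def test_proportional_order_statistics_with_undefined_points():
    """With 95 defined values the 10 % features use round(9.5) = 10 values."""
    values = np.linspace(0, 0.94, 100)
    values[:5] = np.nan
    f = compute_features(_curve(values))
    defined = np.sort(values[~np.isnan(values)])
    assert f["f11"] == pytest.approx(defined[-10:].mean())
    assert f["f12"] == pytest.approx(defined[:10].mean())


def test_full_ft_phantom_features_are_saturated():
    """FT everywhere: mean RGF is exactly 1 in all three regions."""
    vol = generate_phantom(PhantomSpec(shape=(110, 84, 130),
                                       voxel_spacing_mm=(1.0, 1.0, 1.0),
                                       ft_mode="full", seed=0))
    ob = OrientedBreast(breast_mask=vol.breast_mask, ft_mask=vol.ft_mask,
                        rotation_angle_deg=0.0)
    per_region = features_for_subject(ob)
    assert list(per_region) == ["posterior", "middle", "anterior"]
    for feats in per_region.values():
        assert feats["f1"] == 1.0
        assert feats["f2"] == 0.0


def test_uniform_phantom_features_are_flat(uniform_phantom_1mm):
    """Uniform FT: small dispersion and near-zero slope in every region."""
    ob = OrientedBreast(breast_mask=uniform_phantom_1mm.breast_mask,
                        ft_mask=uniform_phantom_1mm.ft_mask,
                        rotation_angle_deg=0.0)
    for region, feats in features_for_subject(ob).items():
        assert feats["f2"] < 0.05, region
        assert abs(feats["f3"]) < 0.15, region


def test_nonsparse_phantom_middle_region_decays():
    vol = generate_phantom(PhantomSpec(shape=(110, 84, 130),
                                       voxel_spacing_mm=(1.0, 1.0, 1.0),
                                       ft_mode="nonsparse", seed=11))
    ob = OrientedBreast(breast_mask=vol.breast_mask, ft_mask=vol.ft_mask,
                        rotation_angle_deg=0.0)
    feats = features_for_subject(ob)["middle"]
    assert feats["f3"] < 0
    assert feats["f10"] > 0
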