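"""Reorientation of the supine axial breast into the coronal RGF frame.

The measurement frame requires (1) cubic 1 mm voxels and (2) the breast
axis — chest wall to nipple — aligned with the anterior direction, so that
coronal slices are perpendicular to that axis. The axis tilt is quantified
as the acute in-axial-plane angle between the anterior-posterior direction
and the chest-wall-plane normal through the nipple; the volume is then
rotated about the superior-inferior (SI) axis by that angle.

Masks are always interpolated linearly and re-binarized at 0.5, and the FT
mask is re-intersected with the breast mask after every interpolation, so
the subset invariant survives the pipeline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .io import LabeledVolume

__all__ = [
    "OrientedBreast",
    "resample_isotropic",
    "chest_wall_plane",
    "detect_nipple",
    "nipple_angle",
    "rotate_about_si",
    "coronal_slices",
    "preprocess",
    "BreastReorienter",
]


@dataclass
class OrientedBreast:
    """A breast volume at 1 mm isotropic voxels, nipple on the anterior axis.

    ``coronal_axis`` names the grid axis along which coronal slices are
    indexed (always 1, anterior -> posterior, in the canonical axis order).
    """

    breast_mask: np.ndarray
    ft_mask: np.ndarray
    rotation_angle_deg: float
    coronal_axis: int = 1
    nipple_voxel: tuple[int, int, int] | None = None
    intensities: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.breast_mask = np.asarray(self.breast_mask) > 0
        self.ft_mask = np.asarray(self.ft_mask) > 0
        if self.ft_mask.shape != self.breast_mask.shape:
            raise ValueError("mask shapes differ")
        if np.any(self.ft_mask & ~self.breast_mask):
            raise ValueError("ft_mask must be a subset of breast_mask")
        if not -90.0 <= self.rotation_angle_deg <= 90.0:
            raise ValueError("rotation angle must be acute (|angle| <= 90)")

    def fibroglandular_composition(self) -> float:
        n = int(self.breast_mask.sum())
        if n == 0:
            raise ValueError("empty breast mask")
        return float(self.ft_mask.sum()) / n


def _is_isotropic_1mm(spacing) -> bool:
    return bool(np.allclose(spacing, 1.0, atol=1e-6))


def resample_isotropic(vol: LabeledVolume) -> LabeledVolume:
    """Resample a volume to cubic 1 mm voxels (linear interpolation).

    Masks are interpolated as floats then re-binarized at 0.5; the FT mask
    is intersected with the breast mask afterwards. A volume that is already
    1 mm isotropic is returned unchanged (identity, no interpolation).
    """
    spacing = vol.voxel_spacing_mm
    if any(s <= 0 for s in spacing):
        raise ValueError(f"degenerate voxel spacing {spacing}")
    if _is_isotropic_1mm(spacing):
        return vol

    def _zoom(arr, is_mask):
        out = ndimage.zoom(np.asarray(arr, dtype=float), zoom=spacing, order=1,
                           mode="grid-constant", grid_mode=True)
        return out >= 0.5 if is_mask else out

    breast = _zoom(vol.breast_mask, True)
    ft = _zoom(vol.ft_mask, True) & breast if vol.ft_mask is not None else None
    intens = _zoom(vol.intensities, False) if vol.intensities is not None else None
    nipple = None
    if vol.nipple_voxel is not None:
        nipple = tuple(
            int(round((i + 0.5) * s - 0.5)) for i, s in zip(vol.nipple_voxel, spacing)
        )
    return LabeledVolume(
        breast_mask=breast, ft_mask=ft, intensities=intens,
        voxel_spacing_mm=(1.0, 1.0, 1.0), nipple_voxel=nipple, meta=dict(vol.meta),
    )


# --------------------------------------------------------------------------
# Chest wall plane and nipple
# --------------------------------------------------------------------------

def chest_wall_plane(vol: LabeledVolume) -> tuple[float, float, float]:
    """Least-squares chest-wall plane of the posterior breast-mask boundary.

    The plane is y = alpha * x_si + beta * x_lr + gamma in mm (y = AP
    coordinate). Fitted by RANSAC over the posterior boundary voxels: the
    chest wall is the largest planar subset of that boundary, so a consensus
    fit rejects the curved-surface rim that also faces posterior when the
    breast axis is tilted in-plane. Deterministic (fixed internal seed).
    """
    breast = vol.breast_mask
    s0, s1, s2 = vol.voxel_spacing_mm
    # posterior boundary: breast voxels whose posterior (AP+1) neighbour is outside
    post_neigh = np.zeros_like(breast)
    post_neigh[:, :-1, :] = breast[:, 1:, :]
    boundary = breast & ~post_neigh
    pts = np.argwhere(boundary).astype(float)
    if len(pts) < 3:
        raise ValueError("breast mask too small to fit a chest-wall plane")
    x_si, y_ap, x_lr = pts[:, 0] * s0, pts[:, 1] * s1, pts[:, 2] * s2
    A = np.column_stack([x_si, x_lr, np.ones(len(pts))])

    rng = np.random.default_rng(0)
    tol = 2.0          # mm
    best_inliers = None
    best_count = -1
    for _ in range(300):
        tri = rng.choice(len(pts), size=3, replace=False)
        try:
            coef = np.linalg.solve(A[tri], y_ap[tri])
        except np.linalg.LinAlgError:
            continue
        if abs(coef[0]) > 2.0 or abs(coef[1]) > 2.0:   # steeper than ~63 deg: not a chest wall
            continue
        resid = np.abs(A @ coef - y_ap)
        count = int((resid <= tol).sum())
        if count > best_count:
            best_count = count
            best_inliers = resid <= tol
    if best_inliers is None or best_count < 3:
        raise ValueError("could not find a planar chest-wall boundary")
    keep = best_inliers
    for _ in range(3):
        coef, *_ = np.linalg.lstsq(A[keep], y_ap[keep], rcond=None)
        new_keep = np.abs(A @ coef - y_ap) <= tol
        if new_keep.sum() < 3 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    alpha, beta, gamma = (float(c) for c in coef)
    return alpha, beta, gamma


def detect_nipple(vol: LabeledVolume) -> tuple[int, int, int]:
    """Auto-detect the nipple: the breast voxel with maximal perpendicular
    distance anterior of the chest-wall plane."""
    alpha, beta, gamma = chest_wall_plane(vol)
    s0, s1, s2 = vol.voxel_spacing_mm
    idx = np.argwhere(vol.breast_mask).astype(float)
    x_si, y_ap, x_lr = idx[:, 0] * s0, idx[:, 1] * s1, idx[:, 2] * s2
    # signed distance, positive toward anterior (smaller AP coordinate)
    dist = (alpha * x_si + beta * x_lr + gamma - y_ap) / math.sqrt(
        1.0 + alpha * alpha + beta * beta
    )
    # the apex is a shallow extremum: average the near-maximal candidates
    near = dist >= dist.max() - 1.0
    best = idx[near].mean(axis=0)
    return tuple(int(round(i)) for i in best)


def nipple_angle(vol: LabeledVolume, auto_detect: bool = True) -> float:
    """Acute in-axial-plane angle (degrees) between the anterior-posterior
    axis and the chest-wall-normal line through the nipple.

    A positive angle means the breast axis leans toward the +LR (patient
    right) direction; the same signed angle fed to :func:`rotate_about_si`
    brings the nipple onto the anterior axis.
    """
    if vol.nipple_voxel is None and not auto_detect:
        raise ValueError("no nipple landmark present and auto-detection disabled")
    _, beta, _ = chest_wall_plane(vol)
    angle = math.degrees(math.atan(beta))
    # fold to the acute range (atan already lands in (-90, 90))
    return float(angle)


# --------------------------------------------------------------------------
# Rotation and slicing
# --------------------------------------------------------------------------

def rotate_about_si(vol: LabeledVolume, angle_deg: float) -> OrientedBreast:
    """Rotate every axial plane in-plane by ``-angle_deg`` about the breast
    centroid so that a breast axis at ``+angle_deg`` lands on the anterior axis.

    Requires 1 mm isotropic voxels. Linear interpolation; out-of-grid samples
    read as background; masks re-binarized at 0.5 and FT intersected with the
    breast.
    """
    if not _is_isotropic_1mm(vol.voxel_spacing_mm):
        raise ValueError("rotate_about_si requires a 1 mm isotropic volume; "
                         "run resample_isotropic first")
    theta = math.radians(angle_deg)
    c_, s_ = math.cos(theta), math.sin(theta)
    # maps output offsets to input offsets in the (AP, LR) plane
    M = np.array([
        [1.0, 0.0, 0.0],
        [0.0, c_, s_],
        [0.0, -s_, c_],
    ])
    centroid = np.array(ndimage.center_of_mass(vol.breast_mask))
    offset = centroid - M @ centroid

    def _warp(arr, is_mask):
        out = ndimage.affine_transform(np.asarray(arr, dtype=float), M, offset=offset,
                                       order=1, mode="constant", cval=0.0)
        return out >= 0.5 if is_mask else out

    breast = _warp(vol.breast_mask, True)
    if vol.ft_mask is None:
        raise ValueError("rotate_about_si needs an FT mask (run segmentation first)")
    ft = _warp(vol.ft_mask, True) & breast
    intens = _warp(vol.intensities, False) if vol.intensities is not None else None

    nipple = None
    if vol.nipple_voxel is not None:
        p = np.asarray(vol.nipple_voxel, dtype=float)
        q = centroid + M.T @ (p - centroid)
        nipple = tuple(int(round(x)) for x in q)

    return OrientedBreast(
        breast_mask=breast, ft_mask=ft, rotation_angle_deg=float(angle_deg),
        nipple_voxel=nipple, intensities=intens, meta=dict(vol.meta),
    )


def coronal_slices(ob: OrientedBreast) -> list[tuple[np.ndarray, np.ndarray]]:
    """Ordered (breast, FT) coronal mask pairs, chest wall first.

    Slice 0 is the posterior-most non-empty coronal plane (the chest wall),
    the last slice the anterior-most (the nipple); empty leading/trailing
    planes are trimmed.
    """
    breast, ft = ob.breast_mask, ob.ft_mask
    if not breast.any():
        raise ValueError("empty breast mask")
    nonempty = np.nonzero(breast.any(axis=(0, 2)))[0]
    first, last = int(nonempty.min()), int(nonempty.max())
    # posterior = high AP index -> iterate downward
    return [(breast[:, j, :], ft[:, j, :]) for j in range(last, first - 1, -1)]


def preprocess(vol: LabeledVolume, nipple: str | tuple[int, int, int] | None = "auto",
               ) -> OrientedBreast:
    """Full reorientation: resample to 1 mm, measure the nipple angle, rotate.

    ``nipple`` may be an explicit voxel index (in the *input* grid), "auto"
    to detect it from the mask, or None to use the landmark stored on the
    volume (falling back to auto-detection).
    """
    if vol.ft_mask is None:
        raise ValueError("preprocess requires an FT mask; run segmentation first")
    iso = resample_isotropic(vol)
    if isinstance(nipple, (tuple, list)):
        scaled = tuple(
            int(round((i + 0.5) * s - 0.5))
            for i, s in zip(nipple, vol.voxel_spacing_mm)
        )
        iso.nipple_voxel = scaled
    elif nipple == "auto" or iso.nipple_voxel is None:
        iso.nipple_voxel = detect_nipple(iso)
    angle = nipple_angle(iso)
    ob = rotate_about_si(iso, angle)
    if ob.nipple_voxel is not None:
        centroid = np.array(ndimage.center_of_mass(ob.breast_mask))
        off_lr = abs(ob.nipple_voxel[2] - centroid[2])
        if off_lr > 5.0:
            warnings.warn(
                f"nipple {off_lr:.1f} voxels off the anterior axis after rotation; "
                "check the landmark or mask quality", stacklevel=2,
            )
    return ob


class BreastReorienter(BaseEstimator, TransformerMixin):
    """Transformer mapping LabeledVolume sequences to OrientedBreast sequences.

    Stateless (fit is a no-op); exists so the reorientation step composes
    with sklearn pipelines.

    Parameters
    ----------
    nipple : "auto" or None
        Landmark policy passed to :func:`preprocess` for every volume.
    """

    def __init__(self, nipple: str | None = "auto"):
        self.nipple = nipple

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> list[OrientedBreast]:
        return [preprocess(vol, nipple=self.nipple) for vol in X]
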