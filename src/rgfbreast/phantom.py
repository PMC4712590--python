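"""Synthetic breast CT phantoms with controllable fibroglandular distributions.

The breast is modelled as a half-ellipsoid attached to a flat chest-wall
plane; the breast axis (chest wall centre to nipple) may be tilted in the
axial plane by ``nipple_offset_deg``, emulating the lateral orientation of a
supine breast. Fibroglandular tissue (FT) is laid down inside the breast in
one of several modes:

* ``nonsparse`` — per-slice, per-radial-bin thresholding of a smooth random
  field against an exponentially decaying occupancy target: FT is condensed
  near the breast axis and thins toward the periphery, so the radial
  glandular fraction falls from the centre (r = 0) to the edge (r = 1).
* ``sparse``    — small FT clusters (prolate ellipsoids, elongated along the
  superior-inferior axis like ductal structures) dropped uniformly at random
  until the target composition is met: the radial profile is near flat.
* ``uniform``   — the same stratified thresholding with a constant occupancy
  target, giving a flat radial profile at the target composition.
* ``annulus``   — FT exactly in a band of relative radius (diagnostic mode).
* ``full`` / ``empty`` — degenerate masks for exact end-to-end checks.

All randomness flows from the single integer seed of the spec; cohort
generation splits it with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import LabeledVolume

__all__ = ["PhantomSpec", "PhantomSizeError", "generate_phantom", "generate_cohort",
           "render_intensities"]

FT_MODES = ("nonsparse", "sparse", "uniform", "annulus", "empty", "full")

#: smoothing lengths (mm, per canonical axis) of the noise field; FT
#: structures must stay wider than the slice thickness so linear
#: interpolation + re-thresholding preserves their volume
NOISE_SIGMA_MM = (5.0, 3.0, 3.0)


class PhantomSizeError(ValueError):
    """The requested breast ellipsoid does not fit inside the voxel grid."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic breast volume.

    Defaults emulate a radiotherapy planning CT: 2.5 mm slices along the
    superior-inferior axis, 1 mm in-plane, a breast of roughly 80 x 60 x
    90 mm (SI x chest-to-nipple x LR) and a fibroglandular composition of
    about 25 %. ``posterior_margin_mm`` leaves grid space behind the chest
    wall, needed when the generated volume will itself be rotated in place.
    """

    shape: tuple[int, int, int] = (44, 84, 130)
    voxel_spacing_mm: tuple[float, float, float] = (2.5, 1.0, 1.0)
    breast_halfaxes_mm: tuple[float, float, float] = (40.0, 60.0, 45.0)
    nipple_offset_deg: float = 0.0
    ft_mode: str = "nonsparse"
    ft_fraction: float = 0.25
    cluster_radius_mm: float = 3.0
    decay_scale: float = 25.0
    annulus_bounds: tuple[float, float] = (0.4, 0.7)
    posterior_margin_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ft_mode not in FT_MODES:
            raise ValueError(f"unknown ft_mode {self.ft_mode!r}; choose from {FT_MODES}")
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError("shape must be 3 positive integers")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if any(h <= 0 for h in self.breast_halfaxes_mm):
            raise ValueError("breast half-axes must be positive")
        if not 0.0 <= self.ft_fraction <= 1.0:
            raise ValueError("ft_fraction must lie in [0, 1]")
        if self.cluster_radius_mm <= 0 or self.decay_scale <= 0:
            raise ValueError("cluster_radius_mm and decay_scale must be positive")
        lo, hi = self.annulus_bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("annulus_bounds must satisfy 0 <= lo < hi <= 1")


def _grid_mm(spec: PhantomSpec):
    """Voxel-centre coordinates in mm along each canonical axis."""
    return [np.arange(n) * s for n, s in zip(spec.shape, spec.voxel_spacing_mm)]


def _breast_geometry(spec: PhantomSpec):
    """Breast mask, ellipsoid centre (mm) and nipple position (mm).

    The chest-wall plane is the plane through the ellipsoid centre whose
    normal is the (possibly tilted) breast axis; the mask is the anterior
    half of the ellipsoid.
    """
    a_si, b_ap, c_lr = spec.breast_halfaxes_mm
    theta = math.radians(spec.nipple_offset_deg)
    s, c = math.sin(theta), math.cos(theta)
    ext = [n * sp for n, sp in zip(spec.shape, spec.voxel_spacing_mm)]

    # supports of the tilted half-ellipsoid around its centre
    ant_support = math.sqrt((b_ap * c) ** 2 + (c_lr * s) ** 2)
    post_support = abs(s) * c_lr          # base disc leans backwards when tilted
    lr_support = math.sqrt((b_ap * s) ** 2 + (c_lr * c) ** 2)

    margin = 2.0
    post_margin = spec.posterior_margin_mm
    center = np.array([ext[0] / 2.0, ext[1] - post_support - post_margin, ext[2] / 2.0])
    if (a_si + margin > ext[0] / 2.0
            or ant_support + post_support + margin + post_margin > ext[1]
            or lr_support + margin > ext[2] / 2.0):
        raise PhantomSizeError(
            f"breast half-axes {spec.breast_halfaxes_mm} mm (tilt "
            f"{spec.nipple_offset_deg} deg) exceed grid extent {tuple(ext)} mm"
        )

    g0, g1, g2 = _grid_mm(spec)
    u0 = g0[:, None, None] - center[0]
    u1 = g1[None, :, None] - center[1]
    u2 = g2[None, None, :] - center[2]
    # local frame: l1 along the breast axis (negative = anterior), l2 across
    l1 = c * u1 - s * u2
    l2 = s * u1 + c * u2
    inside = (u0 / a_si) ** 2 + (l1 / b_ap) ** 2 + (l2 / c_lr) ** 2 <= 1.0
    breast = inside & (l1 <= 0)
    nipple_mm = center + np.array([0.0, -b_ap * c, b_ap * s])
    return breast, center, nipple_mm


def _slice_radial_maps(breast: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    """Per-coronal-slice distance (mm) from the slice breast centroid and the
    relative radius d / R_equivalent. Returned maps are NaN outside the breast."""
    s0, _, s2 = spacing
    dist = np.full(breast.shape, np.nan)
    rel = np.full(breast.shape, np.nan)
    px_area = s0 * s2
    for j in range(breast.shape[1]):
        sl = breast[:, j, :]
        n = sl.sum()
        if n == 0:
            continue
        ii, kk = np.nonzero(sl)
        cy, cx = ii.mean(), kk.mean()
        d = np.hypot((ii - cy) * s0, (kk - cx) * s2)
        r_eq = math.sqrt(n * px_area / math.pi)
        dist[ii, j, kk] = d
        rel[ii, j, kk] = d / r_eq
    return dist, rel


def _smooth_noise(shape, spacing, rng) -> np.ndarray:
    """Unit-variance Gaussian random field with ~NOISE_SIGMA_MM correlation."""
    sigma_vox = [sig / s for sig, s in zip(NOISE_SIGMA_MM, spacing)]
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _occupancy_scale(weights: np.ndarray, counts: np.ndarray, target: float) -> float:
    """Scale c such that mean over voxels of min(c * w, 1) equals ``target``.

    Solved by bisection; the left side is monotone in c.
    """
    total = counts.sum()

    def realized(c):
        return float((np.minimum(c * weights, 1.0) * counts).sum()) / total

    lo, hi = 0.0, 1.0
    while realized(hi) < target and hi < 1e9:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target:
            lo = mid
        else:
            hi = mid
    return hi


def _stratified_threshold(breast: np.ndarray, dist: np.ndarray, noise: np.ndarray,
                          target_frac: float, decay_scale: float | None) -> np.ndarray:
    """FT by per-slice, per-radial-bin quantile thresholding of the noise field.

    Each coronal slice is split into 1 mm radial bins around the slice
    centroid; in each bin the highest-noise voxels are selected so that the
    bin's occupancy matches the radial target min(c * w(d), 1), with
    w(d) = exp(-d / decay_scale) (or w = 1 when ``decay_scale`` is None,
    the flat/uniform case) and c calibrated per slice so the slice-mean
    occupancy equals ``target_frac``. This pins the radial glandular
    fraction profile by construction while the smooth noise keeps the FT
    structures several voxels wide.
    """
    ft = np.zeros_like(breast)
    if target_frac <= 0:
        return ft
    for j in range(breast.shape[1]):
        sl = breast[:, j, :]
        n = int(sl.sum())
        if n == 0:
            continue
        d = dist[:, j, :][sl]
        z = noise[:, j, :][sl]
        bins = np.floor(d).astype(int)
        uniq, inv, counts = np.unique(bins, return_inverse=True, return_counts=True)
        if decay_scale is None:
            w = np.ones(len(uniq))
        else:
            w = np.exp(-(uniq + 0.5) / decay_scale)
        c = _occupancy_scale(w, counts, min(target_frac, 1.0))
        occ = np.minimum(c * w, 1.0)
        sel = np.zeros(n, dtype=bool)
        order = np.argsort(-z)              # highest noise first
        inv_sorted = inv[order]
        for b, (n_b, p_b) in enumerate(zip(counts, occ)):
            take = int(round(p_b * n_b))
            members = order[inv_sorted == b][:take]
            sel[members] = True
        plane = np.zeros_like(sl)
        plane[sl] = sel
        ft[:, j, :] = plane
    return ft


#: superior-inferior elongation of sparse-mode clusters (prolate ellipsoids);
#: keeps clusters resolvable at the slice thickness
CLUSTER_SI_ELONGATION = 1.5


def _sparse_clusters(spec: PhantomSpec, breast: np.ndarray, rng) -> np.ndarray:
    """Drop random ellipsoidal clusters until the FC target is met."""
    target = spec.ft_fraction
    n_breast = int(breast.sum())
    ft = np.zeros_like(breast)
    if target <= 0:
        return ft
    idx = np.argwhere(breast)
    spacing = np.asarray(spec.voxel_spacing_mm)
    r = spec.cluster_radius_mm
    # precompute the cluster footprint in voxels
    half_mm = np.array([r * CLUSTER_SI_ELONGATION, r, r])
    half = np.ceil(half_mm / spacing).astype(int)
    off = np.stack(np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij"), -1)
    ball = off[(((off * spacing) / half_mm) ** 2).sum(axis=-1) <= 1.0]
    for _ in range(100_000):
        center = idx[rng.integers(len(idx))]
        pts = center + ball
        ok = np.all((pts >= 0) & (pts < np.array(breast.shape)), axis=1)
        pts = pts[ok]
        sel = breast[pts[:, 0], pts[:, 1], pts[:, 2]]
        pts = pts[sel]
        ft[pts[:, 0], pts[:, 1], pts[:, 2]] = True
        if ft.sum() / n_breast >= target:
            return ft
    raise ValueError(
        f"ft_fraction={target} unreachable with cluster_radius_mm={r} for this geometry"
    )


def generate_phantom(spec: PhantomSpec) -> LabeledVolume:
    """Generate one phantom volume; deterministic for a given spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    breast, center, nipple_mm = _breast_geometry(spec)
    if not breast.any():
        raise PhantomSizeError("breast mask is empty; enlarge the grid or half-axes")

    mode = spec.ft_mode
    if mode == "full":
        ft = breast.copy()
    elif mode == "empty":
        ft = np.zeros_like(breast)
    elif mode == "sparse":
        ft = _sparse_clusters(spec, breast, rng)
    else:
        dist, rel = _slice_radial_maps(breast, spec.voxel_spacing_mm)
        if mode == "annulus":
            lo, hi = spec.annulus_bounds
            ft = breast & (rel >= lo) & (rel < hi)
        else:
            noise = _smooth_noise(spec.shape, spec.voxel_spacing_mm, rng)
            decay = spec.decay_scale if mode == "nonsparse" else None
            ft = _stratified_threshold(breast, dist, noise, spec.ft_fraction, decay)

    if mode in ("nonsparse", "sparse", "uniform"):
        fc = ft.sum() / breast.sum()
        if abs(fc - spec.ft_fraction) > 0.05:
            raise ValueError(
                f"realized FC {fc:.3f} misses target {spec.ft_fraction} by more than 0.05"
            )

    nipple_vox = _nearest_breast_voxel(breast, nipple_mm, spec.voxel_spacing_mm)
    return LabeledVolume(
        breast_mask=breast,
        ft_mask=ft,
        voxel_spacing_mm=spec.voxel_spacing_mm,
        nipple_voxel=nipple_vox,
        meta={"ft_mode": mode, "nipple_offset_deg": spec.nipple_offset_deg,
              "seed": spec.seed},
    )


def _nearest_breast_voxel(breast, point_mm, spacing):
    """Breast voxel closest (in mm) to a physical point."""
    idx = np.argwhere(breast)
    d2 = (((idx * np.asarray(spacing)) - np.asarray(point_mm)) ** 2).sum(1)
    return tuple(int(i) for i in idx[int(np.argmin(d2))])


def render_intensities(vol: LabeledVolume, fat_hu: float = -100.0, ft_hu: float = 40.0,
                       noise_sigma: float = 10.0, seed: int = 0) -> LabeledVolume:
    """Two-level HU rendering (fat / fibroglandular) with additive Gaussian
    noise, for exercising intensity-based segmentation. Air is -1000 HU."""
    if vol.ft_mask is None:
        raise ValueError("volume has no FT mask to render")
    rng = np.random.default_rng(seed)
    img = np.full(vol.shape, -1000.0)
    img[vol.breast_mask] = fat_hu
    img[vol.ft_mask] = ft_hu
    img += rng.normal(0.0, noise_sigma, size=vol.shape)
    out = vol.copy()
    out.intensities = img
    return out


def generate_cohort(
    n_nonsparse: int,
    n_sparse: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[tuple[LabeledVolume, str]]:
    """Generate a labelled cohort with per-subject anatomical jitter.

    Half-axes are jittered by +/-10 %, the FT composition target by +/-0.07
    (group-independent, so FC itself carries no group signal), the nipple
    tilt is drawn in [-20, 20] degrees and the mode-specific scale parameters
    are jittered by +/-20 %. Group 1 subjects use the non-sparse mode, group
    2 the sparse mode.
    """
    if n_nonsparse < 1 or n_sparse < 1:
        raise ValueError("both group counts must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    labels = ["nonsparse"] * n_nonsparse + ["sparse"] * n_sparse
    children = np.random.SeedSequence(seed).spawn(len(labels))
    cohort = []
    for label, child in zip(labels, children):
        rng = np.random.default_rng(child)
        ha = tuple(h * rng.uniform(0.9, 1.1) for h in base.breast_halfaxes_mm)
        spec = replace(
            base,
            breast_halfaxes_mm=ha,
            ft_fraction=float(np.clip(base.ft_fraction + rng.uniform(-0.07, 0.07),
                                      0.05, 0.95)),
            nipple_offset_deg=float(rng.uniform(-20.0, 20.0)),
            decay_scale=base.decay_scale * rng.uniform(0.8, 1.2),
            cluster_radius_mm=base.cluster_radius_mm * rng.uniform(0.8, 1.2),
            ft_mode=label,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        cohort.append((generate_phantom(spec), label))
    return cohort
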