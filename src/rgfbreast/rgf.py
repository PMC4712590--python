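"""Radial glandular fraction (RGF) curves per coronal slice and breast region.

For a coronal slice, the breast's area-equivalent radius R satisfies
pi R^2 = breast pixel area. The RGF at relative radius r is the fraction of
fibroglandular pixels among the breast pixels lying on the circle of radius
r * R centred at the breast mask's centre of mass. Circles are rasterized as
1-pixel-wide annuli: a pixel at distance d belongs to the circle of radius
rho when d is in [rho - 0.5, rho + 0.5). One hundred relative radii are
sampled, r_k = k/100 for k = 1..100.

The whole breast (chest wall to nipple) is split into three equal regions —
posterior, middle, anterior — and each region's curve is the pointwise mean
of the five slice curves centred on the region's middle slice.

An RGF value is *undefined* (NaN) at radii where the annulus contains no
breast pixel; undefined points are skipped, never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import OrientedBreast, coronal_slices

__all__ = [
    "N_RADII",
    "RGFCurve",
    "RegionScheme",
    "REGION_IDS",
    "breast_radius",
    "slice_rgf",
    "define_regions",
    "region_rgf",
    "subject_region_curves",
]

#: number of relative-radius samples per curve
N_RADII = 100

REGION_IDS = ("posterior", "middle", "anterior")

#: the fixed relative-radius grid r_k = k/100, k = 1..100
RADII = np.arange(1, N_RADII + 1) / N_RADII


@dataclass
class RGFCurve:
    """One RGF curve: 100 (relative radius, fraction) pairs.

    ``values`` entries are NaN where the curve is undefined.
    """

    radii: np.ndarray
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.radii.shape != (N_RADII,) or self.values.shape != (N_RADII,):
            raise ValueError(f"curve must have exactly {N_RADII} samples")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        defined = ~np.isnan(self.values)
        if np.any((self.values[defined] < 0) | (self.values[defined] > 1)):
            raise ValueError("defined RGF values must lie in [0, 1]")

    @property
    def n_defined(self) -> int:
        return int((~np.isnan(self.values)).sum())


@dataclass
class RegionScheme:
    """Division of the coronal slice range into three equal regions."""

    n_slices: int
    boundaries: tuple[int, int]       # region edges: [0, b0), [b0, b1), [b1, N)
    central_slices: tuple[int, int, int]
    window: int = 5

    def region_range(self, region: str) -> tuple[int, int]:
        b0, b1 = self.boundaries
        return {
            "posterior": (0, b0),
            "middle": (b0, b1),
            "anterior": (b1, self.n_slices),
        }[region]


def breast_radius(slice_mask: np.ndarray, pixel_area_mm2: float = 1.0) -> float:
    """Area-equivalent breast radius R (mm): pi R^2 = breast pixel area."""
    area = float(np.count_nonzero(slice_mask)) * pixel_area_mm2
    if area == 0:
        raise ValueError("empty breast slice")
    return float(np.sqrt(area / np.pi))


def slice_rgf(breast_slice: np.ndarray, ft_slice: np.ndarray,
              provenance: str = "") -> RGFCurve:
    """RGF curve of one coronal slice.

    The circle centre is the centre of mass of the breast mask; both the
    numerator (FT pixels) and the denominator are restricted to breast
    pixels, since a circle can leave the (non-circular) breast contour.
    """
    breast = np.asarray(breast_slice) > 0
    ft = np.asarray(ft_slice) > 0
    if breast.shape != ft.shape:
        raise ValueError("slice shapes differ")
    if np.any(ft & ~breast):
        raise ValueError("FT slice must be a subset of the breast slice")
    ii, jj = np.nonzero(breast)
    if len(ii) == 0:
        raise ValueError("empty breast slice")
    cy, cx = ii.mean(), jj.mean()
    R = breast_radius(breast)
    dist = np.hypot(ii - cy, jj - cx)
    ft_flags = ft[ii, jj]

    values = np.full(N_RADII, np.nan)
    for k, r in enumerate(RADII):
        rho = r * R
        in_annulus = (dist >= rho - 0.5) & (dist < rho + 0.5)
        denom = int(in_annulus.sum())
        if denom > 0:
            values[k] = float(ft_flags[in_annulus].sum()) / denom
    return RGFCurve(radii=RADII.copy(), values=values, provenance=provenance)


def define_regions(slices, window: int = 5) -> RegionScheme:
    """Split the ordered coronal slice range into three equal regions.

    With N slices the edges are floor(N/3) and floor(2N/3); each region's
    central slice is the floor of its mean index. Requires N >= 3 * window
    so the averaging window fits in every region.
    """
    n = len(slices)
    if n < 3 * window:
        raise ValueError(
            f"need at least {3 * window} coronal slices for three {window}-slice "
            f"regions, got {n}; resample finer or reduce the window"
        )
    b0, b1 = n // 3, (2 * n) // 3
    centers = ((0 + b0 - 1) // 2, (b0 + b1 - 1) // 2, (b1 + n - 1) // 2)
    return RegionScheme(n_slices=n, boundaries=(b0, b1), central_slices=centers,
                        window=window)


def region_rgf(slices, scheme: RegionScheme, region: str) -> RGFCurve:
    """Region curve: pointwise mean of the ``window`` slice curves centred on
    the region's central slice, skipping undefined values per radius."""
    if region not in REGION_IDS:
        raise ValueError(f"unknown region {region!r}")
    s = scheme.central_slices[REGION_IDS.index(region)]
    half = scheme.window // 2
    lo, hi = s - half, s + half
    if lo < 0 or hi >= scheme.n_slices:
        raise ValueError(f"averaging window [{lo}, {hi}] exceeds the slice range")

    curves = []
    for j in range(lo, hi + 1):
        breast, ft = slices[j]
        if not np.any(breast):
            warnings.warn(f"coronal slice {j} has an empty breast mask; excluded",
                          stacklevel=2)
            continue
        curves.append(slice_rgf(breast, ft, provenance=f"slice {j}").values)
    if not curves:
        raise ValueError(f"all slices in the window of region {region!r} are empty")
    stacked = np.vstack(curves)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stacked, axis=0)
    return RGFCurve(radii=RADII.copy(), values=mean, provenance=f"region {region}")


def subject_region_curves(ob: OrientedBreast, window: int = 5,
                          ) -> dict[str, RGFCurve]:
    """The three region RGF curves of one oriented breast."""
    slices = coronal_slices(ob)
    scheme = define_regions(slices, window=window)
    return {region: region_rgf(slices, scheme, region) for region in REGION_IDS}
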