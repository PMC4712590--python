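"""Volume, mask and table I/O plus the shared in-memory data model.

Canonical in-memory axis convention
-----------------------------------
All 3D grids in this package are stored with a fixed anatomical axis order:

* axis 0 — superior -> inferior (SI)
* axis 1 — anterior -> posterior (AP); the chest wall sits at *high* index,
  the nipple at *low* index
* axis 2 — left -> right (LR)

NIfTI files are reoriented to this convention on read (via the closest
canonical RAS+ orientation) and written back with an affine that encodes it,
so round trips are lossless on integer masks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "LabeledVolume",
    "FEATURE_COLUMNS",
    "COHORT_COLUMNS",
    "read_volume",
    "write_volume",
    "write_features",
    "read_features",
    "validate_cohort_table",
]

#: ordered feature column names of the 13-feature vector
FEATURE_COLUMNS = [f"f{i}" for i in range(1, 14)]

#: full cohort-table schema (one row per subject x region)
COHORT_COLUMNS = ["subject", "region", *FEATURE_COLUMNS, "FC", "label"]

REGIONS = ("posterior", "middle", "anterior")
LABELS = ("nonsparse", "sparse")


@dataclass
class LabeledVolume:
    """A breast CT (or label) volume with its masks and metadata.

    Grids follow the canonical axis order documented in the module docstring.
    ``intensities`` is optional (mask-only pipelines never need it) and
    ``ft_mask`` may be absent until segmentation has run.
    """

    breast_mask: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    ft_mask: np.ndarray | None = None
    intensities: np.ndarray | None = None
    nipple_voxel: tuple[int, int, int] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.breast_mask = np.asarray(self.breast_mask) > 0
        if self.breast_mask.ndim != 3:
            raise ValueError("breast_mask must be a 3D grid")
        sp = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"voxel spacing must be 3 positive reals, got {sp}")
        self.voxel_spacing_mm = sp
        if self.ft_mask is not None:
            self.ft_mask = np.asarray(self.ft_mask) > 0
            if self.ft_mask.shape != self.breast_mask.shape:
                raise ValueError(
                    "ft_mask shape "
                    f"{self.ft_mask.shape} != breast_mask shape {self.breast_mask.shape}"
                )
            if np.any(self.ft_mask & ~self.breast_mask):
                raise ValueError("ft_mask must be a subset of breast_mask")
        if self.intensities is not None:
            self.intensities = np.asarray(self.intensities, dtype=float)
            if self.intensities.shape != self.breast_mask.shape:
                raise ValueError("intensities shape does not match breast_mask")
        if self.nipple_voxel is not None:
            self.nipple_voxel = tuple(int(i) for i in self.nipple_voxel)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.breast_mask.shape

    def fibroglandular_composition(self) -> float:
        """FC = fraction of breast voxels marked fibroglandular."""
        if self.ft_mask is None:
            raise ValueError("no FT mask present")
        n_breast = int(self.breast_mask.sum())
        if n_breast == 0:
            raise ValueError("empty breast mask")
        return float(self.ft_mask.sum()) / n_breast

    def copy(self) -> "LabeledVolume":
        return replace(
            self,
            breast_mask=self.breast_mask.copy(),
            ft_mask=None if self.ft_mask is None else self.ft_mask.copy(),
            intensities=None if self.intensities is None else self.intensities.copy(),
            meta=dict(self.meta),
        )


# --------------------------------------------------------------------------
# NIfTI round trip
# --------------------------------------------------------------------------

def _ras_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    """Affine for the on-disk RAS-ordered array produced by
    :func:`_from_canonical` (axes L->R, P->A, I->S)."""
    s0, s1, s2 = spacing
    return np.diag([s2, s1, s0, 1.0])


def _to_canonical(img: nib.Nifti1Image, path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Return (array, spacing) in the package's canonical axis order."""
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {img.ndim}D")
    aff = img.affine
    if aff is None or not np.all(np.isfinite(aff)) or np.linalg.det(aff[:3, :3]) == 0:
        raise ValueError(
            f"{path}: missing or degenerate orientation metadata; "
            "re-export the file with a valid affine or pass explicit axis flags"
        )
    ras = nib.as_closest_canonical(img)
    arr = np.asanyarray(ras.dataobj)
    zooms = ras.header.get_zooms()[:3]
    # RAS array axes: 0 = L->R, 1 = P->A, 2 = I->S; ours: (S->I, A->P, L->R)
    arr_c = np.flip(arr.transpose(2, 1, 0), axis=(0, 1)).copy()
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return arr_c, spacing


def _from_canonical(arr: np.ndarray) -> np.ndarray:
    """Inverse of the array reordering in :func:`_to_canonical`."""
    return np.flip(arr, axis=(0, 1)).transpose(2, 1, 0)


def read_volume(
    path: str | Path | None,
    breast_mask_path: str | Path,
    ft_mask_path: str | Path | None = None,
    landmark_path: str | Path | None = None,
) -> LabeledVolume:
    """Read a volume, its masks and an optional nipple-landmark sidecar.

    ``path`` (intensities) is optional because the pipeline runs on masks
    alone. Masks are binarized at strictly-greater-than-zero so 0/1/255 label
    encodings all work. All files must agree on shape and voxel spacing.
    """
    breast_img = nib.load(str(breast_mask_path))
    breast, spacing = _to_canonical(breast_img, breast_mask_path)

    def _load_matching(p):
        arr, sp = _to_canonical(nib.load(str(p)), p)
        if arr.shape != breast.shape:
            raise ValueError(
                f"{p}: shape {arr.shape} does not match breast mask {breast.shape}"
            )
        if not np.allclose(sp, spacing, rtol=1e-3):
            raise ValueError(f"{p}: voxel spacing {sp} does not match breast mask {spacing}")
        return arr

    intensities = _load_matching(path) if path is not None else None
    ft = (_load_matching(ft_mask_path) > 0) if ft_mask_path is not None else None
    if ft is not None:
        stray = ft & ~(breast > 0)
        if stray.any():
            warnings.warn(
                f"{ft_mask_path}: {int(stray.sum())} FT voxels outside the breast mask "
                "were clipped",
                stacklevel=2,
            )
            ft = ft & (breast > 0)

    nipple = None
    if landmark_path is not None:
        with open(landmark_path) as fh:
            sidecar = json.load(fh)
        nipple = tuple(int(i) for i in sidecar["nipple_voxel"])

    return LabeledVolume(
        breast_mask=breast,
        ft_mask=ft,
        intensities=intensities,
        voxel_spacing_mm=spacing,
        nipple_voxel=nipple,
    )


def write_volume(vol: LabeledVolume, out_dir: str | Path, stem: str = "volume") -> dict:
    """Write masks (and intensities, if any) as .nii.gz plus a JSON sidecar.

    Returns a dict of the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _ras_affine(vol.voxel_spacing_mm)
    paths = {}

    def _save(arr, name, dtype):
        img = nib.Nifti1Image(_from_canonical(np.asarray(arr, dtype=dtype)), aff)
        p = out_dir / f"{stem}_{name}.nii.gz"
        nib.save(img, str(p))
        paths[name] = p

    _save(vol.breast_mask, "breast", np.uint8)
    if vol.ft_mask is not None:
        _save(vol.ft_mask, "ft", np.uint8)
    if vol.intensities is not None:
        _save(vol.intensities, "ct", np.float32)

    sidecar = dict(vol.meta)
    if vol.nipple_voxel is not None:
        sidecar["nipple_voxel"] = list(vol.nipple_voxel)
    p = out_dir / f"{stem}.json"
    with open(p, "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)
    paths["sidecar"] = p
    return paths


# --------------------------------------------------------------------------
# Cohort feature tables
# --------------------------------------------------------------------------

def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the (subject, region) feature table schema and invariants."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if table.empty:
        raise ValueError("cohort table is empty")
    dup = table.duplicated(subset=["subject", "region"])
    if dup.any():
        raise ValueError("cohort table has duplicate (subject, region) rows")
    bad_regions = set(table["region"]) - set(REGIONS)
    if bad_regions:
        raise ValueError(f"unknown region ids: {sorted(bad_regions)}")
    bad_labels = set(table["label"]) - set(LABELS)
    if bad_labels:
        raise ValueError(f"unknown group labels: {sorted(bad_labels)}")
    return table[COHORT_COLUMNS].reset_index(drop=True)


def write_features(table: pd.DataFrame, path: str | Path) -> None:
    """Write the cohort feature table as CSV with a stable column order.

    Floats are written with 17 significant digits so a re-read reproduces
    the values essentially bitwise.
    """
    table = validate_cohort_table(table)
    table.to_csv(path, index=False, float_format="%.17g")


def read_features(path: str | Path) -> pd.DataFrame:
    return validate_cohort_table(pd.read_csv(path))
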