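"""Pluggable fibroglandular-tissue segmentation adapter.

The pipeline's reference inputs carry precomputed FT masks (clinician or
upstream segmentation), so the default method is ``precomputed`` — a pass
through. Two simple intensity-based methods are provided to make the
end-to-end pipeline runnable on intensity volumes: a HU threshold and a
two-cluster k-means on the in-breast intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans

from .io import LabeledVolume

__all__ = ["SegmentationConfig", "segment_ft", "FTSegmenter"]

METHODS = ("precomputed", "threshold", "kmeans2")


@dataclass
class SegmentationConfig:
    method: str = "precomputed"
    hu_threshold: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.method == "threshold" and self.hu_threshold is None:
            raise ValueError("threshold method requires hu_threshold")


def segment_ft(vol: LabeledVolume, cfg: SegmentationConfig | None = None) -> LabeledVolume:
    """Populate the FT mask of a volume according to the configuration.

    ``threshold``: FT = breast voxels with intensity >= hu_threshold.
    ``kmeans2``: 2-cluster k-means on in-breast intensities; FT is the
    higher-mean cluster. If the clustering degenerates (indistinguishable
    cluster means) the FT mask is left empty with a warning.
    """
    cfg = cfg or SegmentationConfig()
    if cfg.method == "precomputed":
        if vol.ft_mask is None:
            raise ValueError("method 'precomputed' but the volume has no FT mask")
        return vol

    if vol.intensities is None:
        raise ValueError(f"method {cfg.method!r} requires an intensity volume")
    breast = vol.breast_mask
    vals = vol.intensities[breast]

    if cfg.method == "threshold":
        ft_flags = vals >= cfg.hu_threshold
    else:  # kmeans2
        km = KMeans(n_clusters=2, n_init=5, random_state=cfg.seed)
        labels = km.fit_predict(vals.reshape(-1, 1))
        means = km.cluster_centers_.ravel()
        if abs(means[0] - means[1]) < 1e-6 * max(1.0, abs(means).max()):
            warnings.warn("degenerate two-cluster segmentation (uniform intensities); "
                          "FT mask left empty", stacklevel=2)
            ft_flags = np.zeros(vals.shape, dtype=bool)
        else:
            ft_flags = labels == int(np.argmax(means))

    ft = np.zeros(vol.shape, dtype=bool)
    ft[breast] = ft_flags
    out = vol.copy()
    out.ft_mask = ft
    return out


class FTSegmenter(BaseEstimator, TransformerMixin):
    """Transformer applying :func:`segment_ft` to a sequence of volumes."""

    def __init__(self, method: str = "precomputed", hu_threshold: float | None = None,
                 seed: int = 0):
        self.method = method
        self.hu_threshold = hu_threshold
        self.seed = seed

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> list[LabeledVolume]:
        cfg = SegmentationConfig(method=self.method, hu_threshold=self.hu_threshold,
                                 seed=self.seed)
        return [segment_ft(vol, cfg) for vol in X]
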