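"""The 13 texture features summarising a region RGF curve.

Feature numbering (fixed, used as CSV column order):

1.  mean RGF
2.  standard deviation of RGF
3.  slope of the ordinary least-squares fit of RGF against relative radius r
4.  radial position r of the maximum RGF (smallest r on ties)
5.  minimum RGF
6.  maximum RGF
7.  maximum - minimum
8.  mean of the radially inner 50 % (r <= 0.5)
9.  mean of the radially outer 50 % (r > 0.5)
10. inner mean - outer mean
11. mean of the highest 10 % of RGF values
12. mean of the lowest 10 % of RGF values
13. highest-10 % mean - lowest-10 % mean

All statistics run over the *defined* curve points only; a curve with more
than 10 undefined points is rejected as too truncated. The "10 %" features
use order statistics: the 10 largest / smallest of the 100 values
(proportionally fewer when some are undefined, never fewer than one). The
standard deviation uses the n-1 (sample) normalisation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import OrientedBreast
from .io import FEATURE_COLUMNS
from .rgf import N_RADII, REGION_IDS, RGFCurve, subject_region_curves

__all__ = ["compute_features", "features_for_subject", "cohort_feature_table",
           "RGFFeatureExtractor"]

#: maximum tolerated number of undefined curve points
MAX_UNDEFINED = 10


def compute_features(curve: RGFCurve) -> dict[str, float]:
    """Map one RGF curve to the 13-feature vector (keys ``f1`` .. ``f13``)."""
    defined = ~np.isnan(curve.values)
    n_undef = N_RADII - int(defined.sum())
    if n_undef > MAX_UNDEFINED:
        raise ValueError(
            f"curve has {n_undef} undefined values (> {MAX_UNDEFINED}); too truncated"
        )
    r = curve.radii[defined]
    v = curve.values[defined]
    n = len(v)

    f1 = v.mean()
    f2 = v.std(ddof=1)
    # OLS slope of v on r
    r_c = r - r.mean()
    f3 = float(np.dot(r_c, v - v.mean()) / np.dot(r_c, r_c))
    f6 = v.max()
    f5 = v.min()
    f4 = float(r[np.argmax(v)])          # argmax returns the first (smallest r) tie
    f7 = f6 - f5

    inner = v[r <= 0.5]
    outer = v[r > 0.5]
    f8 = inner.mean() if inner.size else np.nan
    f9 = outer.mean() if outer.size else np.nan
    f10 = f8 - f9

    m = max(1, int(round(0.1 * n)))
    v_sorted = np.sort(v)
    f11 = v_sorted[-m:].mean()
    f12 = v_sorted[:m].mean()
    f13 = f11 - f12

    return {
        "f1": float(f1), "f2": float(f2), "f3": float(f3), "f4": float(f4),
        "f5": float(f5), "f6": float(f6), "f7": float(f7), "f8": float(f8),
        "f9": float(f9), "f10": float(f10), "f11": float(f11), "f12": float(f12),
        "f13": float(f13),
    }


def features_for_subject(ob: OrientedBreast, window: int = 5) -> dict[str, dict[str, float]]:
    """Feature vectors for the three regions of one oriented breast,
    ordered posterior, middle, anterior."""
    curves = subject_region_curves(ob, window=window)
    return {region: compute_features(curves[region]) for region in REGION_IDS}


def cohort_feature_table(oriented, labels, window: int = 5) -> pd.DataFrame:
    """Full cohort table (subject, region, f1..f13, FC, label) from oriented
    breasts and their positionally aligned group labels."""
    if len(oriented) != len(labels):
        raise ValueError("labels must align with the oriented volumes")
    rows = []
    for i, (ob, label) in enumerate(zip(oriented, labels)):
        subject = ob.meta.get("subject", f"S{i:03d}")
        table = RGFFeatureExtractor(window=window).fit_transform([ob])
        table["subject"] = subject
        table["label"] = label
        rows.append(table)
    return pd.concat(rows, ignore_index=True)


class RGFFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer from OrientedBreast sequences to a tidy feature table.

    ``transform`` returns a DataFrame with one row per (subject, region) and
    columns subject, region, f1..f13, FC — the cohort-table schema minus the
    group label, which the caller attaches.

    Parameters
    ----------
    window : int
        Number of coronal slices averaged per region (odd).
    """

    def __init__(self, window: int = 5):
        self.window = window

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        rows = []
        for i, ob in enumerate(X):
            subject = ob.meta.get("subject", f"S{i:03d}")
            per_region = features_for_subject(ob, window=self.window)
            fc = ob.fibroglandular_composition()
            for region in REGION_IDS:
                row = {"subject": subject, "region": region}
                row.update(per_region[region])
                row["FC"] = fc
                rows.append(row)
        return pd.DataFrame(rows, columns=["subject", "region", *FEATURE_COLUMNS, "FC"])
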