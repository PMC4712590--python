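"""Group-difference testing between sparse and non-sparse cohorts.

Each of the 13 RGF features, per breast region, and the fibroglandular
composition (FC) are compared between the two groups with the two-sided
Wilcoxon rank-sum (Mann-Whitney U) test. The exact null distribution is
used whenever the combined sample is small (<= 25) and tie-free; otherwise
the normal approximation with tie correction applies. Significance is
declared at alpha = 0.05 per test; no multiple-testing correction is
applied (the per-feature reporting convention), so note the 13-test family
when interpreting the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import FEATURE_COLUMNS, validate_cohort_table

__all__ = ["GroupTestResult", "wilcoxon_rank_sum", "compare_groups", "results_table"]

ALPHA = 0.05
#: largest combined sample for which the exact null distribution is used
EXACT_MAX_N = 25


@dataclass
class GroupTestResult:
    feature: str            # "f1".."f13" or "FC"
    region: str             # region id, or "all" for the FC test
    mean_nonsparse: float
    mean_sparse: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided") -> float:
    """Two-sided Wilcoxon rank-sum p-value for two independent samples.

    Exact when len(a) + len(b) <= 25 with no ties across the pooled sample,
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MAX_N and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.pvalue)


def compare_groups(table: pd.DataFrame, alternative: str = "two-sided",
                   ) -> list[GroupTestResult]:
    """Per-(region, feature) Wilcoxon tests plus the FC comparison.

    FC is a per-subject quantity (identical across a subject's region rows),
    so its test runs once on the subject-level values, reported with region
    id "all".
    """
    table = validate_cohort_table(table)
    labels = sorted(table["label"].unique())
    if len(labels) < 2:
        raise ValueError(f"need both group labels, found only {labels}")

    def _split(df, col):
        return (df.loc[df["label"] == "nonsparse", col].to_numpy(),
                df.loc[df["label"] == "sparse", col].to_numpy())

    results = []
    for region, sub in table.groupby("region", sort=False):
        for feat in FEATURE_COLUMNS:
            g1, g2 = _split(sub, feat)
            results.append(GroupTestResult(
                feature=feat, region=str(region),
                mean_nonsparse=float(g1.mean()), mean_sparse=float(g2.mean()),
                p_value=wilcoxon_rank_sum(g1, g2, alternative=alternative),
            ))
    per_subject = table.drop_duplicates("subject")
    g1, g2 = _split(per_subject, "FC")
    results.append(GroupTestResult(
        feature="FC", region="all",
        mean_nonsparse=float(g1.mean()), mean_sparse=float(g2.mean()),
        p_value=wilcoxon_rank_sum(g1, g2, alternative=alternative),
    ))
    return results


def results_table(results: list[GroupTestResult]) -> pd.DataFrame:
    """Flatten test results to a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        [{
            "region": r.region, "feature": r.feature,
            "mean_nonsparse": r.mean_nonsparse, "mean_sparse": r.mean_sparse,
            "p": r.p_value, "significant": r.significant,
        } for r in results]
    )
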