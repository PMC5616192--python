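"""Per-ROI statistics: region means, pooled-variance two-sample t tests,
and Holm-Šidák step-down multiple-comparison adjustment.

The adjustment treats the tests of one metric (or histology marker)
across all regions as a family: with m ordered p-values p(1) <= ... <=
p(m), the adjusted value of the i-th is

    p_adj(i) = max_{j <= i}  1 - (1 - p(j))^(m - j + 1)

clipped to 1 and mapped back to the input order.  Adjusted significance
is marked "*" at alpha, raw significance "#".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import feature_columns, split_feature_name

__all__ = ["TTestResult", "roi_means", "student_t_two_sample",
           "holm_sidak_adjust", "table_analysis", "results_frame",
           "t_to_p", "adjusted_p_from_t"]


@dataclass
class TTestResult:
    """One ROI's test within a metric family."""

    roi: str
    metric: str
    t: float
    df: int
    p: float
    p_adj: float
    family_size: int

    def significant(self, alpha: float = 0.05, adjusted: bool = True) -> bool:
        return (self.p_adj if adjusted else self.p) < alpha

    @property
    def flags(self) -> str:
        """Significance marks: '#' raw p < 0.05, '*' adjusted p < 0.05."""
        return ("#" if self.p < 0.05 else "") + ("*" if self.p_adj < 0.05 else "")


def roi_means(metric_map: np.ndarray, labels: np.ndarray,
              roi_labels: dict[str, int]) -> dict[str, float]:
    """Arithmetic mean of a scalar map over each labeled region; empty
    regions yield NaN."""
    metric_map = np.asarray(metric_map, float)
    labels = np.asarray(labels)
    if metric_map.shape != labels.shape:
        raise ValueError("metric map and label volume grids differ")
    out: dict[str, float] = {}
    for roi, lab in roi_labels.items():
        mask = labels == lab
        out[roi] = float(metric_map[mask].mean()) if mask.any() else float("nan")
    return out


def student_t_two_sample(a, b) -> tuple[float, int, float]:
    """Pooled-variance Student's t with df = n1 + n2 - 2 and two-sided p.

    Degenerate case (zero pooled variance): t = 0, p = 1 when the means
    agree; otherwise t is signed infinity with p = 0.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), df, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), df, float(p)


def holm_sidak_adjust(p_values) -> np.ndarray:
    """Holm-Šidák step-down adjusted p-values, in the input order."""
    p = np.asarray(p_values, float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty 1-D array of p-values")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm-sidak")[1]


def t_to_p(t, df: int) -> np.ndarray:
    """Two-sided p from |t| under Student's t with ``df`` degrees of freedom."""
    return 2.0 * stats.t.sf(np.abs(np.asarray(t, float)), df)


def adjusted_p_from_t(t, df: int) -> np.ndarray:
    """Convenience: |t| -> two-sided p -> Holm-Šidák adjustment, the
    family being all entries of ``t``."""
    return holm_sidak_adjust(t_to_p(t, df))


def table_analysis(
    features: pd.DataFrame,
    family: str,
    alpha: float = 0.05,
    group_column: str = "group",
) -> list[TTestResult]:
    """Per-ROI two-sample t tests for one metric family with Holm-Šidák
    adjustment across the family's ROIs.

    ``features`` is a cohort table (see ``tbikit.cohort``); ``family`` is
    a metric or marker name selecting the "<roi>_<family>" columns.
    ROIs whose feature column contains missing values are excluded from
    the family (reducing m) with a warning.
    """
    groups = features[group_column].unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {list(groups)}")
    g1 = features[features[group_column] == groups[0]]
    g2 = features[features[group_column] == groups[1]]
    cols = [c for c in feature_columns(features)
            if split_feature_name(c)[1] == family]
    if not cols:
        raise ValueError(f"no feature columns for family {family!r}")
    kept, skipped = [], []
    for c in cols:
        if features[c].isna().any():
            skipped.append(c)
        else:
            kept.append(c)
    if skipped:
        import warnings
        warnings.warn(f"excluding features with missing values: {skipped}",
                      stacklevel=2)
    stats_rows = [student_t_two_sample(g2[c].to_numpy(), g1[c].to_numpy())
                  for c in kept]
    p_adj = holm_sidak_adjust([p for _, _, p in stats_rows])
    results = []
    for c, (t, df, p), pa in zip(kept, stats_rows, p_adj):
        roi, metric = split_feature_name(c)
        results.append(TTestResult(roi=roi, metric=metric, t=t, df=df,
                                   p=p, p_adj=float(pa), family_size=len(kept)))
    return results


def results_frame(results: list[TTestResult]) -> pd.DataFrame:
    """Long-format results table with significance flags."""
    return pd.DataFrame(
        {
            "roi": [r.roi for r in results],
            "metric": [r.metric for r in results],
            "t": [r.t for r in results],
            "df": [r.df for r in results],
            "p": [r.p for r in results],
            "p_adj": [r.p_adj for r in results],
            "family_size": [r.family_size for r in results],
            "flags": [r.flags for r in results],
        }
    )
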