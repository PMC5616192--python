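"""Synthetic two-group feature cohorts.

A cohort is a samples x (ROI x metric) table with a group label per
sample — the common currency of the ROI statistics and the classifier.
Features are Gaussian within group, matching the assumptions of the
pooled-variance t tests applied downstream: for a feature with Cohen's d,

    value_sham    ~ N(mu, sigma^2)
    value_injured ~ N(mu + d * sigma, sigma^2).

Effect sizes are typically calibrated from published two-sample t
statistics via d = t * sqrt(1/n1 + 1/n2) (see ``tbikit.datasets``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import DTI_METRICS, ROI_NAMES

__all__ = ["CohortSpec", "make_feature_cohort", "feature_name",
           "split_feature_name", "feature_columns"]

#: Feature columns are named "<roi>_<metric>"; ROI names may themselves
#: contain underscores, so parsing splits on the LAST underscore.
_SEP = "_"


def feature_name(roi: str, metric: str) -> str:
    return f"{roi}{_SEP}{metric}"


def split_feature_name(col: str) -> tuple[str, str]:
    roi, _, metric = col.rpartition(_SEP)
    if not roi:
        raise ValueError(f"not a '<roi>_<metric>' feature column: {col!r}")
    return roi, metric


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The feature columns of a cohort table (everything but the
    bookkeeping columns)."""
    return [c for c in table.columns if c not in ("sample_id", "group")]


@dataclass
class CohortSpec:
    """Study-condition description of a synthetic cohort.

    ``effect_map`` holds Cohen's d per (roi, metric); omitted pairs get
    d = 0.  ``baseline`` and ``sigma`` give the sham mean and the common
    within-group standard deviation per (roi, metric) pair (scalars are
    broadcast).
    """

    n_sham: int = 5
    n_injured: int = 5
    rois: tuple[str, ...] = ROI_NAMES
    metrics: tuple[str, ...] = DTI_METRICS
    effect_map: dict[tuple[str, str], float] = field(default_factory=dict)
    baseline: float | dict[tuple[str, str], float] = 0.5
    sigma: float | dict[tuple[str, str], float] = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sham < 2 or self.n_injured < 2:
            raise ValueError("need at least two samples per group")
        for (roi, metric) in self.effect_map:
            if roi not in self.rois:
                raise ValueError(f"effect on unknown ROI: {roi!r}")
            if metric not in self.metrics:
                raise ValueError(f"effect on unknown metric: {metric!r}")
        sigmas = (self.sigma.values() if isinstance(self.sigma, dict)
                  else [self.sigma])
        if any(s <= 0 for s in sigmas):
            raise ValueError("within-group standard deviations must be positive")

    def _lookup(self, table, roi: str, metric: str, default: float) -> float:
        if isinstance(table, dict):
            return table.get((roi, metric), default)
        return float(table)

    @classmethod
    def from_effect_frame(cls, effects: pd.DataFrame, **kwargs) -> "CohortSpec":
        """Build a spec from a ROI x metric frame of Cohen's d values."""
        emap = {(roi, metric): float(effects.loc[roi, metric])
                for roi in effects.index for metric in effects.columns}
        return cls(rois=tuple(effects.index), metrics=tuple(effects.columns),
                   effect_map=emap, **kwargs)


def make_feature_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort: rows = samples, columns = sample_id, group, then
    one feature column per (roi, metric), reproducible under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sham + spec.n_injured
    groups = ["sham"] * spec.n_sham + ["injured"] * spec.n_injured
    data: dict[str, np.ndarray] = {
        "sample_id": np.array([f"{g}_{i:02d}" for i, g in enumerate(groups)]),
        "group": np.array(groups),
    }
    injured = np.array([g == "injured" for g in groups])
    for roi in spec.rois:
        for metric in spec.metrics:
            mu = spec._lookup(spec.baseline, roi, metric, 0.5)
            sd = spec._lookup(spec.sigma, roi, metric, 0.05)
            d = spec.effect_map.get((roi, metric), 0.0)
            vals = rng.normal(mu, sd, size=n)
            vals[injured] += d * sd
            data[feature_name(roi, metric)] = vals
    return pd.DataFrame(data)
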