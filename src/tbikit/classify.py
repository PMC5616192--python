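"""Random-forest injury classification with out-of-bag evaluation.

A Breiman-style forest: each tree is grown on a bootstrap sample of n
rows drawn with replacement, splits choose among m_try = floor(sqrt(F))
randomly selected features by Gini impurity, and trees are unpruned
(individual trees come from scikit-learn).  Out-of-bag (OOB) votes give
per-sample predictions without a held-out set; classification error is
incorrect / total, reported per class and overall.

Feature importance is the mean decrease in accuracy (MDA): for each
tree, the OOB accuracy drop when one feature's values are permuted among
that tree's OOB rows, averaged over trees.  Both the raw average and the
sd-normalised score (mean divided by its standard error across trees)
are reported; independent forest repeats give a spread for error bars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn
from sklearn.tree import DecisionTreeClassifier

from .cohort import feature_columns, split_feature_name

__all__ = ["RFConfig", "RFReport", "rf_classify", "metric_subset_trials",
           "rank_rois", "threshold_classify"]


@dataclass
class RFConfig:
    """Forest parameters; defaults mirror the common R-package defaults
    for classification, except the tree count raised to 2000 so every
    feature of a wide table is considered many times."""

    n_trees: int = 2000
    m_try: int | None = None  # None -> floor(sqrt(n_features))
    seed: int = 0
    n_repeats: int = 10       # independent forests for importance spread

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    def resolved_m_try(self, n_features: int) -> int:
        m = self.m_try if self.m_try is not None else int(np.sqrt(n_features))
        return int(np.clip(m, 1, n_features))


@dataclass
class RFReport:
    """Forest evaluation: OOB confusion, errors, and MDA importances."""

    classes: tuple[str, str]
    confusion: dict[str, dict[str, int]]   # class -> {correct, incorrect}
    class_error: dict[str, float]
    overall_error: float
    oob_predictions: pd.Series
    mda: pd.DataFrame                      # per feature: raw, scaled, spread
    config: RFConfig

    @property
    def overall_accuracy(self) -> float:
        return 1.0 - self.overall_error

    def summary(self) -> str:
        lines = ["Random-forest OOB report", "========================"]
        for c in self.classes:
            cc = self.confusion[c]
            lines.append(f"{c:<10} correct {cc['correct']:>3}  incorrect "
                         f"{cc['incorrect']:>3}  error {self.class_error[c]:.2f}")
        lines.append(f"overall error {self.overall_error:.2f} "
                     f"(accuracy {self.overall_accuracy:.2f})")
        top = self.mda.sort_values("scaled", ascending=False).head(5)
        lines.append("top features by scaled MDA:")
        for name, row in top.iterrows():
            lines.append(f"  {name:<40} {row['scaled']:8.3f}")
        return "\n".join(lines)


def _grow_forest(X: np.ndarray, y: np.ndarray, n_trees: int, m_try: int,
                 rng: np.random.Generator, compute_mda: bool):
    """One forest pass.  Returns (oob_vote_counts, per-tree MDA sums)."""
    n, F = X.shape
    classes, y_enc = np.unique(y, return_inverse=True)
    # float32 C-contiguous features allow the trees' fast no-validation path
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    votes = np.zeros((n, classes.size), dtype=np.int64)
    mda_sum = np.zeros(F)
    mda_sqsum = np.zeros(F)
    mda_trees = 0
    max_int = np.iinfo(np.int32).max
    with sklearn.config_context(skip_parameter_validation=True):
        for _ in range(n_trees):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
            tree = DecisionTreeClassifier(
                criterion="gini", max_features=m_try,
                random_state=int(rng.integers(max_int)),
            )
            tree.fit(X32[boot], y_enc[boot], check_input=False)
            if oob.size == 0:
                continue
            # predict returns values of y_enc, i.e. global class indices
            pred = tree.predict(X32[oob], check_input=False).astype(int)
            np.add.at(votes, (oob, pred), 1)
            if compute_mda:
                base_correct = np.count_nonzero(pred == y_enc[oob])
                # batch: one stacked prediction for all F permuted copies
                Xoob = X32[oob]
                m = oob.size
                stacked = np.repeat(Xoob[None, :, :], F, axis=0)
                perm = np.argsort(rng.random((F, m)), axis=1)
                f_idx = np.arange(F)[:, None]
                stacked[f_idx, np.arange(m)[None, :], f_idx] = Xoob[perm, f_idx]
                perm_pred = tree.predict(
                    np.ascontiguousarray(stacked.reshape(F * oob.size, F)),
                    check_input=False)
                perm_correct = (
                    perm_pred.reshape(F, oob.size) == y_enc[oob][None, :]
                ).sum(axis=1)
                delta = (base_correct - perm_correct) / oob.size
                mda_sum += delta
                mda_sqsum += delta**2
                mda_trees += 1
    return votes, classes, mda_sum, mda_sqsum, mda_trees


def rf_classify(
    features: pd.DataFrame,
    labels=None,
    config: RFConfig | None = None,
    compute_importance: bool = True,
    group_column: str = "group",
) -> RFReport:
    """Fit repeated OOB-evaluated forests on a cohort table.

    ``features`` may be a cohort table carrying a ``group`` column (then
    ``labels`` is ignored) or a pure feature frame with ``labels`` given
    separately.  The first forest provides the OOB confusion and error;
    ``config.n_repeats`` independent forests provide the MDA mean and its
    spread (sd across repeats).
    """
    config = config or RFConfig()
    if labels is None:
        if group_column not in features.columns:
            raise ValueError("no labels given and no group column present")
        labels = features[group_column]
    cols = feature_columns(features)
    X = features[cols].to_numpy(dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, found {list(classes)}")
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("each class needs at least two samples")

    m_try = config.resolved_m_try(X.shape[1])
    rng = np.random.default_rng(config.seed)
    n_rep = config.n_repeats if compute_importance else 1
    raw_reps = []
    scaled_reps = []
    first_votes = first_classes = None
    for rep in range(n_rep):
        votes, cls, s, sq, ntree = _grow_forest(
            X, y, config.n_trees, m_try, rng, compute_mda=compute_importance)
        if rep == 0:
            first_votes, first_classes = votes, cls
        if compute_importance and ntree > 0:
            mean = s / ntree
            var = np.maximum(sq / ntree - mean**2, 0.0)
            se = np.sqrt(var / ntree)
            raw_reps.append(mean)
            scaled_reps.append(np.where(se > 0, mean / np.where(se > 0, se, 1.0), 0.0))

    # OOB majority vote; ties broken toward the first class name
    no_vote = first_votes.sum(axis=1) == 0
    pred = first_classes[np.argmax(first_votes, axis=1)]
    oob_pred = pd.Series(pred, index=features.index, name="oob_prediction")
    confusion = {}
    class_error = {}
    correct_mask = (pred == y) & ~no_vote
    for c in classes:
        in_c = y == c
        ncorr = int(np.count_nonzero(correct_mask & in_c))
        confusion[str(c)] = {"correct": ncorr,
                             "incorrect": int(in_c.sum()) - ncorr}
        class_error[str(c)] = 1.0 - ncorr / in_c.sum()
    overall_error = 1.0 - correct_mask.sum() / y.size

    if compute_importance:
        raw = np.mean(raw_reps, axis=0)
        scaled = np.mean(scaled_reps, axis=0)
        spread = (np.std(raw_reps, axis=0, ddof=1) if n_rep > 1
                  else np.zeros_like(raw))
        mda = pd.DataFrame({"raw": raw, "scaled": scaled, "spread": spread},
                           index=pd.Index(cols, name="feature"))
    else:
        mda = pd.DataFrame(columns=["raw", "scaled", "spread"],
                           index=pd.Index(cols, name="feature"), dtype=float)
    return RFReport(
        classes=tuple(str(c) for c in classes),
        confusion=confusion,
        class_error=class_error,
        overall_error=float(overall_error),
        oob_predictions=oob_pred,
        mda=mda,
        config=config,
    )


def metric_subset_trials(
    features: pd.DataFrame,
    subsets: dict[str, tuple[str, ...]],
    labels=None,
    config: RFConfig | None = None,
    compute_importance: bool = False,
) -> dict[str, RFReport]:
    """Re-run the forest on column subsets restricted by metric name.

    ``subsets`` maps a trial name (e.g. "FA-T") to the metric names kept;
    all ROIs are retained.  Bookkeeping columns pass through.
    """
    out = {}
    keep_meta = [c for c in features.columns if c not in feature_columns(features)]
    for name, metrics in subsets.items():
        if not metrics:
            raise ValueError(f"subset {name!r} is empty")
        cols = [c for c in feature_columns(features)
                if split_feature_name(c)[1] in metrics]
        if not cols:
            raise ValueError(f"subset {name!r} matches no feature columns")
        out[name] = rf_classify(features[keep_meta + cols], labels=labels,
                                config=config,
                                compute_importance=compute_importance)
    return out


def rank_rois(report: RFReport, top_k: int = 3,
              assoc_fraction: float = 0.5) -> pd.DataFrame:
    """Rank ROIs by their best feature importance.

    An ROI's score is the maximum sd-normalised MDA among its features;
    the "associated metrics" are the ROI's features scoring at least
    ``assoc_fraction`` of that maximum, listed best first.  All-equal
    scores tie-break by ROI name order.
    """
    if report.mda.empty or report.mda["scaled"].isna().all():
        raise ValueError("report carries no importance values")
    rows = []
    for feat, row in report.mda.iterrows():
        roi, metric = split_feature_name(feat)
        rows.append((roi, metric, row["scaled"]))
    df = pd.DataFrame(rows, columns=["roi", "metric", "scaled"])
    grouped = df.groupby("roi", sort=True)
    scores = grouped["scaled"].max().sort_values(ascending=False, kind="stable")
    if top_k > scores.size:
        import warnings
        warnings.warn(f"top_k={top_k} exceeds {scores.size} ROIs; truncating",
                      stacklevel=2)
        top_k = scores.size
    out_rows = []
    for roi in scores.index[:top_k]:
        sub = df[df["roi"] == roi].sort_values("scaled", ascending=False,
                                               kind="stable")
        best = sub["scaled"].iloc[0]
        assoc = sub[sub["scaled"] >= assoc_fraction * best]["metric"].tolist()
        out_rows.append({"roi": roi, "score": best,
                         "associated_metrics": assoc})
    return pd.DataFrame(out_rows)


def threshold_classify(values, labels) -> tuple[float, int]:
    """Best single-threshold classification of one feature.

    Evaluates the midpoints between adjacent sorted values (and the two
    outer extremes) with both label orientations; returns the threshold
    minimising the misclassification count (ties -> smallest threshold)
    and that count.
    """
    v = np.asarray(values, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    order = np.argsort(v, kind="stable")
    vs = v[order]
    cands = [vs[0] - 1.0]
    cands += [0.5 * (vs[i] + vs[i + 1]) for i in range(vs.size - 1)]
    cands.append(vs[-1] + 1.0)
    best_thr, best_err = cands[0], v.size + 1
    for thr in cands:
        below = v <= thr
        for lo in classes:
            err = int(np.count_nonzero(below & (y != lo))
                      + np.count_nonzero(~below & (y == lo)))
            if err < best_err or (err == best_err and thr < best_thr):
                best_err, best_thr = err, thr
    return float(best_thr), int(best_err)
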