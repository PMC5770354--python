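"""Stepwise wrapper feature selection over a ranked feature list.

The training partition is split once (75/25 by default) into a sub-train
and an internal test set, held fixed across steps.  Ranked features are
then introduced cumulatively — prefixes of size step_size, 2*step_size,
... up to all features (the final partial prefix is always evaluated) —
and for each prefix a fresh learner is fitted on the sub-train rows and
scored on the internal test rows (RMSE and PVE).  The selected feature
set (SF) is the prefix minimizing internal-test RMSE; ties go to the
smaller prefix, and an optional parsimony tolerance accepts the smallest
prefix within tau of the minimum.  The Independent Validation Set never
enters this procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR

from .errors import ConfigurationError, TooSmallError
from .featurize import FeatureMatrix
from .transform import DataSplit, partition_data
from .validation import compute_pve, compute_rmse

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LearnerConfig:
    """Learner used for the stepwise models and the final fits.

    SVM regression with an RBF kernel is the default: cost C=1,
    epsilon=0.1 and kernel width gamma = 1 / (number of features
    currently in the model) — library-conventional settings, all
    overridable.  ``rf`` swaps in a random forest.
    """

    learner: str = "svm"
    C: float = 1.0
    epsilon: float = 0.1
    gamma: str | float = "auto"  # "auto" = 1 / n_features
    ntree: int = 500

    def __post_init__(self) -> None:
        if self.learner not in ("svm", "rf"):
            raise ConfigurationError("learner must be 'svm' or 'rf'")

    def make(self, seed: int = 0):
        if self.learner == "svm":
            return SVR(kernel="rbf", C=self.C, epsilon=self.epsilon, gamma=self.gamma)
        return RandomForestRegressor(
            n_estimators=self.ntree, max_features=1 / 3, random_state=seed % (2**32), n_jobs=1
        )


@dataclass
class StepwiseTrace:
    """RMSE/PVE at each feature count, plus the internal split used."""

    steps: pd.DataFrame  # columns feature_count, rmse, pve
    learner: LearnerConfig
    split: DataSplit
    ranking_method: str = ""

    def to_csv(self, path) -> None:
        self.steps.to_csv(path, index=False)


@dataclass
class SelectedFeatureSet:
    features: list[str] = field(default_factory=list)
    rmse: float = float("nan")
    pve: float = float("nan")

    @property
    def size(self) -> int:
        return len(self.features)


def _prefix_counts(total: int, step_size: int) -> list[int]:
    counts = list(range(step_size, total + 1, step_size))
    if not counts or counts[-1] != total:
        counts.append(total)
    return counts


def stepwise_trace(
    X_train: FeatureMatrix,
    y_train,
    ranked: list[str],
    learner: LearnerConfig | None = None,
    step_size: int = 1,
    seed: int = 0,
    internal_fraction: float = 0.75,
    ranking_method: str = "",
) -> StepwiseTrace:
    """Fit and score one learner per cumulative ranked-feature prefix."""
    if not ranked:
        raise ConfigurationError("ranked feature list is empty")
    if step_size < 1:
        raise ConfigurationError("step_size must be >= 1")
    learner = learner or LearnerConfig()

    ids = X_train.row_ids
    split = partition_data(ids, train_fraction=internal_fraction, seed=seed)
    if len(split.train_ids) < 4 or len(split.ivs_ids) < 4:
        raise TooSmallError(
            f"internal split too small: {len(split.train_ids)}/{len(split.ivs_ids)} rows"
        )
    y = pd.Series(np.asarray(y_train, dtype=float), index=ids)
    X_sub = X_train.subset_rows(split.train_ids)
    X_int = X_train.subset_rows(split.ivs_ids)
    y_sub = y.loc[split.train_ids].to_numpy()
    y_int = y.loc[split.ivs_ids].to_numpy()

    rows = []
    for count in _prefix_counts(len(ranked), step_size):
        cols = ranked[:count]
        est = learner.make(seed=seed)
        est.fit(X_sub.subset_columns(cols).to_numpy(), y_sub)
        pred = est.predict(X_int.subset_columns(cols).to_numpy())
        rows.append(
            {
                "feature_count": count,
                "rmse": compute_rmse(y_int, pred),
                "pve": compute_pve(y_int, pred),
            }
        )
    trace = pd.DataFrame(rows)
    logger.info(
        "stepwise trace over %d steps: min RMSE %.4f at %d features",
        len(trace), trace["rmse"].min(), int(trace.loc[trace["rmse"].idxmin(), "feature_count"]),
    )
    return StepwiseTrace(steps=trace, learner=learner, split=split, ranking_method=ranking_method)


def select_features(
    trace: StepwiseTrace, ranked: list[str], tolerance: float = 0.0
) -> SelectedFeatureSet:
    """Pick the minimal-RMSE prefix (or the smallest within ``tolerance``)."""
    if trace.steps.empty:
        raise ConfigurationError("stepwise trace is empty")
    if tolerance < 0:
        raise ConfigurationError("tolerance must be >= 0")
    rmses = trace.steps["rmse"].to_numpy()
    counts = trace.steps["feature_count"].to_numpy()
    best = float(rmses.min())
    # counts increase along the trace, so the first qualifying step is the
    # smallest prefix; tolerance 0 reduces to argmin with fewer-features ties
    idx = int(np.flatnonzero(rmses <= best + tolerance)[0])
    return SelectedFeatureSet(
        features=list(ranked[: counts[idx]]),
        rmse=float(rmses[idx]),
        pve=float(trace.steps["pve"].iloc[idx]),
    )


def plot_trace(trace: StepwiseTrace, path) -> None:
    """Render the RMSE-vs-feature-count curve to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(trace.steps["feature_count"], trace.steps["rmse"], marker="o", ms=3)
    ax.set_xlabel("features in model")
    ax.set_ylabel("internal-test RMSE")
    ax.set_title(f"stepwise {trace.learner.learner} models ({trace.ranking_method or 'ranked'})")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
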