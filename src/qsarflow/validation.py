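"""Final model fitting, external validation and applicability domain.

Two figures of merit drive every evaluation:

    PVE  = 1 - sum_i (y_i - yhat_i)^2 / sum_i (y_i - ybar)^2
    RMSE = sqrt( (1/N) sum_i (y_i - yhat_i)^2 )

The full-model (all features) and the SF-model (selected features) are
each fitted on the whole training partition and validated on the
Independent Validation Set; the internal test split from the stepwise
stage is replayed so internal and external scores are comparable.

The applicability domain (AD) is distance-based: the threshold is the
mean plus Z standard deviations of each training compound's Euclidean
distance to its nearest training neighbour (self excluded), computed in
the scaled feature space of the model's own input columns.  An IVS
compound whose nearest-training distance strictly exceeds the threshold
is flagged as outside the domain — flagged, never removed; the decision
is left to the user.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import AlignmentError, ConfigurationError, DomainError, TooSmallError
from .featurize import FeatureMatrix
from .transform import ScalerParams, apply_minmax

logger = logging.getLogger(__name__)

DEFAULT_AD_Z = 0.5


def compute_pve(y, y_hat) -> float:
    """Proportion of variance explained, 1 - SSE/SST.

    Negative for models predicting worse than the mean activity.
    """
    ya = np.asarray(y, dtype=float)
    yh = np.asarray(y_hat, dtype=float)
    if ya.shape != yh.shape or ya.size < 2:
        raise DomainError("PVE needs >= 2 paired observations")
    sst = float(np.sum((ya - ya.mean()) ** 2))
    if sst == 0.0:
        raise DomainError("PVE undefined for constant observations")
    return 1.0 - float(np.sum((ya - yh) ** 2)) / sst


def compute_rmse(y, y_hat) -> float:
    """Root mean squared prediction error."""
    ya = np.asarray(y, dtype=float)
    yh = np.asarray(y_hat, dtype=float)
    if ya.shape != yh.shape or ya.size == 0:
        raise DomainError("RMSE needs >= 1 paired observation")
    return float(np.sqrt(np.mean((ya - yh) ** 2)))


@dataclass
class ValidationReport:
    """PVE/RMSE per (model, evaluation set) pair."""

    entries: list[dict] = field(default_factory=list)

    def add(self, model: str, eval_set: str, y, y_hat, n_features: int) -> None:
        self.entries.append(
            {
                "model": model,
                "set": eval_set,
                "pve": compute_pve(y, y_hat),
                "rmse": compute_rmse(y, y_hat),
                "n_features": n_features,
            }
        )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False)

    def lookup(self, model: str, eval_set: str) -> dict:
        for e in self.entries:
            if e["model"] == model and e["set"] == eval_set:
                return e
        raise KeyError((model, eval_set))


@dataclass
class ADReport:
    """Per-compound nearest-training distances and in/out-of-domain flags."""

    threshold: float
    z: float
    table: pd.DataFrame  # columns compound_id, nn_distance, outside

    @property
    def n_outside(self) -> int:
        return int(self.table["outside"].sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def applicability_domain(X_train_scaled, X_ivs_scaled, z: float = DEFAULT_AD_Z) -> ADReport:
    """Flag external compounds outside the Euclidean nearest-neighbour domain.

    threshold = mean + z * std of training nearest-neighbour distances
    (self excluded, population std); a compound is outside iff its
    distance to the nearest training compound strictly exceeds it.
    """
    if isinstance(X_train_scaled, FeatureMatrix):
        train = X_train_scaled.to_numpy()
    else:
        train = np.asarray(X_train_scaled, dtype=float)
    if isinstance(X_ivs_scaled, FeatureMatrix):
        ivs = X_ivs_scaled.to_numpy()
        ivs_ids = X_ivs_scaled.row_ids
    else:
        ivs = np.asarray(X_ivs_scaled, dtype=float)
        ivs_ids = [f"row{i + 1}" for i in range(ivs.shape[0])]
    if train.shape[0] < 2:
        raise TooSmallError("applicability domain needs >= 2 training rows")
    if train.shape[1] != ivs.shape[1]:
        raise AlignmentError("training and external matrices have different columns")

    dtt = cdist(train, train)
    np.fill_diagonal(dtt, np.inf)
    nn_train = dtt.min(axis=1)
    threshold = float(nn_train.mean() + z * nn_train.std())

    nn_ivs = cdist(ivs, train).min(axis=1)
    table = pd.DataFrame(
        {"compound_id": ivs_ids, "nn_distance": nn_ivs, "outside": nn_ivs > threshold}
    )
    logger.info("AD threshold %.4f (Z=%.2f): %d/%d external compounds outside",
                threshold, z, int(table["outside"].sum()), len(table))
    return ADReport(threshold=threshold, z=z, table=table)


@dataclass
class ModelBundle:
    """Everything needed to re-predict: learner, feature subset, scalers.

    The scaled training matrix (restricted to the subset) is kept so that
    new predictions carry applicability-domain flags.
    """

    estimator: object
    feature_subset: list[str]
    scaler: ScalerParams
    activity_prescaled: bool
    learner_config: dict
    seed: int
    ad_z: float
    train_scaled: pd.DataFrame

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.estimator, directory / "estimator.joblib")
        (directory / "scaler.json").write_text(self.scaler.to_json(), encoding="utf-8")
        self.train_scaled.to_csv(directory / "train_scaled.csv", index_label="compound_id")
        manifest = {
            "feature_subset": self.feature_subset,
            "activity_prescaled": self.activity_prescaled,
            "learner_config": self.learner_config,
            "seed": self.seed,
            "ad_z": self.ad_z,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text(encoding="utf-8"))
        return cls(
            estimator=joblib.load(directory / "estimator.joblib"),
            feature_subset=manifest["feature_subset"],
            scaler=ScalerParams.from_json((directory / "scaler.json").read_text(encoding="utf-8")),
            activity_prescaled=manifest["activity_prescaled"],
            learner_config=manifest["learner_config"],
            seed=manifest["seed"],
            ad_z=manifest["ad_z"],
            train_scaled=pd.read_csv(directory / "train_scaled.csv", index_col="compound_id"),
        )

    def predict(self, features: pd.DataFrame | FeatureMatrix) -> pd.DataFrame:
        """Scale raw feature rows with the stored params, restrict to the
        subset, predict, and attach AD flags."""
        df = features.values if isinstance(features, FeatureMatrix) else features
        missing = [c for c in self.scaler.mins.index if c not in df.columns]
        if missing:
            raise AlignmentError(f"input lacks feature column(s): {missing[:5]}")
        scaled = (df[self.scaler.mins.index] - self.scaler.mins) / (
            self.scaler.maxs - self.scaler.mins
        )
        X = scaled[self.feature_subset].to_numpy(dtype=float)
        preds = self.estimator.predict(X)
        ad = applicability_domain(self.train_scaled.to_numpy(), X, z=self.ad_z)
        return pd.DataFrame(
            {
                "compound_id": list(df.index),
                "prediction": preds,
                "nn_distance": ad.table["nn_distance"].to_numpy(),
                "outside_ad": ad.table["outside"].to_numpy(),
            }
        )


def fit_and_validate(
    X_train_scaled: FeatureMatrix,
    y_train,
    X_ivs_scaled: FeatureMatrix,
    y_ivs,
    feature_subset: list[str] | None,
    learner=None,
    seed: int = 0,
    internal_split=None,
    model_name: str = "model",
    report: ValidationReport | None = None,
    bundle_dir: str | Path | None = None,
    scaler: ScalerParams | None = None,
    activity_prescaled: bool = False,
    ad_z: float = DEFAULT_AD_Z,
):
    """Fit one final model on the whole training partition and validate it.

    ``feature_subset=None`` means all columns (the full-model).  When
    ``internal_split`` (a DataSplit of training ids) is given, the fitted
    model is also scored on the internal test rows so the report mirrors
    the stepwise stage's evaluation sets.  Returns ``(report, bundle)``;
    the bundle is persisted when ``bundle_dir`` and ``scaler`` are given.
    """
    if learner is None:
        from .stepwise import LearnerConfig

        learner = LearnerConfig()
    subset = list(feature_subset) if feature_subset is not None else X_train_scaled.column_names
    if not subset:
        raise ConfigurationError("feature subset is empty")
    report = report if report is not None else ValidationReport()

    y_tr = pd.Series(np.asarray(y_train, dtype=float), index=X_train_scaled.row_ids)
    Xs = X_train_scaled.subset_columns(subset)
    est = learner.make(seed=seed)
    est.fit(Xs.to_numpy(), y_tr.to_numpy())

    if internal_split is not None:
        X_int = Xs.subset_rows(internal_split.ivs_ids)
        report.add(
            model_name,
            "internal_test",
            y_tr.loc[internal_split.ivs_ids].to_numpy(),
            est.predict(X_int.to_numpy()),
            len(subset),
        )
    X_ext = X_ivs_scaled.subset_columns(subset)
    report.add(model_name, "ivs", np.asarray(y_ivs, dtype=float),
               est.predict(X_ext.to_numpy()), len(subset))

    bundle = None
    if scaler is not None:
        bundle = ModelBundle(
            estimator=est,
            feature_subset=subset,
            scaler=scaler,
            activity_prescaled=activity_prescaled,
            learner_config=dataclasses.asdict(learner),
            seed=seed,
            ad_z=ad_z,
            train_scaled=Xs.values,
        )
        if bundle_dir is not None:
            bundle.save(bundle_dir)
    return report, bundle
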