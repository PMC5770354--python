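"""Activity scaling, feature min-max scaling and the train/IVS partition.

Raw activities (nM concentrations) are mapped onto [0, 1] by a piecewise
log transform: values at or above 10,000 nM (10 uM, effectively inactive)
scale to 0, values at or below 1 nM (maximal potency) scale to 1, and in
between the value is (4 - log10(v)) / 4 — continuous at both cut-offs.

Features are min-max scaled per column, with parameters fitted on the
training partition only and applied unchanged to the Independent
Validation Set (IVS); IVS values may legitimately fall outside [0, 1] and
are not clipped — out-of-range values are applicability-domain signal,
and fitting on the training rows only avoids leaking the IVS into model
selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DomainError,
    InternalConsistencyError,
    TooSmallError,
)
from .featurize import FeatureMatrix

ACTIVITY_UPPER_CUTOFF_NM = 10_000.0  # >= this -> scaled 0
ACTIVITY_LOWER_CUTOFF_NM = 1.0  # <= this -> scaled 1


def scale_activity(raw_value):
    """Scale a positive nM activity (or array of them) onto [0, 1].

    Monotone non-increasing in the raw value: potent (low-concentration)
    measurements map near 1, inactive ones near 0.
    """
    arr = np.asarray(raw_value, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError("activity values must be positive and finite")
    with np.errstate(divide="ignore"):
        mid = (4.0 - np.log10(arr)) / 4.0
    out = np.where(arr >= ACTIVITY_UPPER_CUTOFF_NM, 0.0,
                   np.where(arr <= ACTIVITY_LOWER_CUTOFF_NM, 1.0, mid))
    if np.isscalar(raw_value) or np.ndim(raw_value) == 0:
        return float(out)
    return out


@dataclass
class ScaledActivities:
    """Activities on the [0, 1] scale (or passed through when pre-normalized)."""

    values: pd.Series
    skip_flag: bool = False  # True when the user supplied already-normalized data

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if np.any(v < 0) or np.any(v > 1):
            raise DomainError("scaled activities must lie in [0, 1]")


def scale_activities(raw: pd.Series, skip: bool = False) -> ScaledActivities:
    """Vector version of :func:`scale_activity`; ``skip=True`` passes
    pre-normalized values through unchanged (they must already be in [0, 1])."""
    if skip:
        return ScaledActivities(raw.astype(float), skip_flag=True)
    return ScaledActivities(pd.Series(scale_activity(raw.to_numpy(dtype=float)),
                                      index=raw.index), skip_flag=False)


@dataclass
class ScalerParams:
    """Per-column min/max fitted on the training rows."""

    mins: pd.Series
    maxs: pd.Series

    def to_json(self) -> str:
        return json.dumps({"mins": self.mins.to_dict(), "maxs": self.maxs.to_dict()})

    @classmethod
    def from_json(cls, text: str) -> "ScalerParams":
        d = json.loads(text)
        return cls(pd.Series(d["mins"]), pd.Series(d["maxs"]))


def fit_minmax(train_matrix: FeatureMatrix) -> ScalerParams:
    """Fit per-column min/max on the training rows only.

    Constant columns should have been removed at merge time; meeting one
    here indicates an upstream bug, not bad user input.
    """
    mins = train_matrix.values.min(axis=0)
    maxs = train_matrix.values.max(axis=0)
    bad = mins.index[(maxs - mins).to_numpy() <= 0].tolist()
    if bad:
        raise InternalConsistencyError(
            f"constant columns reached the scaler (merge should have removed them): {bad[:5]}"
        )
    return ScalerParams(mins, maxs)


def apply_minmax(matrix: FeatureMatrix, params: ScalerParams) -> FeatureMatrix:
    """Affine per-column transform x' = (x - min) / (max - min); no clipping."""
    if list(matrix.values.columns) != list(params.mins.index):
        raise AlignmentError("matrix columns do not match scaler parameters")
    scaled = (matrix.values - params.mins) / (params.maxs - params.mins)
    return FeatureMatrix(scaled, matrix.column_kind, dict(matrix.meta))


@dataclass
class DataSplit:
    """Disjoint train / IVS identifier sets, reproducible from the seed."""

    train_ids: list = field(default_factory=list)
    ivs_ids: list = field(default_factory=list)
    seed: int = 0
    train_fraction: float = 0.75


def partition_data(ids, train_fraction: float = 0.75, seed: int = 0) -> DataSplit:
    """Random 75/25 (by default) split into training set and IVS.

    The training size is round(train_fraction * n) (half-up), clamped so
    both sides are non-empty; sampling is uniform without replacement.
    """
    ids = list(ids)
    n = len(ids)
    if n < 4:
        raise TooSmallError(f"need at least 4 records to partition, got {n}")
    if not 0 < train_fraction < 1:
        raise DomainError("train_fraction must be in (0, 1)")
    n_train = int(np.floor(train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = [ids[i] for i in perm[:n_train]]
    ivs = [ids[i] for i in perm[n_train:]]
    return DataSplit(train_ids=train, ivs_ids=ivs, seed=seed, train_fraction=train_fraction)
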