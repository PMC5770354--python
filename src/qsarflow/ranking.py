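"""Random-Forest permutation-importance feature ranking.

Variable importance of feature j in one forest is the mean, over trees,
of the increase in out-of-bag (OOB) mean squared error when column j is
randomly permuted among that tree's OOB samples:

    VI(X_j) = sum_t VI^(t)(X_j) / ntree          (raw / "unscaled" score)
    Z_j     = VI(X_j) / (sigma_hat / sqrt(ntree))  ("scaled" z-score)

where sigma_hat is the standard deviation of the per-tree increases.
Because a single forest is stochastic, the forest fit is repeated over an
nfold cross-validation split of the training set (each run fits on a
fold's training portion) and the per-run scores are averaged; features
are then ranked in descending order of the averaged score without
eliminating any feature.

The bagged ensemble is built by hand on top of scikit-learn regression
trees so that each tree's bootstrap/OOB bookkeeping is explicit — the
per-tree OOB permutation scheme is not available from the stock
RandomForestRegressor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .errors import AlignmentError, ConfigurationError, TooSmallError
from .featurize import FeatureMatrix

logger = logging.getLogger(__name__)

RANKING_METHODS = ("scaled", "unscaled")

# cap on the temporary (rows x features) block built per tree when
# evaluating all single-feature permutations in one batched predict
_PERMUTATION_BLOCK_FLOATS = 4_000_000


@dataclass
class ImportanceRun:
    """Per-feature raw importance and standard error from one forest fit."""

    feature_names: list[str]
    raw: np.ndarray  # VI(X_j) for this forest
    se: np.ndarray  # sigma_hat / sqrt(ntree)
    ntree: int
    seed: int


@dataclass
class ImportanceTable:
    """Aggregated importances over nfold forest runs.

    ``table`` holds columns feature, mean_importance (unscaled score),
    z_score (scaled score), rank_scaled, rank_unscaled.
    """

    table: pd.DataFrame
    method: str
    ntree: int
    nfold: int
    seed: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(X, FeatureMatrix) or (hasattr(X, "to_numpy") and hasattr(X, "column_names")):
        return X.to_numpy(), np.asarray(y, dtype=float), list(X.column_names)
    Xa = np.asarray(X, dtype=float)
    return Xa, np.asarray(y, dtype=float), [f"f{i}" for i in range(Xa.shape[1])]


def rf_importance_run(
    X, y, ntree: int = 500, seed: int = 0, max_features: float | str = "third"
) -> ImportanceRun:
    """Fit one bagged forest and measure per-tree OOB permutation importance.

    ``max_features="third"`` tries p/3 features per split (the regression
    convention).  Reproducible from ``seed``.
    """
    Xa, ya, names = _as_xy(X, y)
    n, p = Xa.shape
    if n < 10:
        raise TooSmallError(f"need at least 10 rows for forest importance, got {n}")
    if ntree < 1:
        raise ConfigurationError("ntree must be >= 1")
    mf = max(1, p // 3) if max_features == "third" else max_features
    rng = np.random.default_rng(seed)

    per_tree = np.zeros((ntree, p))
    feat_chunk = max(1, min(p, _PERMUTATION_BLOCK_FLOATS // max(1, n * p)))
    for t in range(ntree):
        boot = rng.integers(0, n, size=n)
        tree = DecisionTreeRegressor(
            max_features=mf, random_state=int(rng.integers(0, 2**31 - 1))
        )
        tree.fit(Xa[boot], ya[boot])
        oob = np.flatnonzero(~np.isin(np.arange(n), boot))
        m = oob.size
        if m < 2:
            continue  # degenerate bootstrap: no usable OOB set, VI^(t) = 0
        Xo = Xa[oob]
        yo = ya[oob]
        base_mse = float(np.mean((tree.predict(Xo) - yo) ** 2))
        # evaluate all single-feature permutations in batched predicts
        for start in range(0, p, feat_chunk):
            cols = np.arange(start, min(start + feat_chunk, p))
            block = np.tile(Xo, (cols.size, 1))
            for bi, j in enumerate(cols):
                block[bi * m : (bi + 1) * m, j] = Xo[rng.permutation(m), j]
            preds = tree.predict(block).reshape(cols.size, m)
            per_tree[t, cols] = np.mean((preds - yo) ** 2, axis=1) - base_mse

    raw = per_tree.mean(axis=0)
    se = per_tree.std(axis=0, ddof=1) / np.sqrt(ntree) if ntree > 1 else np.zeros(p)
    return ImportanceRun(feature_names=names, raw=raw, se=se, ntree=ntree, seed=seed)


def aggregate_importance(runs: list[ImportanceRun], method: str = "unscaled") -> ImportanceTable:
    """Average per-run importances into one table.

    The unscaled score is the mean of per-run raw importances; the scaled
    score is the mean of per-run z = raw/se ratios, with z := 0 for runs
    whose standard error is exactly 0 (no division error).
    """
    if method not in RANKING_METHODS:
        raise ConfigurationError(f"method must be one of {RANKING_METHODS}")
    if not runs:
        raise ConfigurationError("need at least one importance run")
    names = runs[0].feature_names
    name_set = set(names)
    raws, zs = [], []
    for r in runs:
        if set(r.feature_names) != name_set:
            raise AlignmentError("importance runs cover different feature sets")
        # align by name so run/column order cannot affect the aggregate
        idx = np.array([r.feature_names.index(n) for n in names]) if r.feature_names != names \
            else np.arange(len(names))
        raws.append(r.raw[idx])
        zs.append(np.divide(r.raw, r.se, out=np.zeros_like(r.raw), where=r.se > 0)[idx])
    raws = np.vstack(raws)
    zs = np.vstack(zs)
    df = pd.DataFrame(
        {
            "feature": names,
            "mean_importance": raws.mean(axis=0),
            "z_score": zs.mean(axis=0),
        }
    )
    for score, col in (("z_score", "rank_scaled"), ("mean_importance", "rank_unscaled")):
        order = np.lexsort((df["feature"].to_numpy(), -df[score].to_numpy()))
        ranks = np.empty(len(df), dtype=int)
        ranks[order] = np.arange(1, len(df) + 1)
        df[col] = ranks
    return ImportanceTable(
        table=df, method=method, ntree=runs[0].ntree, nfold=len(runs), seed=runs[0].seed
    )


def rank_features(table: ImportanceTable) -> list[str]:
    """Feature names in descending order of the active method's score.

    Ties break toward the lexicographically smaller name; no feature is
    eliminated, the output is a permutation of all features.
    """
    col = "rank_scaled" if table.method == "scaled" else "rank_unscaled"
    return table.table.sort_values(col)["feature"].tolist()


def rank_by_forest(
    X_train,
    y_train,
    nfold: int = 10,
    ntree: int = 500,
    seed: int = 0,
    method: str = "unscaled",
    max_features: float | str = "third",
) -> ImportanceTable:
    """Full ranking procedure: nfold repeated forest fits, then aggregation.

    Run t fits on the training portion of fold t of a shuffled KFold split
    of the training set and uses seed ``seed + t`` so the whole ranking is
    reproducible from one integer.
    """
    Xa, ya, names = _as_xy(X_train, y_train)
    if nfold < 2:
        raise ConfigurationError("nfold must be >= 2")
    kf = KFold(n_splits=nfold, shuffle=True, random_state=seed % (2**32))
    runs = []
    for t, (fit_idx, _held) in enumerate(kf.split(Xa)):
        run = rf_importance_run(
            FeatureMatrixLike(Xa[fit_idx], names), ya[fit_idx],
            ntree=ntree, seed=seed + t, max_features=max_features,
        )
        runs.append(run)
    table = aggregate_importance(runs, method=method)
    table.seed = seed
    return table


class FeatureMatrixLike:
    """Minimal duck-typed feature matrix (ndarray + column names)."""

    def __init__(self, array: np.ndarray, names: list[str]):
        self._array = array
        self.column_names = list(names)

    def to_numpy(self) -> np.ndarray:
        return self._array
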