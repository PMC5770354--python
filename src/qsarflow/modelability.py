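"""Dataset modelability (MODI) estimation and gating.

MODI for regression is the coefficient of determination of leave-one-out
k-nearest-neighbour prediction on the scaled training set: for each
compound, the unweighted mean activity of its k nearest neighbours (by
Euclidean distance over all retained, [0,1]-scaled columns) is compared
with the observed activity.  It rests on the similarity principle —
similar compounds should show similar activity — so datasets riddled with
activity cliffs score low.  A score above 0.45 is taken as evidence that
a model with acceptable predictivity is reachable; below it, the pipeline
warns or halts with curation advice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import TooSmallError, UndefinedModelabilityError
from .featurize import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_GATE_THRESHOLD = 0.45
DEFAULT_KS = (3, 5)


@dataclass
class ModiResult:
    k: int
    score: float
    gate_threshold: float = DEFAULT_GATE_THRESHOLD
    # passed iff score strictly exceeds the threshold
    passed: bool = False

    def __post_init__(self) -> None:
        self.passed = self.score > self.gate_threshold


class ModelabilityGateFailure(Exception):
    """Raised in halt mode when the dataset is judged non-modelable."""


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.to_numpy()
    return np.asarray(X, dtype=float)


def knn_loo_predictions(X, y, k: int) -> np.ndarray:
    """Leave-one-out kNN regression predictions.

    For each row, the prediction is the unweighted mean activity of its k
    nearest other rows by Euclidean distance; exact distance ties are
    broken toward the lower row index (stable sort).
    """
    Xa = _as_array(X)
    ya = np.asarray(y, dtype=float)
    n = Xa.shape[0]
    if n <= k:
        raise TooSmallError(f"need more than k={k} rows for LOO kNN, got {n}")
    dist = cdist(Xa, Xa)
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    return ya[order].mean(axis=1)


def modi_ssr2(y, y_hat) -> float:
    """Coefficient of determination 1 - SSE/SST of the LOO predictions.

    May be negative when neighbours predict worse than the mean activity.
    """
    ya = np.asarray(y, dtype=float)
    yh = np.asarray(y_hat, dtype=float)
    if ya.shape != yh.shape or ya.size < 2:
        raise TooSmallError("need at least 2 paired observations")
    sst = float(np.sum((ya - ya.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedModelabilityError("constant activities: modelability undefined")
    sse = float(np.sum((ya - yh) ** 2))
    return 1.0 - sse / sst


def modi(X, y, k: int = 5, gate_threshold: float = DEFAULT_GATE_THRESHOLD) -> ModiResult:
    """Compute MODI for one neighbour count on the scaled training set."""
    return ModiResult(k=k, score=modi_ssr2(y, knn_loo_predictions(X, y, k)),
                      gate_threshold=gate_threshold)


def modelability_gate(result: ModiResult, mode: str = "halt") -> bool:
    """Gate the pipeline on a MODI result.

    In ``halt`` mode a failing score aborts with curation advice; in
    ``warn`` mode the pipeline proceeds with a logged warning.  Returns
    the gate decision.
    """
    if result.passed:
        logger.info("MODI(k=%d) = %.3f > %.2f: dataset judged modelable",
                    result.k, result.score, result.gate_threshold)
        return True
    msg = (
        f"MODI(k={result.k}) = {result.score:.3f} <= {result.gate_threshold:.2f}: the dataset "
        "is unlikely to yield a predictive model. Consider additional curation: remove "
        "activity cliffs or assay mixtures, add compounds, or try a different feature set."
    )
    if mode == "halt":
        raise ModelabilityGateFailure(msg)
    logger.warning(msg)
    return False
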