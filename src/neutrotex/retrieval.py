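"""Extended-Canberra ranking of database descriptors against a query.

The extended Canberra distance between non-negative feature vectors ``a``
and ``b`` is ``sum_t |a_t - b_t| / (a_t + mean(a) + b_t + mean(b))``.
Adding each vector's mean to the denominator tempers the ordinary Canberra
distance's hypersensitivity near zero bins while keeping every summand in
``[0, 1)`` and the whole distance scale-free: rescaling both vectors by the
same positive factor leaves it unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator


@dataclass(frozen=True)
class RankedResult:
    """Top-eta database matches for one query, ascending by distance."""

    query_id: str
    ranked_ids: List[str]
    distances: List[float]
    eta: int

    def __post_init__(self) -> None:
        if len(self.ranked_ids) != len(self.distances):
            raise ValueError("ranked_ids and distances must have equal length")
        if any(d2 < d1 - 1e-12 for d1, d2 in zip(self.distances, self.distances[1:])):
            raise ValueError("distances must be non-decreasing")


@dataclass(frozen=True)
class FeatureDatabase:
    """Descriptor matrix with per-image ids and class labels."""

    ids: List[str]
    X: np.ndarray
    labels: List[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("image ids must be unique")
        if self.X.ndim != 2 or self.X.shape[0] != len(self.ids):
            raise ValueError("X must be 2-D with one row per id")
        if len(self.labels) != len(self.ids):
            raise ValueError("labels must match ids")

    @property
    def dim(self) -> int:
        return self.X.shape[1]


def extended_canberra(a: np.ndarray, b: np.ndarray) -> float:
    """Extended Canberra distance between two non-negative vectors.

    Terms with a zero denominator (possible only when both vectors are
    identically zero) contribute 0.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"incompatible descriptors: shapes {a.shape} and {b.shape}")
    mu_a = a.mean()
    mu_b = b.mean()
    denom = a + mu_a + b + mu_b
    num = np.abs(a - b)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, num / denom, 0.0)
    return float(terms.sum())


def _pairwise_to_query(X: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Extended Canberra distance from ``q`` to every row of ``X``."""
    mu_rows = X.mean(axis=1, keepdims=True)
    mu_q = q.mean()
    denom = X + mu_rows + q[None, :] + mu_q
    num = np.abs(X - q[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, num / denom, 0.0)
    return terms.sum(axis=1)


def query(
    db: FeatureDatabase,
    q: np.ndarray,
    eta: int,
    query_id: str = "query",
    exclude_self: bool = False,
) -> RankedResult:
    """Rank all database images against descriptor ``q``; return the top eta.

    Ties are broken by lexicographic image id so runs are reproducible.  When
    the query is itself a database member its self-match (distance 0) ranks
    first unless ``exclude_self`` is set, in which case the entry whose id
    equals ``query_id`` is dropped before ranking.
    """
    if db.X.shape[0] == 0:
        raise ValueError("database is empty")
    q = np.asarray(q, dtype=np.float64)
    if q.shape != (db.dim,):
        raise ValueError(f"query dim {q.shape} does not match database dim {db.dim}")
    if not 1 <= eta:
        raise ValueError(f"eta must be >= 1, got {eta}")
    ids = np.asarray(db.ids, dtype=object)
    X = db.X
    if exclude_self:
        keep = ids != query_id
        ids = ids[keep]
        X = X[keep]
        if X.shape[0] == 0:
            raise ValueError("database is empty after excluding the query")
    dist = _pairwise_to_query(X, q)
    order = np.lexsort((ids.astype(str), dist))
    top = order[: min(eta, len(order))]
    return RankedResult(
        query_id=query_id,
        ranked_ids=[str(ids[i]) for i in top],
        distances=[float(dist[i]) for i in top],
        eta=int(eta),
    )


class CanberraRetrievalIndex(BaseEstimator):
    """Fitted retrieval index over descriptor rows with class labels.

    Parameters
    ----------
    eta : int, default=100
        Retrieval depth (top matches returned per query).
    exclude_self : bool, default=False
        Drop a database entry whose id equals the query id before ranking.

    Attributes
    ----------
    database_ : FeatureDatabase
        The stored descriptors, ids and labels.
    n_features_in_ : int
        Descriptor dimensionality.
    """

    def __init__(self, eta: int = 100, exclude_self: bool = False):
        self.eta = eta
        self.exclude_self = exclude_self

    def fit(self, X, y, ids: Optional[Sequence[str]] = None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D descriptor matrix")
        labels = [str(v) for v in y]
        if ids is None:
            ids = [f"img{i:05d}" for i in range(X.shape[0])]
        self.database_ = FeatureDatabase(ids=list(map(str, ids)), X=X, labels=labels)
        self.n_features_in_ = X.shape[1]
        return self

    def query(self, q: np.ndarray, query_id: str = "query") -> RankedResult:
        self._check_fitted()
        return query(self.database_, q, eta=self.eta, query_id=query_id,
                     exclude_self=self.exclude_self)

    def query_all(self, Q: np.ndarray, query_ids: Sequence[str]) -> List[RankedResult]:
        """Rank every row of ``Q``; one :class:`RankedResult` per query."""
        self._check_fitted()
        Q = np.asarray(Q, dtype=np.float64)
        return [self.query(Q[i], query_id=str(query_ids[i])) for i in range(Q.shape[0])]

    def kneighbors(self, Q: np.ndarray):
        """Distances and database indices of the top-eta matches per row of ``Q``."""
        self._check_fitted()
        Q = np.asarray(Q, dtype=np.float64)
        ids = np.asarray(self.database_.ids, dtype=object)
        dists, idxs = [], []
        for i in range(Q.shape[0]):
            d = _pairwise_to_query(self.database_.X, Q[i])
            order = np.lexsort((ids.astype(str), d))[: min(self.eta, len(ids))]
            dists.append(d[order])
            idxs.append(order)
        return np.vstack(dists), np.vstack(idxs)

    def _check_fitted(self) -> None:
        if not hasattr(self, "database_"):
            raise ValueError("CanberraRetrievalIndex is not fitted; call fit first")
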