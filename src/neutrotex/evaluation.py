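"""Retrieval metrics: avgP, avgR, F-score, mean average precision, CV.

With every database image used as a query, retrieval depth ``eta`` and, for
query ``i``, ``r_i`` relevant images among the top eta and ``g_i`` relevant
images in the whole database:

* ``avgP = (100 / omega) * sum_i r_i / eta``
* ``avgR = (100 / omega) * sum_i r_i / g_i``
* ``Fscore = 2 * avgP * avgR / (avgP + avgR)``
* ``MavgP`` is the mean over queries of average precision, where a query's
  average precision is ``(1 / g_i) * sum over relevant ranks k <= eta of
  (relevant-so-far at k) / k``.

The coefficient of variation (population standard deviation over mean) of a
metric across noise conditions quantifies how stable a descriptor is under
image degradation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .retrieval import RankedResult


@dataclass(frozen=True)
class MetricsReport:
    """Aggregate retrieval rates, in percent, for one condition."""

    avgP: float
    avgR: float
    Fscore: float
    MavgP: float
    eta: int
    omega: int

    def as_dict(self) -> Dict[str, float]:
        return {
            "avgP": self.avgP,
            "avgR": self.avgR,
            "Fscore": self.Fscore,
            "MavgP": self.MavgP,
            "eta": self.eta,
            "omega": self.omega,
        }


def _query_class(result: RankedResult, labels: Mapping[str, str],
                 query_class: Optional[str]) -> str:
    if query_class is not None:
        return str(query_class)
    if result.query_id not in labels:
        raise KeyError(f"no label for query id {result.query_id!r}")
    return str(labels[result.query_id])


def per_query_counts(
    result: RankedResult,
    labels: Mapping[str, str],
    query_class: Optional[str] = None,
) -> Tuple[int, int]:
    """``(r, g)``: relevant retrieved in the top eta, relevant in the database.

    ``labels`` maps every database image id to its class; ``g`` is the count
    of database entries sharing the query's class (the query itself included
    when it is a database member).  The query's class is looked up from
    ``labels`` unless ``query_class`` is given.
    """
    qclass = _query_class(result, labels, query_class)
    for rid in result.ranked_ids:
        if rid not in labels:
            raise KeyError(f"no label for retrieved id {rid!r}")
    r = sum(1 for rid in result.ranked_ids if str(labels[rid]) == qclass)
    g = sum(1 for v in labels.values() if str(v) == qclass)
    return r, g


def _average_precision(result: RankedResult, labels: Mapping[str, str],
                       qclass: str, g: int) -> float:
    if g == 0:
        return 0.0
    hits = 0
    total = 0.0
    for k, rid in enumerate(result.ranked_ids, start=1):
        if str(labels[rid]) == qclass:
            hits += 1
            total += hits / k
    return total / g


def aggregate_metrics(
    runs: Sequence[RankedResult],
    labels: Mapping[str, str],
    eta: int,
    query_classes: Optional[Sequence[str]] = None,
) -> MetricsReport:
    """Aggregate the four retrieval rates over all queries."""
    if not runs:
        raise ValueError("at least one query result is required")
    for run in runs:
        if run.eta != eta:
            raise ValueError(
                f"inconsistent retrieval depth: run {run.query_id!r} used eta="
                f"{run.eta}, expected {eta}"
            )
    omega = len(runs)
    p_sum = r_sum = ap_sum = 0.0
    for i, run in enumerate(runs):
        qclass = _query_class(
            run, labels, None if query_classes is None else query_classes[i]
        )
        r, g = per_query_counts(run, labels, query_class=qclass)
        p_sum += r / eta
        r_sum += (r / g) if g > 0 else 0.0
        ap_sum += _average_precision(run, labels, qclass, g)
    avgP = 100.0 * p_sum / omega
    avgR = 100.0 * r_sum / omega
    fscore = 0.0 if avgP + avgR == 0 else 2.0 * avgP * avgR / (avgP + avgR)
    mavgp = 100.0 * ap_sum / omega
    return MetricsReport(avgP=avgP, avgR=avgR, Fscore=fscore, MavgP=mavgp,
                         eta=int(eta), omega=omega)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Population standard deviation divided by the mean."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("values must be non-empty")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("coefficient of variation is undefined for zero mean")
    return float(arr.std() / mean)
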