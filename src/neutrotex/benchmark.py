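"""End-to-end pipeline helpers: extract, evaluate, and the noise benchmark.

These functions chain the estimators into the standard protocol: every
database image is used as a query against the full database (clean
condition), then a noise-corrupted copy of every image is used as a query
against the clean database (noisy condition), and the coefficient of
variation of each retrieval rate across the two conditions summarizes
noise stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .descriptor import MsNrRiTxPExtractor
from .evaluation import MetricsReport, aggregate_metrics, coefficient_of_variation
from .retrieval import CanberraRetrievalIndex, RankedResult
from .synthetic import NoiseSpec, SyntheticDataset, build_noisy_query_protocol


@dataclass(frozen=True)
class BenchmarkResult:
    """Clean and (optionally) noisy retrieval reports plus per-metric CV."""

    clean: MetricsReport
    noisy: Optional[MetricsReport]
    cv: Dict[str, float]


def extract_dataset(
    dataset: SyntheticDataset,
    w: int = 3,
    scales: Optional[Sequence[int]] = None,
    normalize: bool = True,
) -> Tuple[MsNrRiTxPExtractor, np.ndarray]:
    """Fit an extractor on a dataset and return it with the descriptor matrix."""
    extractor = MsNrRiTxPExtractor(w=w, scales=scales, normalize=normalize)
    X = extractor.fit_transform(dataset.images)
    return extractor, X


def evaluate_queries(
    index: CanberraRetrievalIndex,
    Q: np.ndarray,
    query_ids: Sequence[str],
    query_classes: Sequence[str],
    eta: int,
) -> Tuple[MetricsReport, List[RankedResult]]:
    """Rank every query row and aggregate the four retrieval rates."""
    runs = index.query_all(Q, query_ids)
    labels = dict(zip(index.database_.ids, index.database_.labels))
    report = aggregate_metrics(runs, labels, eta, query_classes=list(query_classes))
    return report, runs


def cross_condition_cv(clean: MetricsReport, noisy: MetricsReport) -> Dict[str, float]:
    """Per-metric coefficient of variation across the two noise conditions."""
    out = {}
    for key in ("avgP", "avgR", "Fscore", "MavgP"):
        pair = [getattr(clean, key), getattr(noisy, key)]
        out[key] = coefficient_of_variation(pair)
    return out


def run_benchmark(
    dataset: SyntheticDataset,
    noise_spec: Optional[NoiseSpec] = None,
    w: int = 3,
    scales: Optional[Sequence[int]] = None,
    normalize: bool = True,
    eta: int = 100,
    exclude_self: bool = False,
) -> BenchmarkResult:
    """Clean all-queries evaluation, plus the noisy-query condition and CV."""
    extractor, X = extract_dataset(dataset, w=w, scales=scales, normalize=normalize)
    eta = min(eta, len(dataset.ids))
    index = CanberraRetrievalIndex(eta=eta, exclude_self=exclude_self).fit(
        X, dataset.labels, ids=dataset.ids
    )
    clean, _ = evaluate_queries(index, X, dataset.ids, dataset.labels, eta)
    noisy = None
    cv: Dict[str, float] = {}
    if noise_spec is not None:
        protocol = build_noisy_query_protocol(dataset, noise_spec)
        Q = extractor.transform(protocol.queries.images)
        noisy, _ = evaluate_queries(
            index, Q, protocol.queries.ids, protocol.queries.labels, eta
        )
        cv = cross_condition_cv(clean, noisy)
    return BenchmarkResult(clean=clean, noisy=noisy, cv=cv)
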