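"""Per-cell quality filtering and iterative marker-percentile contaminant removal.

The contaminant rule follows the two-stage procedure used for CD138+
selections: cluster all cells, summarize the plasma marker (SDC1 analog)
per cluster with a nearest-rank percentile of raw counts, and drop
clusters whose 90th-percentile cell has zero marker counts; then
re-cluster survivors and repeat at the 75th percentile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .types import ExpressionMatrix


@dataclass
class QCThresholds:
    min_counts: int = 500
    min_features: int = 200
    max_features: int = 6000
    max_mito_fraction: float = 0.20
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_features >= self.max_features:
            raise ValueError("min_features must be < max_features")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass
class QCReport:
    n_input: int
    removed_by_filter: dict[str, int]
    kept_barcodes: list[str]
    removed_clusters: list[list[int]] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return len(self.kept_barcodes)


def qc_filter_cells(
    matrix: ExpressionMatrix, thresholds: QCThresholds | None = None
) -> tuple[list[str], QCReport]:
    """Keep cells passing count/feature/mito filters.

    Removals are attributed to the first failing filter in the fixed order
    (min_counts, min_features, max_features, max_mito).
    """
    thr = thresholds or QCThresholds()
    counts = matrix.counts
    totals = np.asarray(counts.sum(axis=1)).ravel()
    detected = np.asarray((counts > 0).sum(axis=1)).ravel()
    mito_idx = [
        i for i, f in enumerate(matrix.features) if f.startswith(thr.mito_prefix)
    ]
    if mito_idx:
        mito = np.asarray(counts[:, mito_idx].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
        apply_mito = True
    else:
        mito_frac = np.zeros(matrix.n_cells)
        apply_mito = False
        if thr.max_mito_fraction < 1.0:
            warnings.warn(
                f"no features with prefix {thr.mito_prefix!r}; mito filter skipped",
                stacklevel=2,
            )

    removed = {"min_counts": 0, "min_features": 0, "max_features": 0, "max_mito": 0}
    keep = np.ones(matrix.n_cells, dtype=bool)
    for i in range(matrix.n_cells):
        if totals[i] < thr.min_counts:
            removed["min_counts"] += 1
        elif detected[i] < thr.min_features:
            removed["min_features"] += 1
        elif detected[i] > thr.max_features:
            removed["max_features"] += 1
        elif apply_mito and mito_frac[i] > thr.max_mito_fraction:
            removed["max_mito"] += 1
        else:
            continue
        keep[i] = False
    kept = [b for b, k in zip(matrix.barcodes, keep) if k]
    return kept, QCReport(matrix.n_cells, removed, kept)


def percentile_cell_value(values: Sequence[float] | np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the sorted value at rank ceil(q * n)."""
    v = np.asarray(values)
    if v.size == 0:
        raise ValueError("percentile of empty vector")
    if not 0.0 < q <= 1.0:
        raise ValueError(f"q must be in (0, 1], got {q}")
    rank = math.ceil(q * v.size)
    return float(np.sort(v)[rank - 1])


def flag_contaminant_clusters(
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    marker_gene: str,
    q: float,
) -> set[int]:
    """Clusters whose q-percentile cell has zero raw counts of the marker."""
    labels = np.asarray(labels)
    if labels.shape[0] != matrix.n_cells:
        raise ValueError("labels do not cover every cell")
    j = matrix.feature_index(marker_gene)  # KeyError names the gene
    marker = np.asarray(matrix.counts[:, j].todense()).ravel()
    flagged = set()
    for c in np.unique(labels):
        if percentile_cell_value(marker[labels == c], q) == 0:
            flagged.add(int(c))
    return flagged


def iterative_plasma_selection(
    matrix: ExpressionMatrix,
    cluster_fn: Callable[[ExpressionMatrix], np.ndarray],
    marker_gene: str,
    schedule: Sequence[float] = (0.90, 0.75),
) -> tuple[list[str], QCReport]:
    """Iterative contaminant-cluster removal.

    Each pass clusters the surviving cells with ``cluster_fn`` and drops
    clusters flagged at that pass's percentile. ``cluster_fn`` must be
    deterministic given its own seed for the whole procedure to be
    reproducible.
    """
    current = matrix
    dropped_per_iter: list[list[int]] = []
    n_removed = 0
    for q in schedule:
        labels = np.asarray(cluster_fn(current))
        flagged = flag_contaminant_clusters(current, labels, marker_gene, q)
        if flagged and len(flagged) == len(np.unique(labels)):
            raise ValueError("no plasma-like cells retained")
        dropped_per_iter.append(sorted(flagged))
        keep = ~np.isin(labels, list(flagged))
        n_removed += int((~keep).sum())
        current = current.subset_cells(keep)
    report = QCReport(
        matrix.n_cells,
        {"contaminant_clusters": n_removed},
        list(current.barcodes),
        removed_clusters=dropped_per_iter,
    )
    return list(current.barcodes), report
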