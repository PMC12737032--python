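"""Similarity matrices across signal-processing pipelines, and their
hierarchical-clustering dendrograms.

Three cell types quantify, over a cohort, the discrepancy a different
pipeline (device) would have introduced in the same indicator:

* SMAPE (0-200%) for scalar indicators: mean over subjects of
  |Vsi - Vsj| / ((Vsi + Vsj) / 2) * 100;
* window overlap (0-100%): mean circular intersection of the designated
  L5/M10 windows divided by the window length;
* IoU / Jaccard (0-100%): mean intersection-over-union of sleep
  interval sets.

For clustering, a matrix is converted to dissimilarities (SMAPE / 200,
or 1 - overlap / 100), min-max rescaled to [0, 1] over the off-diagonal
cells, and its rows are used as feature vectors under the Euclidean
metric with complete linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core import ConfigurationError, UndefinedValueError
from .npcra import SECONDS_PER_DAY, WindowDesignation

Segments = Sequence[Tuple[int, int]]


@dataclass
class SimilarityMatrix:
    labels: List[str]
    values: np.ndarray     # symmetric, units %
    metric: str            # "SMAPE", "overlap" or "IoU"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)


def smape_matrix(table: pd.DataFrame) -> SimilarityMatrix:
    """SMAPE matrix of a subjects x pipelines table of scalar values."""
    labels = list(table.columns)
    v = table.to_numpy(dtype=float)
    n_lab = len(labels)
    m = np.zeros((n_lab, n_lab))
    for i in range(n_lab):
        for j in range(i + 1, n_lab):
            denom = (v[:, i] + v[:, j]) / 2.0
            zero = denom == 0
            if zero.any():
                s = table.index[int(np.flatnonzero(zero)[0])]
                raise UndefinedValueError(
                    f"SMAPE undefined for subject {s!r}, pipelines "
                    f"{labels[i]!r} vs {labels[j]!r}: both values are zero")
            cell = float(np.mean(np.abs(v[:, i] - v[:, j]) / denom) * 100.0)
            m[i, j] = m[j, i] = cell
    return SimilarityMatrix(labels=labels, values=m, metric="SMAPE")


def circular_window_overlap_s(onset_a: float, onset_b: float,
                              length_s: float,
                              period_s: float = SECONDS_PER_DAY) -> float:
    """Intersection length of two equal-length circular windows."""
    d = abs(onset_a - onset_b) % period_s
    d = min(d, period_s - d)
    # windows can overlap across both arcs of the circle
    return max(0.0, length_s - d) + max(0.0, length_s - (period_s - d))


def overlap_matrix(table: pd.DataFrame, length_h: float) -> SimilarityMatrix:
    """Window-overlap matrix of a subjects x pipelines table of
    :class:`WindowDesignation` cells (all with length ``length_h``)."""
    labels = list(table.columns)
    length_s = length_h * 3600.0
    for col in labels:
        for w in table[col]:
            if not isinstance(w, WindowDesignation):
                raise ConfigurationError("overlap_matrix needs WindowDesignation cells")
            if w.length_h != length_h:
                raise ConfigurationError(
                    f"mixed window lengths: expected {length_h} h, "
                    f"found {w.length_h} h")
    n_lab = len(labels)
    m = np.full((n_lab, n_lab), 100.0)
    for i in range(n_lab):
        for j in range(i + 1, n_lab):
            overlaps = [
                circular_window_overlap_s(wi.onset_s, wj.onset_s, length_s)
                for wi, wj in zip(table.iloc[:, i], table.iloc[:, j])]
            cell = float(np.mean(overlaps) / length_s * 100.0)
            m[i, j] = m[j, i] = cell
    return SimilarityMatrix(labels=labels, values=m, metric="overlap")


def _interval_total(segs: Segments) -> float:
    return float(sum(e - s for s, e in segs))


def _interval_intersection(a: Segments, b: Segments) -> float:
    total = 0.0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def interval_iou(a: Segments, b: Segments) -> float:
    """Jaccard index of two interval sets, measured in time."""
    inter = _interval_intersection(a, b)
    union = _interval_total(a) + _interval_total(b) - inter
    if union == 0:
        raise UndefinedValueError("IoU undefined: both interval sets are empty")
    return inter / union


def iou_matrix(table: pd.DataFrame) -> SimilarityMatrix:
    """IoU matrix of a subjects x pipelines table of segment lists."""
    labels = list(table.columns)
    n_lab = len(labels)
    m = np.full((n_lab, n_lab), 100.0)
    for i in range(n_lab):
        for j in range(i + 1, n_lab):
            cells = []
            for s, (a, b) in zip(table.index,
                                 zip(table.iloc[:, i], table.iloc[:, j])):
                try:
                    cells.append(interval_iou(a, b))
                except UndefinedValueError:
                    raise UndefinedValueError(
                        f"IoU undefined for subject {s!r}, pipelines "
                        f"{labels[i]!r} vs {labels[j]!r}: both segment "
                        "sets are empty") from None
            cell = float(np.mean(cells) * 100.0)
            m[i, j] = m[j, i] = cell
    return SimilarityMatrix(labels=labels, values=m, metric="IoU")


def to_dissimilarity(matrix: SimilarityMatrix) -> np.ndarray:
    """Rescaled [0, 1] dissimilarity form of a similarity matrix."""
    if matrix.metric == "SMAPE":
        d = matrix.values / 200.0
    else:
        d = 1.0 - matrix.values / 100.0
    n = len(matrix.labels)
    off = ~np.eye(n, dtype=bool)
    lo, hi = d[off].min(), d[off].max()
    if hi > lo:
        d = (d - lo) / (hi - lo)
    else:
        d = np.zeros_like(d)
    np.fill_diagonal(d, 0.0)
    return d


def dendrogram(matrix: SimilarityMatrix) -> Tuple[np.ndarray, List[str]]:
    """Complete-linkage tree of the rescaled dissimilarity matrix.

    Each pipeline's feature vector is its row of the rescaled matrix;
    distances are Euclidean. Returns the SciPy linkage array and the
    leaf labels.
    """
    if len(matrix.labels) < 2:
        raise ConfigurationError("dendrogram needs at least two pipelines")
    d = to_dissimilarity(matrix)
    z = hierarchy.linkage(pdist(d, metric="euclidean"), method="complete")
    return z, list(matrix.labels)


def cut_two(z: np.ndarray, labels: Sequence[str]) -> Tuple[set, set]:
    """The first bipartition of a linkage tree (top-level two clusters)."""
    assign = hierarchy.fcluster(z, t=2, criterion="maxclust")
    a = {lab for lab, c in zip(labels, assign) if c == 1}
    b = {lab for lab, c in zip(labels, assign) if c == 2}
    return a, b


def _quote(label: str) -> str:
    return "'" + label.replace("'", "''") + "'"


def to_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    """Newick export with branch lengths equal to merge-height
    differences; labels are single-quoted (they contain parentheses)."""
    tree = hierarchy.to_tree(z)

    def render(node, parent_dist: float) -> str:
        bl = parent_dist - node.dist
        if node.is_leaf():
            return f"{_quote(labels[node.id])}:{bl:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{bl:.10g}"

    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"


def matrices_to_csv(matrices: Dict[str, SimilarityMatrix], outdir) -> None:
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, m in matrices.items():
        m.to_frame().to_csv(outdir / f"{name}.csv")
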