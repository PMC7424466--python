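"""Category similarity, average-linkage (UPGMA) clustering and heatmap tables.

Categories (typically the five scientific areas) are compared by the Jaccard
coefficient of their document-occurrence sets — the documents in which each
category's dictionary matched at least once. The similarity matrix is turned
into a dendrogram by unweighted average linkage on the dissimilarity
``d = 1 - s``: categories that tend to hit the same documents merge early.

UPGMA is implemented here rather than delegated to scipy because the merge
order under ties and the leaf traversal are pinned (alphabetical pair label,
left-first), making every downstream artifact byte-reproducible; scipy's
``linkage(..., "average")`` agrees on tie-free inputs and is used as a
cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .classify import ClassificationProfile


@dataclass
class SimilarityMatrix:
    """A symmetric similarity matrix with unit diagonal, entries in [0, 1]."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("similarity matrix diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class Dendrogram:
    """UPGMA merge tree: (cluster_a, cluster_b, height) per agglomeration.

    Clusters are named by the sorted tuple of their leaf labels; ``leaf_order``
    is the left-first traversal of the final tree.
    """

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    leaf_order: list[str]


def category_jaccard_matrix(
    profiles: Sequence[ClassificationProfile],
    categories: Optional[Sequence[str]] = None,
) -> SimilarityMatrix:
    """Jaccard similarity between categories' document-occurrence sets.

    A category's set contains the documents with at least one dictionary hit
    for it. Two categories hitting no documents at all get off-diagonal 0;
    the diagonal is 1 by definition.
    """
    if categories is None:
        categories = sorted(profiles[0].hits) if profiles else []
    categories = list(categories)
    if len(categories) < 2:
        raise ValueError("need at least two categories")
    sets = {
        c: frozenset(p.doc_id for p in profiles if p.hits.get(c, 0) >= 1)
        for c in categories
    }
    n = len(categories)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            union = sets[categories[i]] | sets[categories[j]]
            s = (len(sets[categories[i]] & sets[categories[j]]) / len(union)
                 if union else 0.0)
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(labels=categories, values=values)


def average_linkage(sim: SimilarityMatrix) -> Dendrogram:
    """UPGMA agglomeration of ``d = 1 - s``.

    Inter-cluster distance is the unweighted mean over all leaf pairs,
    maintained with the size-weighted Lance-Williams update. Candidate merges
    with equal distance are resolved by the alphabetically smallest pair of
    cluster labels, so the tree is deterministic.
    """
    labels = list(sim.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two labels to cluster")
    dist = 1.0 - sim.values
    # active clusters: key = sorted leaf tuple
    clusters: dict[tuple[str, ...], dict] = {
        (lab,): {"size": 1, "height": 0.0, "children": None} for lab in labels
    }
    d: dict[frozenset[tuple[str, ...]], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = (labels[i],), (labels[j],)
            d[frozenset((a, b))] = dist[i, j]

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    while len(clusters) > 1:
        best = min(
            ((pair, h) for pair, h in d.items()),
            key=lambda ph: (ph[1], tuple(sorted(ph[0]))),
        )
        pair, height = best
        a, b = sorted(pair)
        merged = tuple(sorted(a + b))
        merges.append((a, b, height))
        size_a, size_b = clusters[a]["size"], clusters[b]["size"]
        new_entry = {"size": size_a + size_b, "height": height,
                     "children": (a, b)}
        for other in list(clusters):
            if other in (a, b):
                continue
            da = d.pop(frozenset((other, a)))
            db = d.pop(frozenset((other, b)))
            d[frozenset((other, merged))] = (size_a * da + size_b * db) / (
                size_a + size_b
            )
        d.pop(frozenset((a, b)))
        del clusters[a], clusters[b]
        clusters[merged] = new_entry

    # left-first traversal: at each internal node visit the alphabetically
    # smaller child first (merges already store (a, b) sorted)
    children = {tuple(sorted(a + b)): (a, b) for a, b, _ in merges}

    def walk(key: tuple[str, ...]) -> list[str]:
        if key not in children:
            return list(key)
        left, right = children[key]
        return walk(left) + walk(right)

    root = next(iter(clusters))
    return Dendrogram(merges=merges, leaf_order=walk(root))


def to_newick(dend: Dendrogram) -> str:
    """Newick serialization; branch lengths are merge-height differences."""
    heights = {(lab,): 0.0 for lab in dend.leaf_order}
    children: dict[tuple[str, ...], tuple] = {}
    for a, b, h in dend.merges:
        key = tuple(sorted(a + b))
        heights[key] = h
        children[key] = (a, b)
    root = max(children, key=len) if children else (dend.leaf_order[0],)

    def render(key: tuple[str, ...], parent_h: Optional[float]) -> str:
        if key in children:
            a, b = children[key]
            body = f"({render(a, heights[key])},{render(b, heights[key])})"
        else:
            body = key[0].replace(" ", "_")
        if parent_h is None:
            return body
        return f"{body}:{parent_h - heights[key]:.6f}"

    return render(root, None) + ";"


def clustered_heatmap_table(
    rel: pd.DataFrame,
    row_dend: Optional[Dendrogram] = None,
    col_dend: Optional[Dendrogram] = None,
    figure_path: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Permute a relative-frequency table by dendrogram leaf orders.

    Cell values are untouched — only row/column order changes. When
    ``figure_path`` is given, a sequential-colormap heatmap (brightest =
    highest frequency) is rendered headlessly.
    """
    out = rel
    if row_dend is not None:
        missing = set(row_dend.leaf_order) ^ set(rel.index)
        if missing:
            raise ValueError(f"row dendrogram labels do not match table rows: {sorted(missing)}")
        out = out.loc[row_dend.leaf_order]
    if col_dend is not None:
        missing = set(col_dend.leaf_order) ^ set(rel.columns)
        if missing:
            raise ValueError(f"column dendrogram labels do not match table columns: {sorted(missing)}")
        out = out[col_dend.leaf_order]
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4, 0.5 * out.shape[1] + 2), max(3, 0.3 * out.shape[0] + 1))
        )
        im = ax.imshow(out.values, aspect="auto", cmap="viridis")
        ax.set_xticks(range(out.shape[1]), out.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(out.shape[0]), out.index, fontsize=7)
        fig.colorbar(im, ax=ax, label="relative frequency")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return out


class UPGMAClustering(BaseEstimator):
    """Estimator wrapper: fit a similarity matrix, expose the merge tree.

    Attributes after ``fit``: ``dendrogram_``, ``merges_``, ``leaf_order_``.
    """

    def fit(self, X: SimilarityMatrix | pd.DataFrame, y=None):
        if isinstance(X, pd.DataFrame):
            X = SimilarityMatrix(labels=[str(c) for c in X.columns],
                                 values=X.values)
        self.dendrogram_ = average_linkage(X)
        self.merges_ = self.dendrogram_.merges
        self.leaf_order_ = self.dendrogram_.leaf_order
        return self
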