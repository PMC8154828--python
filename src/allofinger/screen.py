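"""Unsupervised segmentation of the feature space, scored by cluster purity.

Asks whether the activator/inhibitor split is directly visible in the
dynamic-fingerprint space: k-means and agglomerative (Ward) clustering are
run for k = 2..6 and each partition is scored by purity — the fraction of
items sitting in a cluster whose majority class is their own. Features are
standardised (per-column z-score) by default because columns mix score
units (kcal/mol) with geometric spread (nm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans


@dataclass
class PurityResult:
    """Contingency table and purity of one clustering."""

    algorithm: str
    k: int
    contingency: pd.DataFrame  # clusters x classes
    purity: float

    def contingency_json(self) -> str:
        return json.dumps(
            {str(c): row.to_dict() for c, row in self.contingency.iterrows()}
        )


def standardize(X: np.ndarray) -> np.ndarray:
    """Per-column z-score; constant columns map to zero."""
    X = np.asarray(X, float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _as_array(X) -> np.ndarray:
    if hasattr(X, "X"):  # FeatureMatrix
        X = X.X
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    return np.asarray(X, float)


def kmeans_segment(
    X, k: int, seed: int = 0, n_init: int = 10
) -> np.ndarray:
    """Lloyd's k-means with k-means++ seeding and ``n_init`` restarts."""
    A = _as_array(X)
    if k > A.shape[0]:
        raise ValueError(f"k={k} exceeds n={A.shape[0]}")
    if k < 1:
        raise ValueError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(A)


def hierarchical_segment(X, k: int, linkage: str = "ward") -> np.ndarray:
    """Agglomerative clustering on Euclidean distance, cut at ``k``."""
    A = _as_array(X)
    if k > A.shape[0]:
        raise ValueError(f"k={k} exceeds n={A.shape[0]}")
    model = AgglomerativeClustering(n_clusters=k, linkage=linkage)
    return model.fit_predict(A)


def purity(
    assignment: Sequence[int], labels: Sequence[str], algorithm: str = ""
) -> PurityResult:
    """Cluster purity: sum over clusters of the majority-class count, / n.

    1 means every cluster is single-class; the floor for any partition is
    the overall majority-class fraction.
    """
    assignment = np.asarray(assignment)
    labels = np.asarray(labels)
    if assignment.size == 0:
        raise ValueError("empty assignment")
    if assignment.shape != labels.shape:
        raise ValueError("assignment and labels lengths differ")
    tab = pd.crosstab(pd.Series(assignment, name="cluster"), pd.Series(labels, name="class"))
    p = float(tab.max(axis=1).sum() / len(labels))
    k = int(tab.shape[0])
    return PurityResult(algorithm, k, tab, p)


def purity_scan(
    X,
    labels: Sequence[str],
    k_range: Iterable[int] = range(2, 7),
    seed: int = 0,
    scale: bool = True,
    linkage: str = "ward",
) -> pd.DataFrame:
    """Purity of k-means and hierarchical clustering over ``k_range``.

    Returns a tidy table (algorithm, k, purity, contingency_json), one row
    per algorithm x k.
    """
    A = _as_array(X)
    if scale:
        A = standardize(A)
    rows = []
    for k in k_range:
        for algo, assign in (
            ("kmeans", kmeans_segment(A, k, seed=seed)),
            ("hierarchical", hierarchical_segment(A, k, linkage=linkage)),
        ):
            res = purity(assign, labels, algorithm=algo)
            rows.append(
                {
                    "algorithm": algo,
                    "k": k,
                    "purity": res.purity,
                    "contingency_json": res.contingency_json(),
                }
            )
    return pd.DataFrame(rows)
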