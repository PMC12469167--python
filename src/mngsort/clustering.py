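"""Unsupervised-clustering evaluation: the limitation analysis.

The traditional spike-sorting route — PCA features plus k-means — is
evaluated against the marking-method ground truth. k is fixed to the known
track count (which already flatters the clustering), the partition is
scored with the external validity indices ARI, NMI and V-measure, and a
component sweep (2..8 principal components) checks whether separability
hides in higher dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    v_measure_score,
)

from .features import FeatureMatrix, ParameterError, fit_pca


@dataclass(frozen=True)
class ClusterReport:
    """External validity indices of one k-means run against ground truth."""

    dataset: str
    feature_space: str
    k: int
    ari: float
    nmi: float
    v_measure: float
    seed: int

    def to_row(self) -> dict:
        return {
            "dataset": self.dataset,
            "feature_space": self.feature_space,
            "k": self.k,
            "ari": self.ari,
            "nmi": self.nmi,
            "v_measure": self.v_measure,
            "seed": self.seed,
        }


def _score(truth, pred, dataset, feature_space, k, seed) -> ClusterReport:
    return ClusterReport(
        dataset=dataset,
        feature_space=feature_space,
        k=k,
        ari=float(adjusted_rand_score(truth, pred)),
        nmi=float(normalized_mutual_info_score(truth, pred)),
        v_measure=float(v_measure_score(truth, pred)),
        seed=seed,
    )


def run_kmeans_eval(
    F: FeatureMatrix,
    k: int,
    truth=None,
    seed: int = 0,
    dataset: str = "",
) -> ClusterReport:
    """k-means (k-means++ init, 10 restarts) scored against ground truth.

    ``k`` must equal the number of distinct truth labels — the evaluation
    asks how well clustering recovers the *known* tracks, not how many
    there are. ``truth`` defaults to the matrix's own labels.
    """
    truth = np.asarray(F.labels if truth is None else truth)
    X = np.asarray(F.X, dtype=np.float64)
    if len(truth) != len(X):
        raise ParameterError("truth labels must align with feature rows")
    n_classes = len(np.unique(truth))
    if k != n_classes:
        raise ParameterError(f"k={k} does not match {n_classes} distinct labels")
    if len(X) <= k:
        raise ParameterError("need more spikes than clusters")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    pred = km.fit_predict(X)
    return _score(truth, pred, dataset, F.feature_set, k, seed)


def pca_component_sweep(
    raw: FeatureMatrix,
    truth=None,
    comps=range(2, 9),
    seed: int = 0,
    dataset: str = "",
) -> pd.DataFrame:
    """k-means indices for increasing PCA component counts of W_raw.

    One row per component count with ARI/NMI/V-measure and the cumulative
    explained variance at that count.
    """
    truth = np.asarray(raw.labels if truth is None else truth)
    X = np.asarray(raw.X, dtype=np.float64)
    k = len(np.unique(truth))
    rows = []
    for n_comp in comps:
        model, scores = fit_pca(X, n_comp)
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
        pred = km.fit_predict(scores)
        rep = _score(truth, pred, dataset, f"W_raw+PCA{n_comp}", k, seed)
        row = rep.to_row()
        row["n_components"] = n_comp
        row["cumulative_explained_variance"] = float(
            np.sum(model.explained_variance_ratio)
        )
        rows.append(row)
    return pd.DataFrame(rows)
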