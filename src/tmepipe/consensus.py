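"""Resampling-based consensus clustering with CDF-area selection of K
(Monti-style).

Items (samples, or genes for the gene-cluster runs) are subsampled repeatedly;
a base clustering is run on every resample; consensus_ij is the fraction of
co-samplings in which i and j co-clustered.  The area under the CDF of the
consensus entries grows with K; the relative-increase elbow rule picks K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .io_core import ValidationError

logger = logging.getLogger("tmepipe")


@dataclass
class ConsensusResult:
    consensus: dict[int, np.ndarray]   # K -> items x items consensus matrix
    labels: dict[int, np.ndarray]      # K -> final labels (1..K)
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int
    item_ids: list
    n_resamples: int
    seed: int

    @property
    def final_labels(self) -> pd.Series:
        return pd.Series(self.labels[self.chosen_k], index=self.item_ids,
                         name="cluster")


def _base_cluster(X: np.ndarray, k: int, method: str, rng,
                  n_init: int = 1) -> np.ndarray:
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=n_init, init="k-means++",
                    random_state=int(rng.integers(2**31)))
        return km.fit_predict(X)
    if method == "hierarchical":
        Z = linkage(X, method="ward")
        return fcluster(Z, k, criterion="maxclust")
    raise ValidationError(f"unknown base clustering {method!r}")


def cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the upper-triangle consensus entries."""
    n = consensus.shape[0]
    vals = np.sort(consensus[np.triu_indices(n, k=1)])
    if len(vals) == 0:
        return 0.0
    xs = np.concatenate([[0.0], vals, [1.0]])
    cdf = np.concatenate([[0.0], np.arange(1, len(vals) + 1) / len(vals), [1.0]])
    return float(np.sum(np.diff(xs) * cdf[:-1]))


def select_k(areas: dict[int, float], threshold: float = 0.1) -> int:
    """Elbow rule on relative CDF-area increase.

    delta(K) = (A(K) - A(K-1)) / A(K-1) for K > K_min; delta(K_min) = A(K_min).
    Chosen K = the largest K whose delta exceeds ``threshold``; if none does,
    the smallest K.  Ties break toward smaller K by construction.
    """
    ks = sorted(areas)
    if len(ks) == 1:
        logger.warning("select_k: single K supplied; returning it")
        return ks[0]
    deltas = {}
    for i, k in enumerate(ks):
        if i == 0:
            deltas[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else np.inf
    logger.info("select_k deltas: %s", {k: round(v, 4) for k, v in deltas.items()})
    passing = [k for k in ks if deltas[k] > threshold]
    return max(passing) if passing else ks[0]


def consensus_cluster(
    features,
    k_range=range(2, 7),
    n_resamples: int = 1000,
    subsample: float = 0.8,
    base: str = "kmeans",
    seed: int = 0,
    delta_threshold: float = 0.1,
    linkage_method: str = "average",
    n_init: int = 1,
) -> ConsensusResult:
    """Consensus clustering of the rows of ``features``.

    Final labels per K come from hierarchical clustering (``linkage_method``)
    of 1 - consensus; chosen K from :func:`select_k`.  The K-means base runs
    a single k-means++ start per resample (``n_init``): the CDF-area elbow
    relies on over-split solutions being irreproducible across resamples,
    and best-of-many restarts makes spurious splits artificially stable.
    """
    if isinstance(features, pd.DataFrame):
        item_ids = list(features.index)
        X = features.to_numpy(float)
    else:
        X = np.asarray(features, float)
        item_ids = list(range(X.shape[0]))
    n = X.shape[0]
    if n < 10:
        raise ValidationError("consensus clustering needs >= 10 items")
    if not np.isfinite(X).all():
        raise ValidationError("features must be finite")
    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample * n)))
    consensus, labels, areas = {}, {}, {}
    for k in k_range:
        if k >= n:
            logger.warning("skipping K=%d >= n_items=%d", k, n)
            continue
        hits = np.zeros((n, n))
        pairs = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = rng.choice(n, m, replace=False) if m < n else np.arange(n)
            lab = _base_cluster(X[idx], k, base, rng, n_init=n_init)
            sel = np.zeros(n, bool)
            sel[idx] = True
            co = np.zeros(n, dtype=int)
            co[idx] = lab
            same = (co[:, None] == co[None, :]) & sel[:, None] & sel[None, :]
            pairs += np.outer(sel, sel)
            hits += same
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.where(pairs > 0, hits / np.maximum(pairs, 1), 0.0)
        if (pairs[np.triu_indices(n, 1)] == 0).any():
            logger.warning("K=%d: some item pairs never co-sampled; entries set to 0", k)
        np.fill_diagonal(C, 1.0)
        C = (C + C.T) / 2
        consensus[k] = C
        D = 1.0 - C
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform(D, checks=False), method=linkage_method)
        labels[k] = fcluster(Z, k, criterion="maxclust")
        areas[k] = cdf_area(C)
    if not consensus:
        raise ValidationError("no K in k_range was usable")
    chosen = select_k(areas, delta_threshold)
    ks = sorted(areas)
    deltas = {ks[0]: areas[ks[0]]}
    for i in range(1, len(ks)):
        prev = areas[ks[i - 1]]
        deltas[ks[i]] = (areas[ks[i]] - prev) / prev if prev > 0 else np.inf
    return ConsensusResult(
        consensus=consensus, labels=labels, cdf_area=areas, delta_area=deltas,
        chosen_k=chosen, item_ids=item_ids, n_resamples=n_resamples, seed=seed,
    )
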