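"""TME gene-signature construction and the TME score.

The common DEGs are reduced to signature genes by random-forest permutation
importance, grouped into gene clusters by consensus clustering, each cluster
is scored per sample by the first principal component of its z-scored
expression block, clusters are labelled favourable/unfavourable by univariate
Cox regression of the cluster score on overall survival, and

    TME score = sum(favourable cluster scores) - sum(unfavourable cluster scores).

The score is dichotomized at the maximally selected rank statistic: the
candidate cutpoint (within an inner quantile range) that maximizes the
absolute standardized two-group log-rank statistic, with a permutation
p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .consensus import ConsensusResult, consensus_cluster
from .io_core import ClinicalTable, ExpressionMatrix, ValidationError
from .survival import cox_fit, logrank_z_cuts

logger = logging.getLogger("tmepipe")


def rf_reduce(
    expr: ExpressionMatrix,
    cluster_labels: pd.Series,
    n_trees: int = 1000,
    seed: int = 0,
    importance: str = "gini",
    n_repeats: int = 5,
) -> pd.DataFrame:
    """Random-forest dimension reduction of the common DEGs.

    Trains a classifier (genes as features, TME cluster as label), ranks genes
    by importance, keeps genes with importance above the mean.  The default
    ranking is the forest's mean Gini impurity decrease, which distributes
    mass across redundant co-informative genes; ``importance="permutation"``
    ranks by permutation importance instead, but degenerates to all-zero
    scores when many genes are interchangeable predictors.  Returns the full
    importance table with a ``kept`` flag, importance-sorted.
    """
    common = [s for s in cluster_labels.index if s in expr.values.columns]
    y = cluster_labels.loc[common]
    if y.nunique() < 2:
        raise ValidationError("rf_reduce needs >= 2 classes")
    if expr.shape[0] < 10:
        raise ValidationError("rf_reduce needs >= 10 genes")
    X = expr.values[common].T.to_numpy(float)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, y.to_numpy())
    if importance == "gini":
        imp = rf.feature_importances_
    elif importance == "permutation":
        imp = permutation_importance(
            rf, X, y.to_numpy(), n_repeats=n_repeats, random_state=seed, n_jobs=1
        ).importances_mean
    else:
        raise ValidationError(f"unknown importance rule {importance!r}")
    table = pd.DataFrame({"importance": imp}, index=expr.values.index)
    table["kept"] = table["importance"] > table["importance"].mean()
    logger.info("rf_reduce: kept %d of %d genes", int(table["kept"].sum()), len(table))
    return table.sort_values("importance", ascending=False)


def cluster_signature_genes(
    expr: ExpressionMatrix,
    genes: list[str],
    k_range=range(2, 6),
    n_resamples: int = 200,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus-cluster the signature genes on their z-scored profiles."""
    sub = expr.values.loc[[g for g in genes if g in expr.values.index]]
    Z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1).replace(0, 1.0), axis=0)
    return consensus_cluster(Z, k_range=k_range, n_resamples=n_resamples, seed=seed)


@dataclass
class GeneClusterSet:
    """Gene-cluster membership, per-sample PC1 scores and prognostic directions."""

    gene_cluster: pd.Series         # gene -> cluster id
    scores: pd.DataFrame            # samples x clusters (PC1 projections)
    explained: dict[int, float]     # PC1 explained-variance ratio per cluster
    directions: dict[int, str] | None = None   # favourable / unfavourable
    cox_hr: dict[int, float] | None = None


def score_gene_clusters(
    expr: ExpressionMatrix, gene_cluster: pd.Series
) -> GeneClusterSet:
    """Per-cluster per-sample signature score: PC1 of the z-scored gene block.

    The PC1 sign is fixed so the loading sum is non-negative, preventing
    run-to-run sign flips; z-scored input makes every score vector zero-mean.
    """
    scores = {}
    explained = {}
    for c in sorted(gene_cluster.unique()):
        genes = [g for g in gene_cluster.index[gene_cluster == c]
                 if g in expr.values.index]
        block = expr.values.loc[genes]
        Z = block.sub(block.mean(axis=1), axis=0)
        sd = block.std(axis=1).replace(0, 1.0)
        Z = Z.div(sd, axis=0).to_numpy(float)          # genes x samples
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        load = U[:, 0]
        if load.sum() < 0:
            load = -load
            Vt = -Vt
        scores[c] = S[0] * Vt[0]
        tot = (S**2).sum()
        explained[c] = float(S[0] ** 2 / tot) if tot > 0 else 1.0
    return GeneClusterSet(
        gene_cluster=gene_cluster,
        scores=pd.DataFrame(scores, index=expr.values.columns),
        explained=explained,
    )


def assign_directions(
    clusters: GeneClusterSet, clinical: ClinicalTable
) -> GeneClusterSet:
    """Label each gene cluster favourable (Cox HR < 1) or unfavourable."""
    common = [s for s in clusters.scores.index if s in clinical.table.index]
    if not common:
        raise ValidationError("no overlap between score samples and clinical table")
    t = clinical.table.loc[common, "os_time"].to_numpy(float)
    e = clinical.table.loc[common, "os_event"].to_numpy(int)
    directions, hrs = {}, {}
    for c in clusters.scores.columns:
        x = clusters.scores.loc[common, c].to_numpy(float)
        x = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
        fit = cox_fit(t, e, x[:, None])
        hr = float(fit.hr[0])
        directions[c] = "favourable" if hr < 1 else "unfavourable"
        hrs[c] = hr
    clusters.directions = directions
    clusters.cox_hr = hrs
    return clusters


def compute_tme_score(
    clusters: GeneClusterSet, directions: dict | None = None
) -> pd.Series:
    """score_s = sum of favourable cluster scores - sum of unfavourable ones."""
    directions = directions or clusters.directions
    if directions is None:
        raise ValidationError(
            "directions required: call assign_directions or supply explicitly"
        )
    score = pd.Series(0.0, index=clusters.scores.index, name="tme_score")
    for c in clusters.scores.columns:
        sign = 1.0 if directions[c] == "favourable" else -1.0
        score += sign * clusters.scores[c]
    return score


@dataclass
class TMEScoreResult:
    score: pd.Series
    cutpoint: float
    group: pd.Series            # "high" / "low"
    statistic: float            # max |standardized log-rank|
    permutation_p: float
    per_cutpoint: pd.DataFrame  # candidate cutpoints with their statistics


def maxstat_cutpoint(
    score,
    os_time,
    os_event,
    quantile_range: tuple = (0.1, 0.9),
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float, pd.DataFrame]:
    """Maximally selected rank statistic.

    Candidates are the observed score values inside the quantile range; for
    each, the standardized two-group log-rank statistic of the score > cut
    split; the cutpoint is the argmax of |statistic| (ties -> smaller value).
    p by permuting scores against the (time, event) pairs.
    """
    score = np.asarray(score, float)
    os_time = np.asarray(os_time, float)
    os_event = np.asarray(os_event, int)
    if len(score) < 20 or os_event.sum() < 5:
        raise ValidationError("maxstat needs >= 20 samples with >= 5 events")
    lo, hi = np.quantile(score, quantile_range)
    cands = np.unique(score[(score >= lo) & (score <= hi)])
    # a cut at the maximum would leave an empty "high" group
    cands = cands[cands < score.max()]
    if len(cands) == 0:
        raise ValidationError("no candidate cutpoints in the quantile range")

    obs = np.abs(logrank_z_cuts(os_time, os_event, score, cands))
    best = int(np.argmax(obs))  # first max -> smallest cutpoint on ties
    cutpoint = float(cands[best])
    statistic = float(obs[best])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(score)
        pc = np.unique(perm[(perm >= lo) & (perm <= hi)])
        pc = pc[pc < perm.max()]
        m = np.abs(logrank_z_cuts(os_time, os_event, perm, pc)).max()
        if m >= statistic:
            count += 1
    p = (1 + count) / (1 + n_perm)
    table = pd.DataFrame({"cutpoint": cands, "abs_statistic": obs})
    return cutpoint, statistic, p, table


def dichotomize(
    score: pd.Series, clinical: ClinicalTable,
    quantile_range: tuple = (0.1, 0.9), n_perm: int = 1000, seed: int = 0,
) -> TMEScoreResult:
    common = [s for s in score.index if s in clinical.table.index]
    s = score.loc[common]
    cut, stat, p, table = maxstat_cutpoint(
        s.to_numpy(), clinical.table.loc[common, "os_time"],
        clinical.table.loc[common, "os_event"],
        quantile_range=quantile_range, n_perm=n_perm, seed=seed,
    )
    group = pd.Series(np.where(score > cut, "high", "low"), index=score.index,
                      name="tme_group")
    return TMEScoreResult(score=score, cutpoint=cut, group=group,
                          statistic=stat, permutation_p=p, per_cutpoint=table)
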