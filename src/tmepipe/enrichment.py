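"""Gene-set enrichment: hypergeometric over-representation analysis on any
GMT collection, and weighted running-sum GSEA between two phenotype groups."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import ExpressionMatrix, GeneSetCollection, ValidationError, normalize_gene_id

logger = logging.getLogger("tmepipe")


def ora(
    query: list[str], sets: GeneSetCollection, universe: list[str]
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per gene set, BH-corrected
    across sets.  Set members outside the universe are ignored."""
    uni = {normalize_gene_id(g) for g in universe}
    q = {normalize_gene_id(g) for g in query} & uni
    if not q:
        raise ValidationError("query has no genes inside the universe")
    rows = []
    for name, genes in sets.sets.items():
        members = {normalize_gene_id(g) for g in genes} & uni
        overlap = len(q & members)
        # P(X >= overlap), X ~ Hypergeom(N=|uni|, K=|members|, n=|q|)
        p = stats.hypergeom.sf(overlap - 1, len(uni), len(members), len(q))
        rows.append({
            "set": name, "overlap": overlap, "set_size": len(members),
            "query_size": len(q), "universe_size": len(uni), "p": float(p),
        })
    out = pd.DataFrame(rows).set_index("set")
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("p")


def rank_genes(
    expr: ExpressionMatrix, groups: pd.Series, metric: str = "signal_to_noise"
) -> pd.Series:
    """Ranking metric between two groups (positive = up in the first label)."""
    g = pd.Series(groups)
    labels = list(pd.unique(g))
    if len(labels) != 2:
        raise ValidationError("ranking needs exactly 2 groups")
    a = [s for s in g[g == labels[0]].index if s in expr.values.columns]
    b = [s for s in g[g == labels[1]].index if s in expr.values.columns]
    Xa = expr.values[a].to_numpy(float)
    Xb = expr.values[b].to_numpy(float)
    if metric == "signal_to_noise":
        sa = np.maximum(Xa.std(1, ddof=1), 0.2 * np.abs(Xa.mean(1)))
        sb = np.maximum(Xb.std(1, ddof=1), 0.2 * np.abs(Xb.mean(1)))
        sa = np.maximum(sa, 1e-8)
        sb = np.maximum(sb, 1e-8)
        m = (Xa.mean(1) - Xb.mean(1)) / (sa + sb)
    elif metric == "mean_diff":
        m = Xa.mean(1) - Xb.mean(1)
    else:
        raise ValidationError(f"unknown ranking metric {metric!r}")
    return pd.Series(m, index=expr.values.index).sort_values(ascending=False)


def enrichment_score(ranked: pd.Series, members: set, weight: float = 1.0) -> float:
    """Subramanian weighted Kolmogorov-Smirnov running-sum enrichment score."""
    genes = [normalize_gene_id(g) for g in ranked.index]
    r = np.abs(ranked.to_numpy(float)) ** weight
    inset = np.array([g in members for g in genes])
    nh = int(inset.sum())
    n = len(genes)
    if nh == 0 or nh == n:
        raise ValidationError("gene set empty or equal to the ranked universe")
    nr = r[inset].sum()
    if nr == 0:
        return 0.0
    step = np.where(inset, r / nr, -1.0 / (n - nh))
    run = np.cumsum(step)
    i = int(np.argmax(np.abs(run)))
    return float(run[i])


def gsea(
    ranked: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """GSEA over a pre-ranked list with gene-label permutation p-values.

    NES normalizes each ES by the mean |permuted ES| of matching sign.
    """
    rng = np.random.default_rng(seed)
    genes = [normalize_gene_id(g) for g in ranked.index]
    gene_set_all = set(genes)
    rows = []
    for name, members_raw in sets.sets.items():
        members = {normalize_gene_id(g) for g in members_raw} & gene_set_all
        if not members or len(members) == len(genes):
            logger.warning("gsea: set %s skipped (no usable members)", name)
            continue
        es = enrichment_score(ranked, members, weight)
        k = len(members)
        perm_es = np.empty(n_perm)
        for i in range(n_perm):
            rand = set(rng.choice(len(genes), k, replace=False))
            memb = {genes[j] for j in rand}
            perm_es[i] = enrichment_score(ranked, memb, weight)
        same = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        if len(same) == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.nan
        else:
            p = (1 + np.sum(np.abs(same) >= abs(es))) / (1 + len(same))
            nes = es / np.mean(np.abs(same))
        rows.append({"set": name, "size": k, "es": es, "nes": float(nes),
                     "p": float(p)})
    out = pd.DataFrame(rows).set_index("set")
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("p")
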