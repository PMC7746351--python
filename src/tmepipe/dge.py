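"""Expression filtering, log-CPM (voom-style) transformation and empirical-
Bayes moderated-t differential expression between infiltration-pattern
clusters.

The moderated t shrinks each gene's pooled residual variance s_g^2 (d_g df)
toward a prior s0^2 with d0 prior df estimated by method-of-moments on
log s_g^2 (Smyth 2004); the posterior variance is
(d0 s0^2 + d_g s_g^2) / (d0 + d_g) and the statistic has d0 + d_g df.
Significance uses the raw-p rule p < 1e-3 and |log2FC| > 1; BH-FDR is
reported as an informational column only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_core import ExpressionMatrix, ValidationError

logger = logging.getLogger("tmepipe")

P_THRESHOLD = 1e-3
LFC_THRESHOLD = 1.0


def filter_low_expression(
    counts: ExpressionMatrix, min_count: float = 10, min_samples_frac: float = 0.2
) -> ExpressionMatrix:
    """Keep genes with >= min_count in >= min_samples_frac of samples
    (boundaries inclusive); gene order preserved."""
    if counts.unit != "counts":
        raise ValidationError("filter_low_expression expects raw counts")
    frac = (counts.values >= min_count).mean(axis=1)
    keep = frac >= min_samples_frac
    logger.info("filter_low_expression: kept %d of %d genes", keep.sum(), len(keep))
    return ExpressionMatrix(counts.values.loc[keep], unit="counts")


def voom_transform(
    counts: ExpressionMatrix, weights: bool = False
) -> ExpressionMatrix | tuple[ExpressionMatrix, pd.DataFrame]:
    """log2-CPM with the voom offsets: log2((count + 0.5) / (libsize + 1) * 1e6).

    With ``weights=True``, observation-level precision weights are returned
    from a lowess fit of sqrt residual SD against mean log2 count.
    """
    if counts.unit != "counts":
        raise ValidationError("voom_transform expects raw counts")
    C = counts.values.to_numpy(float)
    lib = C.sum(axis=0)
    logcpm = np.log2((C + 0.5) / (lib + 1.0)[None, :] * 1e6)
    out = ExpressionMatrix(
        pd.DataFrame(logcpm, index=counts.values.index, columns=counts.values.columns),
        unit="logcpm",
    )
    if not weights:
        return out
    from statsmodels.nonparametric.smoothers_lowess import lowess

    mean_lcount = np.log2(C.mean(axis=1) + 0.5)
    resid_sd = logcpm.std(axis=1, ddof=1)
    sqrt_sd = np.sqrt(np.maximum(resid_sd, 0))
    fit = lowess(sqrt_sd, mean_lcount, frac=0.5, return_sorted=True)
    # interpolate the mean-variance trend at each observation's fitted log-count
    fitted_lcount = np.log2((C + 0.5) / (lib + 1.0)[None, :] * 1e6) \
        + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    trend = np.interp(fitted_lcount, fit[:, 0], fit[:, 1])
    w = 1.0 / np.maximum(trend, 1e-6) ** 4
    return out, pd.DataFrame(w, index=counts.values.index, columns=counts.values.columns)


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (limma's trigammaInverse)."""
    x = np.asarray(x, float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(-dif / y) < 1e-8:
            break
    return y


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on log s_g^2.

    Returns (d0, s0sq); d0 = inf when the residual spread of log s^2 is no
    larger than expected from chi-square sampling alone.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2)
    if evar <= 0:
        d0 = np.inf
        s0sq = float(s2[ok].mean())
    else:
        d0 = float(2 * _trigamma_inverse(np.array([evar]))[0])
        s0sq = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0sq


@dataclass
class DGEResult:
    """Per-gene moderated-t results for one two-group contrast."""

    table: pd.DataFrame        # log2fc, mean_expr, t, p, fdr, significant
    contrast: tuple
    d0: float
    s0sq: float

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def moderated_t(
    expr: ExpressionMatrix,
    groups: pd.Series | np.ndarray,
    contrast: tuple | None = None,
    force_d0: float | None = None,
    p_threshold: float = P_THRESHOLD,
    lfc_threshold: float = LFC_THRESHOLD,
) -> DGEResult:
    """Moderated two-sample t-test per gene between two group labels.

    log2FC is group_a minus group_b on the (assumed log2) expression scale.
    ``force_d0`` pins the prior df (0 recovers the ordinary pooled t).
    """
    g = pd.Series(groups)
    labels = list(pd.unique(g))
    if contrast is None:
        if len(labels) != 2:
            raise ValidationError("groups must have exactly 2 labels or pass contrast")
        contrast = (labels[0], labels[1])
    a, b = contrast
    X = expr.values
    ga = g[g == a].index
    gb = g[g == b].index
    ga = [s for s in ga if s in X.columns]
    gb = [s for s in gb if s in X.columns]
    if len(ga) < 2 or len(gb) < 2:
        raise ValidationError("need >= 2 samples per group")
    Xa = X[ga].to_numpy(float)
    Xb = X[gb].to_numpy(float)
    na, nb = Xa.shape[1], Xb.shape[1]
    ma, mb = Xa.mean(1), Xb.mean(1)
    lfc = ma - mb
    va = Xa.var(1, ddof=1)
    vb = Xb.var(1, ddof=1)
    df_g = na + nb - 2
    s2 = ((na - 1) * va + (nb - 1) * vb) / df_g
    if force_d0 is None:
        d0, s0sq = estimate_prior(s2, df_g)
    else:
        d0 = force_d0
        _, s0sq = estimate_prior(s2, df_g)
    zero_var = s2 == 0
    if zero_var.any():
        logger.info("moderated_t: %d zero-variance genes", int(zero_var.sum()))
    # total df capped at the pooled residual df over all genes (limma convention)
    df_cap = len(s2) * df_g
    if np.isinf(d0):
        post = np.full_like(s2, s0sq)
        df_total = df_cap
    elif d0 == 0:
        post = s2.copy()
        df_total = df_g
        if zero_var.any():  # floor via the prior so the statistic is defined
            post[zero_var] = s0sq if s0sq > 0 else 1e-12
    else:
        post = (d0 * s0sq + df_g * s2) / (d0 + df_g)
        df_total = min(d0 + df_g, df_cap)
    sed = np.sqrt(post * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sed > 0, lfc / sed, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df_total)
    p = np.where(zero_var & (lfc == 0), 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({
        "log2fc": lfc,
        "mean_expr": (ma * na + mb * nb) / (na + nb),
        "t": t,
        "p": p,
        "fdr": fdr,
        "significant": (p < p_threshold) & (np.abs(lfc) > lfc_threshold),
    }, index=X.index)
    return DGEResult(table=table, contrast=(a, b), d0=float(d0), s0sq=float(s0sq))


def pairwise_contrasts(
    expr: ExpressionMatrix, groups: pd.Series, **kwargs
) -> dict[tuple, DGEResult]:
    """One-vs-one moderated-t for every pair of cluster labels."""
    labels = sorted(pd.unique(pd.Series(groups)))
    out = {}
    for a, b in combinations(labels, 2):
        out[(a, b)] = moderated_t(expr, groups, contrast=(a, b), **kwargs)
    return out


def deg_intersection(
    results: dict[tuple, DGEResult], rule: str = "two"
) -> list[str]:
    """Common DEG list across contrasts.

    rule="any": significant in >= 1 contrast; "two": >= 2 (default);
    "all": in every contrast.
    """
    need = {"any": 1, "two": 2, "all": len(results)}.get(rule)
    if need is None:
        raise ValidationError(f"unknown common-DEG rule {rule!r}")
    counts: dict[str, int] = {}
    order: list[str] = []
    for res in results.values():
        for gene in res.significant_genes:
            if gene not in counts:
                counts[gene] = 0
                order.append(gene)
            counts[gene] += 1
    return [g for g in order if counts[g] >= need]
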