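"""Immune-cell deconvolution of bulk expression against an LM22-style
reference by nu-support-vector regression (the CIBERSORT algorithm,
reimplemented).

Per sample: the mixture and the reference are restricted to their common
genes and standardized (the reference jointly over all its entries, the
mixture per sample), a linear-kernel nu-SVR is fitted for nu in
{0.25, 0.5, 0.75}, the nu minimizing the RMSE between fitted and observed
mixture wins, negative coefficients are clipped to zero and the rest
normalized onto the simplex.  The permutation p-value compares each sample's
fit correlation against a shared null built from random gene-shuffled
mixtures.

Input must be on the linear (non-log) scale; quantile normalization of the
mixture is off by default, as recommended for RNA-seq.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import NuSVR

from .io_core import ExpressionMatrix, SignatureMatrixRef, ValidationError, normalize_gene_id

logger = logging.getLogger("tmepipe")

NUS = (0.25, 0.5, 0.75)


@dataclass
class CellFractions:
    fractions: pd.DataFrame    # samples x cell types, simplex rows
    rmse: pd.Series
    pearson_r: pd.Series
    permutation_p: pd.Series
    n_permutations: int
    degenerate: pd.Series      # all-zero coefficient fits flagged

    def __post_init__(self) -> None:
        f = self.fractions.to_numpy()
        if (f < -1e-12).any():
            raise ValidationError("negative cell fractions")
        sums = f.sum(axis=1)
        ok = np.isclose(sums, 1.0, atol=1e-9) | self.degenerate.to_numpy()
        if not ok.all():
            raise ValidationError("fraction rows must sum to 1")


def _quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    ranks = df.rank(method="first").astype(int) - 1
    means = np.sort(df.to_numpy(), axis=0).mean(axis=1)
    return pd.DataFrame(means[ranks.to_numpy()], index=df.index, columns=df.columns)


def _fit_sample(Xs: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Nu-selection SVR fit on standardized system; returns (clipped coefs,
    rmse, pearson r of fitted vs observed)."""
    best = None
    for nu in NUS:
        model = NuSVR(kernel="linear", nu=nu, C=1.0)
        model.fit(Xs, y)
        w = model.coef_.ravel().copy()
        w[w < 0] = 0.0
        fitted = Xs @ w
        rmse = float(np.sqrt(np.mean((fitted - y) ** 2)))
        if best is None or rmse < best[1]:
            r = stats.pearsonr(fitted, y)[0] if np.std(fitted) > 0 else 0.0
            best = (w, rmse, float(r))
    return best


def deconvolve(
    mixture: ExpressionMatrix,
    reference: SignatureMatrixRef,
    n_permutations: int = 1000,
    seed: int = 0,
    quantile_norm: bool = False,
) -> CellFractions:
    """Estimate cell-type fractions for every sample of ``mixture``."""
    mix = mixture.values.copy()
    mix.index = [normalize_gene_id(g) for g in mix.index]
    ref = reference.values.copy()
    ref.index = [normalize_gene_id(g) for g in ref.index]
    common = [g for g in ref.index if g in set(mix.index)]
    frac_found = len(common) / len(ref.index)
    if frac_found < 0.5:
        raise ValidationError(
            f"only {frac_found:.0%} of reference genes found in mixture (< 50%)"
        )
    if mix.to_numpy().max() < 50:
        logger.warning("mixture maximum < 50 — input looks log-scale; "
                       "deconvolution expects linear scale")
    if quantile_norm:
        mix = _quantile_normalize(mix)
    X = ref.loc[common].to_numpy(float)
    Y = mix.loc[common].to_numpy(float)
    # reference standardized jointly; each mixture column on its own stats
    Xs = (X - X.mean()) / X.std()
    rng = np.random.default_rng(seed)

    samples = list(mix.columns)
    k = X.shape[1]
    fractions = np.zeros((len(samples), k))
    rmse = np.zeros(len(samples))
    rvals = np.zeros(len(samples))
    degenerate = np.zeros(len(samples), bool)
    for j, s in enumerate(samples):
        y = Y[:, j]
        sd = y.std()
        y = (y - y.mean()) / (sd if sd > 0 else 1.0)
        w, rm, r = _fit_sample(Xs, y)
        rmse[j] = rm
        rvals[j] = r
        if w.sum() <= 0:
            degenerate[j] = True
            fractions[j] = 1.0 / k
            logger.warning("degenerate all-zero fit for sample %s; uniform fractions", s)
        else:
            fractions[j] = w / w.sum()

    # shared permutation null of fit correlations
    flat = mix.to_numpy().ravel()
    null_r = np.empty(n_permutations)
    for i in range(n_permutations):
        y = flat[rng.integers(0, len(flat), len(common))].astype(float)
        sd = y.std()
        y = (y - y.mean()) / (sd if sd > 0 else 1.0)
        _, _, r = _fit_sample(Xs, y)
        null_r[i] = r
    if n_permutations > 0:
        pvals = np.array([(null_r >= r).mean() for r in rvals])
    else:
        pvals = np.full(len(samples), np.nan)

    idx = pd.Index(samples, name="sample")
    return CellFractions(
        fractions=pd.DataFrame(fractions, index=idx, columns=reference.cell_type_names),
        rmse=pd.Series(rmse, index=idx, name="rmse"),
        pearson_r=pd.Series(rvals, index=idx, name="pearson_r"),
        permutation_p=pd.Series(pvals, index=idx, name="permutation_p"),
        n_permutations=n_permutations,
        degenerate=pd.Series(degenerate, index=idx, name="degenerate"),
    )
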