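"""Survival statistics implemented from first principles: Kaplan-Meier
product-limit curves, the log-rank test, Cox proportional hazards with Breslow
tie handling, the tumor-immune cell interaction network, and ROC/AUC with the
DeLong paired comparison.

The Cox score test evaluated at beta = 0 for a two-group 0/1 covariate equals
the log-rank chi-square exactly under the Breslow convention — a classical
identity the test suite asserts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ClinicalTable, ValidationError

logger = logging.getLogger("tmepipe")


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit estimate for one group."""

    times: np.ndarray          # distinct event times (ascending)
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # risk-set size just before each event time
    n_events: np.ndarray       # events at each time
    censor_times: np.ndarray   # times of censored observations


def km_fit(time, event, groups=None) -> dict[object, KMCurve]:
    """Kaplan-Meier curves, one per group (single pseudo-group if None)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if groups is None:
        groups = np.zeros(len(time), int)
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        m = groups == g
        t, e = time[m], event[m]
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        ev_times = np.unique(t[e == 1])
        surv, risk, nev = [], [], []
        s = 1.0
        for et in ev_times:
            n_risk = int((t >= et).sum())
            d = int(((t == et) & (e == 1)).sum())
            s *= 1.0 - d / n_risk
            surv.append(s)
            risk.append(n_risk)
            nev.append(d)
        out[g] = KMCurve(
            times=ev_times,
            survival=np.array(surv),
            at_risk=np.array(risk, int),
            n_events=np.array(nev, int),
            censor_times=np.sort(t[e == 0]),
        )
    return out


def _logrank_tables(time, event, groups):
    """Observed and expected event counts and hypergeometric variance terms
    per distinct event time, for k groups pooled."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    k = len(labels)
    ev_times = np.unique(time[event == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    # covariance matrix of (O-E) over the first k-1 groups
    V = np.zeros((k, k))
    for et in ev_times:
        at_risk = time >= et
        n = at_risk.sum()
        d = int(((time == et) & (event == 1)).sum())
        for i, g in enumerate(labels):
            ni = int((at_risk & (groups == g)).sum())
            di = int(((time == et) & (event == 1) & (groups == g)).sum())
            O[i] += di
            E[i] += d * ni / n
        if n > 1:
            for i, gi in enumerate(labels):
                ni = int((at_risk & (groups == gi)).sum())
                for j, gj in enumerate(labels):
                    nj = int((at_risk & (groups == gj)).sum())
                    same = 1.0 if i == j else 0.0
                    V[i, j] += d * (ni / n) * (same - nj / n) * (n - d) / (n - 1)
    return labels, O, E, V


def logrank_test(time, event, groups) -> tuple[float, int, float]:
    """k-sample log-rank test; returns (chi2, df, p).

    Tied event times are handled by the simultaneous-event (hypergeometric)
    convention.
    """
    labels, O, E, V = _logrank_tables(time, event, groups)
    k = len(labels)
    if k < 2:
        raise ValidationError("log-rank needs >= 2 groups")
    z = (O - E)[: k - 1]
    Vk = V[: k - 1, : k - 1]
    try:
        chi2 = float(z @ np.linalg.solve(Vk, z))
    except np.linalg.LinAlgError:
        chi2 = 0.0
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def logrank_z(time, event, binary_groups) -> float:
    """Standardized two-group log-rank statistic (O-E)/sqrt(V), signed so a
    positive value means the second (True/1) group has more events than
    expected."""
    groups = np.asarray(binary_groups).astype(int)
    labels, O, E, V = _logrank_tables(time, event, groups)
    i = int(np.flatnonzero(labels == 1)[0]) if 1 in labels else 0
    v = V[i, i]
    if v <= 0:
        return 0.0
    return float((O[i] - E[i]) / np.sqrt(v))


def logrank_z_cuts(time, event, score, cutpoints) -> np.ndarray:
    """Standardized two-group log-rank statistic for every threshold split
    ``score > c`` over an array of candidate cutpoints, vectorized.

    Equivalent to calling :func:`logrank_z` per cutpoint; used by the
    maximally-selected-rank-statistic search where thousands of splits are
    evaluated.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    score = np.asarray(score, float)
    cutpoints = np.asarray(cutpoints, float)
    ev_times = np.unique(time[event == 1])
    R = time[None, :] >= ev_times[:, None]                  # E x n at-risk
    Ev = (time[None, :] == ev_times[:, None]) & (event[None, :] == 1)
    d = Ev.sum(1).astype(float)                             # events per time
    n = R.sum(1).astype(float)
    Z = (score[None, :] > cutpoints[:, None]).astype(float)  # C x n
    n1 = R.astype(float) @ Z.T                              # E x C
    o1 = Ev.astype(float) @ Z.T
    O1 = o1.sum(0)
    frac = n1 / n[:, None]
    E1 = (d[:, None] * frac).sum(0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(n > 1, (n - d) / (n - 1), 0.0)
        V = (d[:, None] * frac * (1 - frac) * corr[:, None]).sum(0)
        z = np.where(V > 0, (O1 - E1) / np.sqrt(V), 0.0)
    return z


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties)
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    names: list[str]
    coef: np.ndarray           # log hazard ratios
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    z: np.ndarray
    p: np.ndarray
    loglik: float
    loglik_null: float
    score_chi2_null: float     # score test at beta = 0
    converged: bool
    n: int
    n_events: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef, "HR": self.hr, "se": self.se,
            "ci95_low": self.ci_low, "ci95_high": self.ci_high,
            "z": self.z, "p": self.p,
        }, index=self.names)


def _cox_derivatives(beta, time, event, X):
    """Breslow partial log-likelihood, gradient and information."""
    order = np.argsort(-time, kind="stable")  # descending time
    t, e, Xo = time[order], event[order], X[order]
    n, p = Xo.shape
    eta = Xo @ beta
    eta -= eta.max()
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    # cumulative sums over risk sets, walking down in time
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        for idx in range(i, j):
            s0 += w[idx]
            s1 += w[idx] * Xo[idx]
            s2 += w[idx] * np.outer(Xo[idx], Xo[idx])
        d_idx = [idx for idx in range(i, j) if e[idx] == 1]
        d = len(d_idx)
        if d:
            xsum = Xo[d_idx].sum(axis=0)
            ll += float(eta[d_idx].sum()) - d * np.log(s0)
            mean = s1 / s0
            grad += xsum - d * mean
            info += d * (s2 / s0 - np.outer(mean, mean))
        i = j
    return ll, grad, info


def cox_fit(
    time, event, covariates: pd.DataFrame | np.ndarray,
    max_iter: int = 50, tol: float = 1e-9,
) -> CoxFit:
    """Newton-Raphson fit of the Cox model with Breslow tie handling.

    Monotone likelihood (perfect separation) is flagged: estimates are
    reported at the iteration cap with converged=False.
    """
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(float)
    else:
        X = np.atleast_2d(np.asarray(covariates, float))
        if X.shape[0] == 1 and len(time) != 1:
            X = X.T
        names = [f"x{i}" for i in range(X.shape[1])]
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n, p = X.shape
    beta = np.zeros(p)
    ll0, grad0, info0 = _cox_derivatives(beta, time, event, X)
    try:
        score_chi2 = float(grad0 @ np.linalg.solve(info0, grad0))
    except np.linalg.LinAlgError:
        raise ValidationError("singular information matrix (collinear covariates)")
    ll_prev = ll0
    converged = False
    for _ in range(max_iter):
        ll, grad, info = _cox_derivatives(beta, time, event, X)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise ValidationError("singular information matrix (collinear covariates)")
        # step-halving for stability
        for _h in range(20):
            llnew, _, _ = _cox_derivatives(beta + step, time, event, X)
            if llnew >= ll - 1e-12:
                break
            step /= 2
        beta = beta + step
        if abs(llnew - ll_prev) < tol:
            converged = True
            ll = llnew
            break
        ll_prev = llnew
    ll, grad, info = _cox_derivatives(beta, time, event, X)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    if (np.abs(beta) > 10).any() or (se > 1e3 * np.maximum(np.abs(beta), 1)).any():
        # likelihood plateau with runaway estimates: monotone likelihood
        converged = False
    if not converged:
        logger.warning("cox_fit: not converged / monotone likelihood; "
                       "estimates reported at the iteration cap")
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    hr = np.exp(beta)
    zc = stats.norm.ppf(0.975)
    lim = 700.0
    return CoxFit(
        names=names, coef=beta, se=se, hr=hr,
        ci_low=np.exp(np.clip(beta - zc * se, -lim, lim)),
        ci_high=np.exp(np.clip(beta + zc * se, -lim, lim)),
        z=z, p=pvals, loglik=float(ll), loglik_null=float(ll0),
        score_chi2_null=score_chi2, converged=converged,
        n=n, n_events=int(event.sum()),
    )


# ---------------------------------------------------------------------------
# Tumor-immune cell network
# ---------------------------------------------------------------------------


@dataclass
class CellNetwork:
    impact: pd.DataFrame   # per cell type: -log10 logrank p, sign, split quantile
    edges: pd.DataFrame    # pairwise Spearman rho with p, thresholded


def cell_network(
    fractions: pd.DataFrame,
    clinical: ClinicalTable,
    split_quantile: float = 0.5,
    rho_threshold: float = 0.2,
    p_threshold: float = 0.05,
) -> CellNetwork:
    """Per-cell-type survival impact (-log10 log-rank p of an abundance split,
    signed risk/favourable) and the Spearman co-infiltration network."""
    common = [s for s in fractions.index if s in clinical.table.index]
    fr = fractions.loc[common]
    t = clinical.table.loc[common, "os_time"].to_numpy(float)
    e = clinical.table.loc[common, "os_event"].to_numpy(int)
    rows = []
    for ct in fr.columns:
        x = fr[ct].to_numpy(float)
        cut = np.quantile(x, split_quantile)
        high = x > cut
        if high.sum() in (0, len(x)):
            logger.warning("cell_network: constant split for %s; dropped", ct)
            continue
        chi2, _, p = logrank_test(t, e, high.astype(int))
        z = logrank_z(t, e, high.astype(int))
        rows.append({
            "cell_type": ct, "impact": -np.log10(max(p, 1e-300)),
            "direction": "risk" if z > 0 else "favourable", "logrank_p": p,
        })
    impact = pd.DataFrame(rows).set_index("cell_type")
    edges = []
    cols = list(fr.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a, b = fr[cols[i]].to_numpy(), fr[cols[j]].to_numpy()
            if np.std(a) == 0 or np.std(b) == 0:
                logger.warning("cell_network: constant column %s/%s; edge dropped",
                               cols[i], cols[j])
                continue
            rho, p = stats.spearmanr(a, b)
            if abs(rho) >= rho_threshold and p < p_threshold:
                edges.append({"a": cols[i], "b": cols[j],
                              "rho": float(rho), "p": float(p)})
    return CellNetwork(impact=impact, edges=pd.DataFrame(edges))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def roc_auc(score, outcome) -> float:
    """AUC by the Mann-Whitney rank identity with midrank tie correction."""
    score = np.asarray(score, float)
    outcome = np.asarray(outcome, int)
    n1 = int(outcome.sum())
    n0 = len(outcome) - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC needs both outcome classes present")
    ranks = stats.rankdata(score)
    return float((ranks[outcome == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _placements(pos, neg):
    """DeLong placement values."""
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / len(neg) for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / len(pos) for q in neg])
    return v10, v01


def delong_compare(score1, score2, outcome) -> tuple[float, float, float]:
    """Paired DeLong test for the difference of two correlated AUCs.

    Returns (delta_auc, z, two-sided p).
    """
    score1 = np.asarray(score1, float)
    score2 = np.asarray(score2, float)
    outcome = np.asarray(outcome, int)
    pos = outcome == 1
    neg = ~pos
    m, n = int(pos.sum()), int(neg.sum())
    aucs, v10s, v01s = [], [], []
    for s in (score1, score2):
        v10, v01 = _placements(s[pos], s[neg])
        v10s.append(v10)
        v01s.append(v01)
        aucs.append(v10.mean())
    v10s = np.array(v10s)
    v01s = np.array(v01s)
    s10 = np.cov(v10s)
    s01 = np.cov(v01s)
    cov = s10 / m + s01 / n
    delta = aucs[0] - aucs[1]
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        return float(delta), 0.0, 1.0
    z = delta / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(delta), float(z), float(p)
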