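"""Mutational-signature analysis: 96-context catalogues, signature extraction
by automatic-relevance-determination NMF, cosine matching against a reference
signature set, exposure clustering, APOBEC TCW enrichment and tumor mutation
burden.

The 96 categories are the six pyrimidine substitutions (C>A, C>G, C>T, T>A,
T>C, T>G) crossed with the four 5' and four 3' flanking bases, in lexicographic
order.  Records whose reference allele is a purine are reverse-complemented
onto the pyrimidine strand before tallying.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF
from sklearn.metrics import silhouette_score

from .io_core import MutationTable, NONSILENT_CLASSES, ValidationError

logger = logging.getLogger("tmepipe")

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Canonical order of the 96 trinucleotide substitution categories.
CONTEXTS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
_CTX_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def collapse_to_pyrimidine(ref: str, alt: str, context: str) -> tuple[str, str, str]:
    """Map a stranded SNV onto the pyrimidine-reference representation.

    Idempotent: records already on the pyrimidine strand are returned as-is.
    """
    if ref in ("C", "T"):
        return ref, alt, context
    return COMPLEMENT[ref], COMPLEMENT[alt], revcomp(context)


def context_category(ref: str, alt: str, context: str) -> str:
    ref, alt, context = collapse_to_pyrimidine(ref, alt, context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class MutCatalogue:
    """Samples x 96 matrix of SNV counts per trinucleotide substitution category."""

    counts: pd.DataFrame  # index sample, columns CONTEXTS_96

    def __post_init__(self) -> None:
        if tuple(self.counts.columns) != CONTEXTS_96:
            raise ValidationError("catalogue must have exactly the 96 canonical columns")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative catalogue counts")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)


def build_catalogue(muts: MutationTable) -> MutCatalogue:
    """Tally SNVs into the 96-category catalogue; non-SNV records are skipped."""
    r = muts.records
    snv = muts.is_snv()
    n_skipped = int((~snv).sum())
    if n_skipped:
        logger.info("build_catalogue: skipped %d non-SNV records", n_skipped)
    if "CONTEXT" not in r.columns:
        raise ValidationError("mutation table lacks CONTEXT column needed for catalogue")
    samples = sorted(r["Tumor_Sample_Barcode"].unique())
    mat = pd.DataFrame(0, index=samples, columns=list(CONTEXTS_96))
    sub = r[snv]
    for s, ref, alt, ctx in zip(
        sub["Tumor_Sample_Barcode"], sub["Reference_Allele"],
        sub["Tumor_Seq_Allele2"], sub["CONTEXT"],
    ):
        mat.loc[s, context_category(ref, alt, str(ctx))] += 1
    return MutCatalogue(mat)


# ---------------------------------------------------------------------------
# Signature extraction
# ---------------------------------------------------------------------------


@dataclass
class SignatureDecomp:
    """NMF decomposition of a catalogue: profiles W (96 x k, columns sum to 1),
    exposures H (k x samples, counts scale) and diagnostics."""

    W: pd.DataFrame
    H: pd.DataFrame
    chosen_k: int
    reconstruction_error: float
    objective: float
    converged: bool
    matches: pd.DataFrame | None = None  # per-signature best reference match

    @property
    def signature_names(self) -> list[str]:
        return list(self.W.columns)


def _kl_div(V: np.ndarray, R: np.ndarray) -> float:
    mask = V > 0
    return float(np.sum(V[mask] * np.log(V[mask] / R[mask])) - V.sum() + R.sum())


def _ard_nmf_once(
    V: np.ndarray,
    k_max: int,
    a: float,
    b: float,
    tol: float,
    max_iter: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool]:
    """One run of ARD-NMF (KL divergence, half-normal column priors).

    Relevance weights lam_k carry an inverse-gamma(a, b) hyperprior; signatures
    whose relevance collapses are driven to zero by the multiplicative updates.
    """
    F, N = V.shape
    scale = np.sqrt(V.mean() / k_max)
    W = rng.uniform(0.5, 1.5, (F, k_max)) * scale
    H = rng.uniform(0.5, 1.5, (k_max, N)) * scale
    lam = (0.5 * (W**2).sum(0) + 0.5 * (H**2).sum(1) + b) / ((F + N) / 2 + a + 1)
    eps = 1e-12
    prev_obj = np.inf
    converged = False
    const = (F + N) / 2 + a + 1
    for it in range(max_iter):
        R = W @ H + eps
        W *= (V / R) @ H.T / (H.sum(1)[None, :] + W / lam[None, :] + eps)
        R = W @ H + eps
        H *= W.T @ (V / R) / (W.sum(0)[:, None] + H / lam[:, None] + eps)
        lam = (0.5 * (W**2).sum(0) + 0.5 * (H**2).sum(1) + b) / const
        if it % 10 == 0 or it == max_iter - 1:
            obj = (
                _kl_div(V, W @ H + eps)
                + float(np.sum((0.5 * (W**2).sum(0) + 0.5 * (H**2).sum(1) + b) / lam))
                + const * float(np.sum(np.log(lam)))
            )
            if np.isfinite(prev_obj) and abs(prev_obj - obj) <= tol * abs(prev_obj):
                converged = True
                prev_obj = obj
                break
            prev_obj = obj
    return W, H, lam, prev_obj, converged


def extract_signatures(
    cat: MutCatalogue,
    k_range: range | tuple = range(1, 7),
    n_restarts: int = 100,
    tol: float = 1e-7,
    a: float = 10.0,
    max_iter: int = 2000,
    seed: int = 0,
    method: str = "ard",
    prune_rel: float = 1e-3,
) -> SignatureDecomp:
    """Extract mutational signatures from a catalogue.

    method="ard": automatic-relevance-determination NMF with half-normal
    priors and inverse-gamma(a) relevance hyperprior; the surviving number of
    components IS the chosen k.  method="plain": KL-NMF per fixed k with an
    elbow rule on reconstruction error.
    """
    V = cat.counts.to_numpy(float).T  # 96 x samples
    if V.shape[1] < 2:
        raise ValidationError("need >= 2 samples for signature extraction")
    if V.sum() < 50:
        raise ValidationError("need >= 50 total mutations for signature extraction")
    ks = list(k_range)
    k_max = max(ks)
    rng = np.random.default_rng(seed)
    if method == "ard":
        b = np.sqrt(max((a - 1) * (a - 2), 1.0) * V.mean() / k_max)
        best = None
        any_converged = False
        for _ in range(n_restarts):
            W, H, lam, obj, conv = _ard_nmf_once(V, k_max, a, b, tol, max_iter, rng)
            any_converged = any_converged or conv
            if best is None or obj < best[3]:
                best = (W, H, lam, obj, conv)
        W, H, lam, obj, conv = best
        if not any_converged:
            logger.warning("ARD-NMF: no restart converged; best-effort result flagged")
        # a dead component's relevance collapses to the prior floor b/const;
        # keep those clearly above it (and above prune_rel of the largest)
        floor = b / ((V.shape[0] + V.shape[1]) / 2 + a + 1)
        keep = (lam > 2.0 * floor) & (lam > prune_rel * lam.max())
        if not keep.any():
            keep = lam == lam.max()
        W, H = W[:, keep], H[keep]
        chosen_k = int(keep.sum())
        # penalty-free KL polish at the ARD-selected rank removes the small
        # profile bias introduced by the half-normal prior
        eps = 1e-12
        prev = np.inf
        for _ in range(2000):
            R = W @ H + eps
            W *= ((V / R) @ H.T) / (H.sum(1)[None, :] + eps)
            R = W @ H + eps
            H *= (W.T @ (V / R)) / (W.sum(0)[:, None] + eps)
            cur = _kl_div(V, W @ H + eps)
            if np.isfinite(prev) and abs(prev - cur) <= 1e-9 * max(abs(prev), 1.0):
                break
            prev = cur
        obj = prev
    else:
        prev_err = None
        chosen = None
        for k in ks:
            model = NMF(
                n_components=k, beta_loss="kullback-leibler", solver="mu",
                init="random", random_state=int(rng.integers(2**31)),
                max_iter=2000, tol=1e-6,
            )
            Wk = model.fit_transform(V)
            Hk = model.components_
            err = _kl_div(V, Wk @ Hk + 1e-12)
            if prev_err is not None and (prev_err - err) < 0.05 * prev_err:
                break
            chosen = (Wk, Hk, err, k)
            prev_err = err
        W, H, obj, chosen_k = chosen
        conv = True
    colsum = W.sum(0)
    colsum[colsum == 0] = 1.0
    H = H * colsum[:, None]
    W = W / W.sum(0, keepdims=True).clip(1e-300)
    order = np.argsort(-H.sum(1))
    W, H = W[:, order], H[order]
    names = [f"Sig{i + 1}" for i in range(chosen_k)]
    recon = float(np.linalg.norm(V - W @ H))
    return SignatureDecomp(
        W=pd.DataFrame(W, index=list(CONTEXTS_96), columns=names),
        H=pd.DataFrame(H, index=names, columns=cat.sample_ids),
        chosen_k=chosen_k,
        reconstruction_error=recon,
        objective=float(obj),
        converged=bool(conv),
    )


def load_reference_signatures(path=None) -> pd.DataFrame:
    """Load a 96 x n reference signature matrix (default: the bundled synthetic
    stand-in for the COSMIC v2 catalogue; supply the real file by path)."""
    if path is None:
        path = resources.files("tmepipe.data") / "cosmic_v2_synthetic.tsv"
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CONTEXTS_96) - set(df.index)
    if missing:
        raise ValidationError(f"reference signatures missing contexts: {sorted(missing)[:3]}")
    return df.loc[list(CONTEXTS_96)]


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def cosine_match(W: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Best reference match per extracted signature (ties -> lowest ref index)."""
    ref = reference.loc[list(CONTEXTS_96)]
    rows = []
    for sig in W.columns:
        sims = np.array([
            cosine_similarity(W[sig].to_numpy(), ref[c].to_numpy()) for c in ref.columns
        ])
        best = int(np.argmax(sims))  # argmax returns first (lowest) index on ties
        rows.append({"signature": sig, "best_match": ref.columns[best],
                     "cosine": float(sims[best])})
    return pd.DataFrame(rows).set_index("signature")


def cluster_exposures(
    H: pd.DataFrame, k_range: range | tuple = range(2, 7), seed: int = 0
) -> pd.DataFrame:
    """K-means on column-normalized exposures; r selected by mean silhouette.

    Returns per-sample cluster id and the cluster's dominant signature.
    """
    X = H.to_numpy(float).T
    tot = X.sum(1, keepdims=True)
    tot[tot == 0] = 1.0
    X = X / tot
    n = X.shape[0]
    best = None
    for r in k_range:
        if r >= n:
            continue
        km = KMeans(n_clusters=r, n_init=10, random_state=seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        sil = silhouette_score(X, labels)
        if best is None or sil > best[0]:
            best = (sil, r, labels)
    if best is None:
        raise ValidationError("exposure clustering failed for every r in k_range")
    _, r, labels = best
    out = pd.DataFrame({"cluster": labels + 1}, index=H.columns)
    top = {}
    for c in range(r):
        members = out.index[out["cluster"] == c + 1]
        top[c + 1] = H[members].sum(1).idxmax()
    out["top_signature"] = out["cluster"].map(top)
    return out


# ---------------------------------------------------------------------------
# APOBEC enrichment and TMB
# ---------------------------------------------------------------------------

_W = ("A", "T")


def _window_background(window: str) -> tuple[int, int]:
    """Count cytosines and TCW motifs in a sequence window, both strands.

    Reverse-strand cytosines appear as G on the given strand; reverse-strand
    TCW appears as WGA.
    """
    n_c = window.count("C") + window.count("G")
    n_tcw = 0
    for i in range(1, len(window) - 1):
        tri = window[i - 1 : i + 2]
        if tri[1] == "C" and tri[0] == "T" and tri[2] in _W:
            n_tcw += 1
        if tri[1] == "G" and tri[2] == "A" and tri[0] in _W:
            n_tcw += 1
    return n_tcw, n_c


def apobec_enrichment(
    muts: MutationTable, flank: int = 20, subs: str = "ctcg"
) -> pd.DataFrame:
    """Per-sample APOBEC enrichment score E with one-sided Fisher p.

    E = (mut_TCW / mut_C) / (context_TCW / context_C) over C>T (and, with
    subs="ctcg", C>G) mutations; the context counts come from the ±flank bp
    windows around the included mutations.  Samples with E > 2 are classed
    "enriched".
    """
    r = muts.records
    if "CONTEXT41" not in r.columns:
        raise ValidationError("APOBEC enrichment needs a CONTEXT41 column (±20 bp)")
    alts = ("T", "G") if subs == "ctcg" else ("T",)
    rows = []
    for sample, grp in r.groupby("Tumor_Sample_Barcode", sort=True):
        mut_tcw = mut_c = ctx_tcw = ctx_c = 0
        snv = (
            grp["Reference_Allele"].astype(str).isin(BASES)
            & grp["Tumor_Seq_Allele2"].astype(str).isin(BASES)
        )
        for _, rec in grp[snv].iterrows():
            ref, alt, ctx = collapse_to_pyrimidine(
                rec["Reference_Allele"], rec["Tumor_Seq_Allele2"], str(rec["CONTEXT"])
            )
            if ref != "C" or alt not in alts:
                continue
            mut_c += 1
            if ctx[0] == "T" and ctx[2] in _W:
                mut_tcw += 1
            win = str(rec["CONTEXT41"])
            mid = len(win) // 2
            lo, hi = max(0, mid - flank), min(len(win), mid + flank + 1)
            t, c = _window_background(win[lo:hi])
            ctx_tcw += t
            ctx_c += c
        if mut_c == 0 or ctx_tcw == 0 or ctx_c == 0:
            score, p = 0.0, 1.0
        else:
            score = (mut_tcw / mut_c) / (ctx_tcw / ctx_c)
            table = [[mut_tcw, mut_c - mut_tcw], [ctx_tcw, ctx_c - ctx_tcw]]
            _, p = fisher_exact(table, alternative="greater")
        rows.append({
            "sample": sample, "enrichment": score, "fisher_p": float(p),
            "mut_tcw": mut_tcw, "mut_c": mut_c,
            "context_tcw": ctx_tcw, "context_c": ctx_c,
            "apobec_class": "enriched" if score > 2 else "non-enriched",
        })
    return pd.DataFrame(rows).set_index("sample")


def apobec_gene_association(
    muts: MutationTable, apobec: pd.DataFrame, gene_col: str = "Hugo_Symbol"
) -> pd.DataFrame:
    """Per-gene one-sided Fisher test for overrepresentation of mutations in
    APOBEC-enriched samples, with BH-adjusted q-values."""
    from statsmodels.stats.multitest import multipletests

    r = muts.records
    if gene_col not in r.columns:
        raise ValidationError(f"mutation table lacks gene column {gene_col!r}")
    enriched = set(apobec.index[apobec["apobec_class"] == "enriched"])
    samples = set(apobec.index)
    n_enr = len(enriched)
    n_non = len(samples) - n_enr
    rows = []
    for gene, grp in r.groupby(gene_col, sort=True):
        carriers = set(grp["Tumor_Sample_Barcode"]) & samples
        a = len(carriers & enriched)
        b = n_enr - a
        c = len(carriers) - a
        d = n_non - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"gene": gene, "mut_enriched": a, "mut_non": c, "p": float(p)})
    out = pd.DataFrame(rows).set_index("gene")
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def compute_tmb(
    muts: MutationTable,
    nonsilent_classes: frozenset = NONSILENT_CLASSES,
    exome_mb: float = 38.0,
) -> pd.DataFrame:
    """Per-sample nonsilent mutation count and per-megabase rate."""
    r = muts.records
    nonsilent = r["Variant_Classification"].isin(nonsilent_classes)
    counts = (
        r[nonsilent].groupby("Tumor_Sample_Barcode").size()
        .reindex(sorted(r["Tumor_Sample_Barcode"].unique()), fill_value=0)
    )
    out = pd.DataFrame({"n_nonsilent": counts})
    out["tmb_per_mb"] = out["n_nonsilent"] / exome_mb
    out.index.name = "sample"
    return out
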