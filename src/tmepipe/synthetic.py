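"""Synthetic cohort generator.

Emulates the statistical structure every downstream stage assumes, so the
whole pipeline runs without any external download:

* bulk expression = reference-signature mixing with Dirichlet cell fractions
  under a small number of planted infiltration patterns, negative-binomial
  counting noise on top;
* overall survival exponential with pattern-specific hazard ratios and
  independent exponential censoring calibrated to a target censoring rate;
* somatic mutation catalogues drawn from planted 96-context signatures, one
  of them APOBEC-like (>= 80% of its mass on T[C>T]W and T[C>G]W);
* copy-number segment tables with planted arm-level and focal events on a toy
  genome of 4 chromosomes x 2 arms x 50 Mb.

All generators are pure functions of :class:`SimConfig` (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_core import (
    ClinicalTable,
    ExpressionMatrix,
    MutationTable,
    SegmentTable,
    SignatureMatrixRef,
    ValidationError,
)
from .mutsig import BASES, CONTEXTS_96, revcomp

# internal sub-seeds so the three generators draw independent streams
_COHORT, _MUTS, _CNV = 11, 22, 33

N_CELL_TYPES = 22

CELL_TYPES = [f"CT{i + 1:02d}" for i in range(N_CELL_TYPES)]


def default_reference(n_genes: int = 500, seed: int = 7654321) -> SignatureMatrixRef:
    """Bundled LM22-style synthetic signature matrix: 22 cell types x
    ``n_genes`` genes, block-structured so every cell type owns >= 10 marker
    genes.  Deterministic — the seed is part of the bundled object's identity.
    """
    rng = np.random.default_rng(seed)
    markers_per_type = max(10, (n_genes - 60) // N_CELL_TYPES)
    base = rng.uniform(1.0, 10.0, (n_genes, N_CELL_TYPES))
    for t in range(N_CELL_TYPES):
        lo = t * markers_per_type
        hi = lo + markers_per_type
        base[lo:hi, t] += rng.uniform(80.0, 120.0, markers_per_type)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    return SignatureMatrixRef(pd.DataFrame(base, index=genes, columns=CELL_TYPES))


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort."""

    seed: int
    n_samples: int = 300
    n_patterns: int = 3
    n_genes: int = 500
    #: Dirichlet baseline and the boost added to each pattern's own cell types.
    dirichlet_base: float = 0.25
    dirichlet_boost: float = 4.0
    #: optional explicit per-pattern Dirichlet alphas (n_patterns x 22),
    #: overriding the block construction
    custom_alphas: tuple | None = None
    library_size: float = 1e5
    library_cv: float = 0.2
    nb_dispersion: float = 0.1
    hazard_ratios: tuple = (0.5, 1.0, 2.0)
    base_hazard: float = np.log(2) / 1000.0  # per day; median OS ~1000 d at HR 1
    censoring_rate: float = 0.3
    #: explicitly planted differentially expressed genes (multiplicative)
    n_deg_genes: int = 60
    deg_log2fc: float = 2.5
    # mutation simulation
    n_mut_signatures: int = 3
    mutations_per_sample: tuple = (50, 200)
    apobec_fraction: float = 0.25
    # CNV simulation: (arm, effect, fraction) and (chrom, start, end, effect, fraction)
    planted_arm_events: tuple = (("chr2q", 1.5, 0.6), ("chr3p", -1.5, 0.4))
    planted_focal_peaks: tuple = (
        ("chr1", 20_000_001, 21_000_000, 2.0, 0.4),
        ("chr4", 70_000_001, 71_000_000, -2.0, 0.35),
    )
    reference: SignatureMatrixRef | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("SimConfig.seed is mandatory")
        if len(self.hazard_ratios) != self.n_patterns:
            raise ValidationError("hazard_ratios length must equal n_patterns")
        for v in (self.library_size, self.nb_dispersion, self.censoring_rate,
                  self.base_hazard):
            if v < 0:
                raise ValidationError("rates must be non-negative")

    def get_reference(self) -> SignatureMatrixRef:
        return self.reference or default_reference(self.n_genes)


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    pattern: pd.Series                 # per-sample planted pattern (1..n_patterns)
    fractions: pd.DataFrame            # true cell fractions (simplex rows)
    linear_predictor: pd.Series        # true log hazard per sample
    planted_degs: list[str]            # explicitly planted DE genes
    expected_degs: list[str]           # genes with true |log2FC| > 1 in >= 2 contrasts
    pattern_alphas: np.ndarray = field(default=None)
    response: pd.Series = field(default=None)  # binary immunotherapy-response proxy


def _pattern_alphas(cfg: SimConfig) -> np.ndarray:
    if cfg.custom_alphas is not None:
        alphas = np.asarray(cfg.custom_alphas, float)
        if alphas.shape != (cfg.n_patterns, N_CELL_TYPES):
            raise ValidationError("custom_alphas must be n_patterns x 22")
        return alphas
    alphas = np.full((cfg.n_patterns, N_CELL_TYPES), cfg.dirichlet_base)
    block = N_CELL_TYPES // cfg.n_patterns
    for p in range(cfg.n_patterns):
        lo = p * block
        hi = N_CELL_TYPES if p == cfg.n_patterns - 1 else lo + block
        alphas[p, lo:hi] += cfg.dirichlet_boost
    return alphas


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:04d}" for i in range(n)]


def _censor_rate(cfg: SimConfig, pattern_probs: np.ndarray) -> float:
    """Exponential censoring rate c with P(censored) = censoring_rate under the
    hazard mixture: P = sum_p pi_p * c / (c + lambda_p)."""
    lam = cfg.base_hazard * np.asarray(cfg.hazard_ratios)
    target = cfg.censoring_rate
    if target <= 0:
        return 0.0

    def f(c):
        return float(np.sum(pattern_probs * c / (c + lam))) - target

    hi = lam.max() * 1e4
    return brentq(f, 1e-12, hi)


def simulate_cohort(cfg: SimConfig) -> tuple[ExpressionMatrix, ClinicalTable, SimTruth]:
    """Generate (counts, clinical, truth) for one cohort."""
    rng = np.random.default_rng([cfg.seed, _COHORT])
    ref = cfg.get_reference()
    R = ref.values.to_numpy(float)  # genes x cell types
    if R.shape[1] != N_CELL_TYPES:
        raise ValidationError("reference must have 22 cell types")
    genes = ref.gene_ids
    n = cfg.n_samples
    samples = _sample_ids(n)

    alphas = _pattern_alphas(cfg)
    pattern = rng.integers(0, cfg.n_patterns, n)
    fractions = np.vstack([rng.dirichlet(alphas[p]) for p in pattern])

    # planted multiplicative DEGs on the tail (non-marker) genes where possible
    markers_end = (N_CELL_TYPES * max(10, (cfg.n_genes - 60) // N_CELL_TYPES)
                   if cfg.reference is None else 0)
    pool = list(range(min(markers_end, cfg.n_genes - cfg.n_deg_genes), cfg.n_genes)) \
        if cfg.n_deg_genes else []
    deg_idx = np.array(sorted(rng.choice(pool, cfg.n_deg_genes, replace=False))) \
        if cfg.n_deg_genes else np.array([], int)
    deg_pattern = rng.integers(0, cfg.n_patterns, len(deg_idx))
    fc = 2.0 ** cfg.deg_log2fc

    mu_frac = fractions @ R.T  # samples x genes
    for gi, gp in zip(deg_idx, deg_pattern):
        mu_frac[pattern == gp, gi] *= fc
    mu_frac /= mu_frac.sum(axis=1, keepdims=True)

    lib = rng.lognormal(
        np.log(cfg.library_size) - 0.5 * np.log(1 + cfg.library_cv**2),
        np.sqrt(np.log(1 + cfg.library_cv**2)), n,
    )
    mu = mu_frac * lib[:, None]
    d = cfg.nb_dispersion
    if d > 0:
        lam = rng.gamma(shape=1.0 / d, scale=mu * d)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(float).T  # genes x samples
    expr = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=samples),
                            unit="counts")

    # survival: exponential with pattern-specific hazard + calibrated censoring
    hr = np.asarray(cfg.hazard_ratios)
    lam_s = cfg.base_hazard * hr[pattern]
    t_event = rng.exponential(1.0 / lam_s)
    probs = np.full(cfg.n_patterns, 1.0 / cfg.n_patterns)
    c_rate = _censor_rate(cfg, probs)
    if c_rate > 0:
        t_cens = rng.exponential(1.0 / c_rate, n)
    else:
        t_cens = np.full(n, np.inf)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)

    # immunotherapy-response proxy tied to the most favourable pattern
    fav = int(np.argmin(hr))
    p_resp = np.where(pattern == fav, 0.5, 0.2)
    response = rng.binomial(1, p_resp)

    clin = ClinicalTable(pd.DataFrame({
        "os_time": os_time, "os_event": os_event,
        "age": rng.integers(35, 85, n),
        "response": response,
    }, index=pd.Index(samples, name="sample_id")))

    # expected DEGs from the noise-free pattern profiles
    mean_frac = alphas / alphas.sum(axis=1, keepdims=True)
    mu_p = mean_frac @ R.T  # patterns x genes
    for gi, gp in zip(deg_idx, deg_pattern):
        mu_p[gp, gi] *= fc
    mu_p /= mu_p.sum(axis=1, keepdims=True)
    n_big = np.zeros(len(genes), int)
    for a in range(cfg.n_patterns):
        for b in range(a + 1, cfg.n_patterns):
            lfc = np.log2(mu_p[a] / mu_p[b])
            n_big += (np.abs(lfc) > 1).astype(int)
    expected = [genes[i] for i in np.flatnonzero(n_big >= 2)]

    truth = SimTruth(
        pattern=pd.Series(pattern + 1, index=samples, name="pattern"),
        fractions=pd.DataFrame(fractions, index=samples, columns=CELL_TYPES),
        linear_predictor=pd.Series(np.log(lam_s), index=samples, name="log_hazard"),
        planted_degs=[genes[i] for i in deg_idx],
        expected_degs=expected,
        pattern_alphas=alphas,
        response=pd.Series(response, index=samples, name="response"),
    )
    return expr, clin, truth


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------


def planted_signatures(n_signatures: int = 3) -> pd.DataFrame:
    """Planted 96-context signatures; the first is APOBEC-like with 90% of its
    mass on T[C>T]W and T[C>G]W."""
    n = len(CONTEXTS_96)
    idx = {c: i for i, c in enumerate(CONTEXTS_96)}

    def peaked(cats, mass):
        v = np.full(n, (1 - mass) / (n - len(cats)))
        for c in cats:
            v[idx[c]] = mass / len(cats)
        return v

    sigs = [peaked([f"T[C>T]{w}" for w in "AT"] + [f"T[C>G]{w}" for w in "AT"], 0.9),
            peaked([f"{f}[C>T]G" for f in BASES], 0.8),
            peaked([f"{f}[T>C]{t}" for f in BASES for t in BASES], 0.7)]
    rng = np.random.default_rng(424242)
    while len(sigs) < n_signatures:
        alpha = np.full(n, 0.1)
        alpha[rng.choice(n, 6, replace=False)] = 4.0
        sigs.append(rng.dirichlet(alpha))
    out = pd.DataFrame(
        np.array(sigs[:n_signatures]).T, index=list(CONTEXTS_96),
        columns=[f"Planted{i + 1}" for i in range(n_signatures)],
    )
    return out / out.sum(0)


_SNV_CLASSES = ("Missense_Mutation", "Nonsense_Mutation", "Silent", "Splice_Site")
_SNV_CLASS_P = (0.6, 0.1, 0.2, 0.1)
_INDEL_CLASSES = ("Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins")

CONTIGS = ("chr1", "chr2", "chr3", "chr4")


def _category_parts(cat: str) -> tuple[str, str, str]:
    # "A[C>T]G" -> ("C", "T", "ACG")
    five, rest = cat.split("[")
    sub, three = rest.split("]")
    ref, alt = sub.split(">")
    return ref, alt, five + ref + three


def simulate_mutations(
    cfg: SimConfig,
) -> tuple[MutationTable, pd.DataFrame, pd.DataFrame]:
    """Draw per-sample mutation catalogues from the planted signatures and
    expand them into MAF records with consistent 3-mer and ±20 bp contexts.

    Returns (mutations, true exposures [samples x signatures], signatures).
    A configured fraction of samples is APOBEC-dominated (90% exposure on the
    TCW-concentrated signature); the rest carry it at near-zero exposure.
    """
    rng = np.random.default_rng([cfg.seed, _MUTS])
    sigs = planted_signatures(cfg.n_mut_signatures)
    S = sigs.to_numpy()  # 96 x k
    k = S.shape[1]
    samples = _sample_ids(cfg.n_samples)
    lo, hi = cfg.mutations_per_sample
    records = []
    exposures = np.zeros((cfg.n_samples, k))
    pos_counter = 1000
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    for si, sample in enumerate(samples):
        if rng.random() < cfg.apobec_fraction:
            expo = np.full(k, 0.1 / (k - 1)) if k > 1 else np.ones(1)
            expo[0] = 0.9
        else:
            rest = rng.dirichlet(np.full(k - 1, 2.0)) if k > 1 else np.array([])
            expo = np.concatenate([[0.02], rest * 0.98]) if k > 1 else np.ones(1)
        exposures[si] = expo
        n_mut = int(rng.integers(lo, hi + 1))
        probs = S @ expo
        cats = rng.multinomial(n_mut, probs / probs.sum())
        for ci in np.flatnonzero(cats):
            for _ in range(cats[ci]):
                ref, alt, ctx = _category_parts(CONTEXTS_96[ci])
                left = "".join(rng.choice(BASES, 19)) + ctx[0]
                right = ctx[2] + "".join(rng.choice(BASES, 19))
                ctx41 = left + ref + right
                if rng.random() < 0.5:  # emit on the purine strand
                    ref2, alt2 = revcomp(ref), revcomp(alt)
                    ctx3, ctx41s = revcomp(ctx), revcomp(ctx41)
                else:
                    ref2, alt2, ctx3, ctx41s = ref, alt, ctx, ctx41
                pos_counter += int(rng.integers(1, 100))
                records.append({
                    "Tumor_Sample_Barcode": sample,
                    "Hugo_Symbol": genes[int(rng.integers(0, len(genes)))],
                    "Chromosome": CONTIGS[int(rng.integers(0, len(CONTIGS)))],
                    "Start_Position": pos_counter,
                    "Reference_Allele": ref2,
                    "Tumor_Seq_Allele2": alt2,
                    "Variant_Classification": rng.choice(_SNV_CLASSES, p=_SNV_CLASS_P),
                    "CONTEXT": ctx3,
                    "CONTEXT41": ctx41s,
                })
        for _ in range(rng.poisson(0.05 * n_mut)):  # a few indels
            pos_counter += int(rng.integers(1, 100))
            records.append({
                "Tumor_Sample_Barcode": sample,
                "Hugo_Symbol": genes[int(rng.integers(0, len(genes)))],
                "Chromosome": CONTIGS[int(rng.integers(0, len(CONTIGS)))],
                "Start_Position": pos_counter,
                "Reference_Allele": "A",
                "Tumor_Seq_Allele2": "-",
                "Variant_Classification": str(rng.choice(_INDEL_CLASSES)),
                "CONTEXT": "",
                "CONTEXT41": "",
            })
    muts = MutationTable(pd.DataFrame.from_records(records), contigs=CONTIGS)
    expo_df = pd.DataFrame(exposures, index=samples, columns=sigs.columns)
    return muts, expo_df, sigs


# ---------------------------------------------------------------------------
# Copy number
# ---------------------------------------------------------------------------

ARM_LENGTH = 50_000_000


def toy_genome() -> pd.DataFrame:
    """Arm definition table for the toy genome: 4 chromosomes x 2 arms x 50 Mb."""
    rows = []
    for chrom in CONTIGS:
        rows.append({"chrom": chrom, "arm": chrom + "p",
                     "start": 1, "end": ARM_LENGTH})
        rows.append({"chrom": chrom, "arm": chrom + "q",
                     "start": ARM_LENGTH + 1, "end": 2 * ARM_LENGTH})
    return pd.DataFrame(rows)


def simulate_cnv(cfg: SimConfig) -> tuple[SegmentTable, pd.DataFrame]:
    """Segment tables with N(0, 0.1) background, planted ±1.5 arm events and
    planted ±2 focal 1-Mb peaks.  Returns (segments, per-sample event truth)."""
    rng = np.random.default_rng([cfg.seed, _CNV])
    genome = toy_genome()
    samples = _sample_ids(cfg.n_samples)
    arm_hits = {ev[0]: rng.random(cfg.n_samples) < ev[2]
                for ev in cfg.planted_arm_events}
    focal_hits = {i: rng.random(cfg.n_samples) < ev[4]
                  for i, ev in enumerate(cfg.planted_focal_peaks)}
    records = []
    truth_rows = []
    for si, sample in enumerate(samples):
        for chrom in CONTIGS:
            # fixed partition: arm boundaries plus any focal windows on this chrom
            cuts = {1, ARM_LENGTH + 1, 2 * ARM_LENGTH + 1}
            for (fc, fs, fe, _eff, _fr) in cfg.planted_focal_peaks:
                if fc == chrom:
                    cuts.update((fs, fe + 1))
            cuts = sorted(cuts)
            for a, b in zip(cuts[:-1], cuts[1:]):
                start, end = a, b - 1
                value = rng.normal(0.0, 0.1)
                for (arm, eff, _fr) in cfg.planted_arm_events:
                    row = genome[genome["arm"] == arm]
                    if len(row) and row.iloc[0]["chrom"] == chrom and arm_hits[arm][si]:
                        if start >= row.iloc[0]["start"] and end <= row.iloc[0]["end"]:
                            value += eff
                for i, (fc, fs, fe, eff, _fr) in enumerate(cfg.planted_focal_peaks):
                    if fc == chrom and focal_hits[i][si] and start >= fs and end <= fe:
                        value += eff
                records.append({"Sample": sample, "Chromosome": chrom,
                                "Start": start, "End": end,
                                "Segment_Mean": round(float(value), 6)})
        truth_rows.append({
            "sample": sample,
            **{f"arm_{arm}": bool(arm_hits[arm][si]) for arm in arm_hits},
            **{f"focal_{cfg.planted_focal_peaks[i][0]}:{cfg.planted_focal_peaks[i][1]}":
               bool(focal_hits[i][si]) for i in focal_hits},
        })
    segs = SegmentTable(pd.DataFrame.from_records(records))
    truth = pd.DataFrame(truth_rows).set_index("sample")
    return segs, truth
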