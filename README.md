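# tmepipe

Characterizing the tumor microenvironment (TME) from bulk tumor molecular
data.  Head-and-neck and other solid-tumor cohorts respond very unevenly to
immune-checkpoint therapy, and the composition of the infiltrating immune
compartment — not just the tumor's mutation burden — carries much of the
signal.  `tmepipe` is a tested, reusable implementation of a complete
TME-characterization workflow for researchers who have a bulk RNA-seq
expression matrix, survival data, somatic mutations and copy-number
segments for a cohort:

1. **Immune-cell deconvolution** — per-sample fractions of 22 leukocyte
   subsets by linear-kernel ν-SVR against an LM22-style signature matrix
   (ν ∈ {0.25, 0.5, 0.75}, simplex-projected coefficients, permutation p).
2. **Infiltration-pattern clusters** — Monti-style consensus clustering of
   the fraction matrix (1000 subsample/recluster rounds per K), with K
   chosen where the relative gain in consensus-CDF area
   Δ(K) = (A(K) − A(K−1))/A(K−1) last exceeds 0.1.
3. **Differential expression** — voom-style log-CPM and empirical-Bayes
   moderated t-tests between clusters (validated against R limma to ~1e-6);
   DEGs called at p < 1e-3 and |log2FC| > 1, "common" DEGs = significant in
   ≥ 2 of the 3 pairwise contrasts.
4. **TME score** — random-forest reduction of the common DEGs, consensus
   gene clusters, per-cluster PC1 signature scores *s_c*, prognostic
   direction by univariate Cox, and

   `TME score = Σ_{c favourable} s_c − Σ_{c unfavourable} s_c`,

   dichotomized at the maximally selected rank statistic (max standardized
   log-rank over candidate cutpoints, permutation p).
5. **Survival statistics** — Kaplan–Meier, log-rank, Cox PH (Breslow ties)
   from first principles; tumor–immune cell interaction network; ROC/AUC
   with DeLong comparison of the TME score against tumor mutation burden.
6. **Mutational signatures** — 96-trinucleotide-context catalogues,
   automatic-relevance-determination NMF (half-normal priors, a = 10,
   tolerance 1e-7) with cosine matching to a reference signature set,
   exposure clustering, and APOBEC TCW enrichment (enriched ⇔ E > 2).
7. **Copy number** — arm-level gain/loss frequencies (|value| > 1 over
   ≥ 50% of the arm) and GISTIC-like per-bin G-scores with a cyclic-shift
   permutation null, BH q-values and peak calling.

A synthetic-cohort generator (`tmepipe.synthetic`) produces expression,
survival, MAF and SEG inputs with planted infiltration patterns, hazard
ratios, mutational signatures and copy-number events, so the entire
pipeline runs and is tested end-to-end with no external data.  See
`docs/methods.md` for models, assumptions and parameter rationale.

## Worked example

Run the full workflow on a 120-sample synthetic cohort:

```bash
tmepipe run --seed 7 --out demo/
```

or from Python:

```python
from tmepipe.pipeline import run_all
manifest = run_all({"seed": 7, "n_samples": 120}, "demo/")
print(manifest["summary"])
```

which prints (abbreviated):

```
"chosen_K": 3,
"cluster_sizes": {"1": 46, "3": 39, "2": 35},
"cluster_logrank_p": 1.08e-06,
"deg_counts": {"1v2": 331, "1v3": 329, "2v3": 312},
"n_common_degs": 471,
"tme_group_sizes": {"low": 87, "high": 33},
"maxstat_p": 0.0050,
"cox_hr_low_vs_high": 3.36,
"auc_tme_score": 0.594, "auc_tmb": 0.490, "delong_p": 0.309,
"n_signatures": 3,
"signature_matches": {"Sig1": "Signature 1", "Sig2": "Signature 11",
                      "Sig3": "Signature 2"},
"n_apobec_enriched": 30,
"n_cnv_peaks": 4
```

Reading this: consensus clustering recovered the generator's three planted
infiltration patterns (`chosen_K: 3`) and they separate survival strongly
(log-rank p ≈ 1e-6).  The TME score built from 471 common DEGs splits the
cohort at the maxstat cutpoint into 87 low / 33 high samples; the low-score
group carries 3.4-fold excess hazard, i.e. a high TME score is protective —
the direction the workflow is designed to expose.  Three mutational
signatures were extracted (matching the CpG-deamination-like and
APOBEC-like entries of the bundled reference), 30 of 120 samples are
APOBEC-enriched (the generator plants ~25%), and all four planted
copy-number events (two arm-level, two focal) are called as peaks.

Every output is also written as TSV next to a `run_manifest.json` with
per-stage seeds, wall times and output hashes; rerunning with the same
seed reproduces every hash.

Module-level subcommands (`tmepipe simulate | deconvolve | cluster | dge |
tmescore | enrich | mutsig | cnv`) expose each stage on its own files; the
library functions accept and return pandas objects throughout.

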