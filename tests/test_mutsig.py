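import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from tmepipe.io_core import MutationTable, ValidationError
from tmepipe.mutsig import (
    CONTEXTS_96,
    MutCatalogue,
    apobec_enrichment,
    build_catalogue,
    cluster_exposures,
    collapse_to_pyrimidine,
    compute_tmb,
    context_category,
    cosine_match,
    cosine_similarity,
    extract_signatures,
    load_reference_signatures,
    revcomp,
)


def maf_from(rows):
    base = {
        "Tumor_Sample_Barcode": "S1", "Chromosome": "chr1",
        "Start_Position": 0, "Variant_Classification": "Missense_Mutation",
    }
    recs = []
    for i, r in enumerate(rows):
        rec = dict(base)
        rec.update(r)
        rec["Start_Position"] = i + 1
        recs.append(rec)
    return MutationTable(pd.DataFrame.from_records(recs))


class TestCatalogue:
    def test_purine_record_reverse_complemented(self):
        # G>A in context TGA collapses to C>T in context TCA
        assert context_category("G", "A", "TGA") == "T[C>T]A"

    def test_collapse_idempotent(self):
        for ref, alt, ctx in [("G", "A", "TGA"), ("C", "T", "TCA"),
                              ("A", "C", "CAG"), ("T", "G", "ATT")]:
            once = collapse_to_pyrimidine(ref, alt, ctx)
            twice = collapse_to_pyrimidine(*once)
            assert once == twice

    def test_catalogue_always_96_categories(self):
        muts = maf_from([
            {"Reference_Allele": "C", "Tumor_Seq_Allele2": "T", "CONTEXT": "ACA"},
        ])
        cat = build_catalogue(muts)
        assert cat.counts.shape[1] == 96
        assert tuple(cat.counts.columns) == CONTEXTS_96

    def test_hand_tallied_ten_record_maf(self):
        rows = [
            {"Reference_Allele": "C", "Tumor_Seq_Allele2": "T", "CONTEXT": "TCA"},
            {"Reference_Allele": "C", "Tumor_Seq_Allele2": "T", "CONTEXT": "TCA"},
            {"Reference_Allele": "G", "Tumor_Seq_Allele2": "A", "CONTEXT": "TGA"},
            {"Reference_Allele": "C", "Tumor_Seq_Allele2": "A", "CONTEXT": "ACG"},
            {"Reference_Allele": "T", "Tumor_Seq_Allele2": "G", "CONTEXT": "ATC"},
            {"Reference_Allele": "A", "Tumor_Seq_Allele2": "C", "CONTEXT": "GAT"},
            {"Reference_Allele": "C", "Tumor_Seq_Allele2": "G", "CONTEXT": "TCT"},
            {"Reference_Allele": "G", "Tumor_Seq_Allele2": "C", "CONTEXT": "AGA"},
            {"Reference_Allele": "T", "Tumor_Seq_Allele2": "C", "CONTEXT": "CTG"},
            {"Reference_Allele": "A", "Tumor_Seq_Allele2": "-", "CONTEXT": ""},
        ]
        cat = build_catalogue(maf_from(rows)).counts.iloc[0]
        # rc(TGA)=TCA so records 1-3 pile on T[C>T]A
        assert cat["T[C>T]A"] == 3
        assert cat["A[C>A]G"] == 1
        # T>G at ATC, and A>C at GAT whose rc is T>G at ATC as well
        assert cat["A[T>G]C"] == 2
        assert cat["T[C>G]T"] == 2          # C>G at TCT plus rc of G>C at AGA
        assert cat["C[T>C]G"] == 1
        assert cat.sum() == 9  # indel skipped

    def test_missing_context_column_fatal(self):
        df = pd.DataFrame([{
            "Tumor_Sample_Barcode": "S1", "Chromosome": "chr1",
            "Start_Position": 1, "Reference_Allele": "C",
            "Tumor_Seq_Allele2": "T",
            "Variant_Classification": "Missense_Mutation",
        }])
        with pytest.raises(ValidationError, match="CONTEXT"):
            build_catalogue(MutationTable(df))


class TestExtraction:
    def _disjoint_pair(self):
        rng = np.random.default_rng(0)
        w1 = np.zeros(96)
        w1[:48] = rng.dirichlet(np.ones(48) * 0.5)
        w2 = np.zeros(96)
        w2[48:] = rng.dirichlet(np.ones(48) * 0.5)
        H = rng.uniform(50, 300, (2, 30))
        H[0, :6] = 0.0
        H[1, 6:12] = 0.0  # scattered exposures make the factorization unique
        return w1, w2, H

    def test_exactly_factorizable_recovered(self):
        w1, w2, H = self._disjoint_pair()
        V = np.c_[w1, w2] @ H
        cat = MutCatalogue(pd.DataFrame(
            V.T, index=[f"s{i}" for i in range(30)], columns=list(CONTEXTS_96)))
        d = extract_signatures(cat, n_restarts=10, seed=1)
        assert d.chosen_k == 2
        for w in (w1, w2):
            best = max(cosine_similarity(d.W[c].to_numpy(), w) for c in d.W.columns)
            assert best >= 0.99

    def test_single_signature_rank_one(self):
        w1, _, _ = self._disjoint_pair()
        rng = np.random.default_rng(1)
        V = np.outer(w1, rng.uniform(100, 200, 10))
        cat = MutCatalogue(pd.DataFrame(
            V.T, index=[f"r{i}" for i in range(10)], columns=list(CONTEXTS_96)))
        d = extract_signatures(cat, n_restarts=5, seed=2)
        assert d.chosen_k == 1
        assert cosine_similarity(d.W.iloc[:, 0].to_numpy(), w1) > 0.999

    def test_w_columns_sum_to_one_and_counts_conserved(self):
        w1, w2, H = self._disjoint_pair()
        V = np.c_[w1, w2] @ H
        cat = MutCatalogue(pd.DataFrame(
            np.round(V).T, index=[f"s{i}" for i in range(30)],
            columns=list(CONTEXTS_96)))
        d = extract_signatures(cat, n_restarts=5, seed=3)
        np.testing.assert_allclose(d.W.sum(0), 1.0, atol=1e-9)
        recon_total = (d.W.to_numpy() @ d.H.to_numpy()).sum()
        assert recon_total == pytest.approx(cat.counts.to_numpy().sum(), rel=0.02)

    def test_plain_method_runs(self):
        w1, w2, H = self._disjoint_pair()
        V = np.c_[w1, w2] @ H
        cat = MutCatalogue(pd.DataFrame(
            V.T, index=[f"s{i}" for i in range(30)], columns=list(CONTEXTS_96)))
        d = extract_signatures(cat, k_range=range(1, 5), method="plain", seed=0)
        assert d.chosen_k >= 2

    def test_too_few_samples_or_mutations_rejected(self):
        cat = MutCatalogue(pd.DataFrame(
            np.ones((1, 96)), index=["s"], columns=list(CONTEXTS_96)))
        with pytest.raises(ValidationError):
            extract_signatures(cat)


class TestCosine:
    def test_identity_match(self):
        ref = load_reference_signatures()
        sub = ref.iloc[:, [0, 5, 12]].copy()
        sub.columns = ["a", "b", "c"]
        m = cosine_match(sub, ref)
        assert list(m["best_match"]) == [ref.columns[0], ref.columns[5],
                                         ref.columns[12]]
        np.testing.assert_allclose(m["cosine"], 1.0, atol=1e-12)

    def test_orthogonal_vectors_zero(self):
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 2.0])) == 0.0

    def test_three_element_hand_value(self):
        a = np.array([1.0, 2.0, 2.0])
        b = np.array([2.0, 1.0, 2.0])
        assert cosine_similarity(a, b) == pytest.approx(8 / 9)

    def test_bundled_reference_shape(self):
        ref = load_reference_signatures()
        assert ref.shape == (96, 30)
        np.testing.assert_allclose(ref.sum(0), 1.0, atol=1e-3)


class TestExposureClusters:
    def test_pure_exposures_cluster_perfectly(self):
        H = pd.DataFrame(np.zeros((2, 20)),
                         index=["SigA", "SigB"],
                         columns=[f"s{i}" for i in range(20)])
        H.iloc[0, :10] = 100.0
        H.iloc[1, 10:] = 80.0
        out = cluster_exposures(H, seed=0)
        a = set(out.iloc[:10]["cluster"])
        b = set(out.iloc[10:]["cluster"])
        assert len(a) == 1 and len(b) == 1 and a != b
        assert out.iloc[0]["top_signature"] == "SigA"
        assert out.iloc[-1]["top_signature"] == "SigB"

    def test_mixed_sample_joins_majority_signature(self):
        H = pd.DataFrame(np.zeros((2, 21)), index=["SigA", "SigB"],
                         columns=[f"s{i}" for i in range(21)])
        H.iloc[0, :10] = 100.0
        H.iloc[1, 10:20] = 80.0
        H.iloc[0, 20] = 70.0
        H.iloc[1, 20] = 30.0
        out = cluster_exposures(H, seed=0)
        assert out.loc["s20", "cluster"] == out.loc["s0", "cluster"]

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        H = pd.DataFrame(rng.uniform(0, 100, (3, 30)),
                         index=["a", "b", "c"],
                         columns=[f"s{i}" for i in range(30)])
        assert cluster_exposures(H, seed=4).equals(cluster_exposures(H, seed=4))


class TestAPOBEC:
    def _window(self, n_tcw, n_other_c):
        """Window with an exact both-strand TCW and cytosine census.

        TCA blocks carry one TCW (and one C); AACAA blocks one C, no TCW;
        padding is A/T only.
        """
        return "TT" + "TCATT" * n_tcw + "AACAA" * n_other_c + "TT"

    def test_hand_computed_enrichment(self):
        # every mutation at TCW; background windows: 1 TCW per 4 cytosines
        win = self._window(1, 3)  # 1 TCW, 4 C total per window
        rows = []
        for i in range(5):
            rows.append({
                "Tumor_Sample_Barcode": "S1", "Chromosome": "chr1",
                "Start_Position": i + 1, "Reference_Allele": "C",
                "Tumor_Seq_Allele2": "T",
                "Variant_Classification": "Missense_Mutation",
                "CONTEXT": "TCA", "CONTEXT41": win,
            })
        muts = MutationTable(pd.DataFrame.from_records(rows))
        res = apobec_enrichment(muts, flank=len(win) // 2)
        # E = (5/5) / (5/20) = 4
        assert res.loc["S1", "enrichment"] == pytest.approx(4.0)
        assert res.loc["S1", "apobec_class"] == "enriched"
        table = [[5, 0], [5, 15]]
        assert res.loc["S1", "fisher_p"] == pytest.approx(
            fisher_exact(table, alternative="greater")[1])

    def test_no_tcw_mutations_scores_zero(self):
        win = self._window(1, 3)
        rows = [{
            "Tumor_Sample_Barcode": "S1", "Chromosome": "chr1",
            "Start_Position": 1, "Reference_Allele": "C",
            "Tumor_Seq_Allele2": "T",
            "Variant_Classification": "Missense_Mutation",
            "CONTEXT": "ACG", "CONTEXT41": win,
        }]
        res = apobec_enrichment(MutationTable(pd.DataFrame.from_records(rows)),
                                flank=len(win) // 2)
        assert res.loc["S1", "enrichment"] == 0.0
        assert res.loc["S1", "apobec_class"] == "non-enriched"

    def test_ct_only_mode_ignores_cg_mutations(self):
        win = self._window(1, 3)
        rows = [{
            "Tumor_Sample_Barcode": "S1", "Chromosome": "chr1",
            "Start_Position": 1, "Reference_Allele": "C",
            "Tumor_Seq_Allele2": "G",
            "Variant_Classification": "Missense_Mutation",
            "CONTEXT": "TCA", "CONTEXT41": win,
        }]
        res = apobec_enrichment(MutationTable(pd.DataFrame.from_records(rows)),
                                subs="ct", flank=len(win) // 2)
        assert res.loc["S1", "mut_c"] == 0

    def test_missing_context41_fatal(self):
        muts = maf_from([{"Reference_Allele": "C", "Tumor_Seq_Allele2": "T",
                          "CONTEXT": "TCA"}])
        with pytest.raises(ValidationError, match="CONTEXT41"):
            apobec_enrichment(muts)


class TestTMB:
    def _records(self):
        rows = []
        for i in range(19):
            rows.append({"Reference_Allele": "C", "Tumor_Seq_Allele2": "T",
                         "CONTEXT": "TCA",
                         "Variant_Classification": "Missense_Mutation"})
        for i in range(6):
            rows.append({"Reference_Allele": "C", "Tumor_Seq_Allele2": "T",
                         "CONTEXT": "TCA", "Variant_Classification": "Silent"})
        return maf_from(rows)

    def test_nineteen_nonsilent_of_twentyfive(self):
        tmb = compute_tmb(self._records())
        assert tmb.loc["S1", "n_nonsilent"] == 19
        assert tmb.loc["S1", "tmb_per_mb"] == pytest.approx(0.5)

    def test_silent_only_sample_zero(self):
        rows = [{"Reference_Allele": "C", "Tumor_Seq_Allele2": "T",
                 "CONTEXT": "TCA", "Variant_Classification": "Silent"}]
        tmb = compute_tmb(maf_from(rows))
        assert tmb.loc["S1", "n_nonsilent"] == 0


def test_revcomp():
    assert revcomp("TGA") == "TCA"
    assert revcomp(revcomp("ACGT")) == "ACGT"
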