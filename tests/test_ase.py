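"""Allele-specific expression: counting, exact binomial testing and
dominance classification."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from hybridscope import count_alleles, test_bias, dominance_summary


def depth_rows(rows):
    return pd.DataFrame(rows, columns=["gene_id", "replicate", "pat_count", "mat_count"])


def counts_for(gene_counts, n_reps=3):
    """gene -> (pat, mat), replicated identically across n_reps."""
    rows = []
    for gene, (pat, mat) in gene_counts.items():
        for r in range(1, n_reps + 1):
            rows.append((gene, f"rep{r}", pat, mat))
    return depth_rows(rows)


def binom_two_sided_oracle(k, n):
    """Tail enumeration: sum of P(X=i) over all i with P(X=i) <= P(X=k)."""
    probs = [comb(n, i) * 0.5 ** n for i in range(n + 1)]
    pk = probs[k]
    return sum(p for p in probs if p <= pk * (1 + 1e-12))


class TestCountAlleles:
    def test_counts_are_additive_over_snps(self):
        depths = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "pos": [10, 20],
                "replicate": ["rep1", "rep1"],
                "pat_count": [10, 5],
                "mat_count": [3, 2],
            }
        )
        diag = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [10, 20], "gene_id": ["geneA", "geneA"]})
        out = count_alleles(depths, diag)
        assert out.loc[0, ["pat_count", "mat_count"]].tolist() == [15, 5]

    def test_unmatched_rows_skipped_and_empty_input(self):
        depths = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [999], "replicate": ["rep1"], "pat_count": [4], "mat_count": [4]}
        )
        diag = pd.DataFrame({"chrom": ["chr1"], "pos": [10], "gene_id": ["geneA"]})
        assert count_alleles(depths, diag).empty
        assert count_alleles(depths.iloc[0:0], diag).empty


class TestBias:
    def test_exact_binomial_p_matches_enumeration_oracle(self):
        res = test_bias(counts_for({"g": (20, 5)}))
        p = res.per_replicate["p"].iloc[0]
        assert p == pytest.approx(binom_two_sided_oracle(20, 25), abs=1e-12)
        assert p == pytest.approx(0.004077315, abs=1e-9)  # verified against R binom.test
        # alone in its test set, q = p <= 0.01 and ratio 4 in every replicate
        assert res.calls["classification"].iloc[0] == "paternal"

    def test_symmetric_counts_are_unbiased(self):
        res = test_bias(counts_for({"g": (30, 30)}))
        assert (res.per_replicate["ratio"] == 1.0).all()
        assert res.calls["classification"].iloc[0] == "unbiased"

    def test_ratio_gate_overrides_significance(self):
        # 1.5-fold is below the 2-fold gate regardless of q
        res = test_bias(counts_for({"g": (150, 100)}))
        assert res.calls["classification"].iloc[0] == "unbiased"

    def test_low_coverage_gene_is_flagged_not_classified(self):
        res = test_bias(counts_for({"g": (6, 0)}), min_total=10)
        assert res.calls["low_coverage"].iloc[0]
        assert res.calls["classification"].iloc[0] == "unbiased"

    def test_zero_maternal_count_gives_infinite_ratio(self):
        res = test_bias(counts_for({"g": (15, 0)}))
        assert np.isinf(res.per_replicate["ratio"]).all()
        assert res.calls["classification"].iloc[0] == "paternal"

    def test_label_swap_antisymmetry(self):
        counts = counts_for({"g1": (40, 8), "g2": (5, 44), "g3": (20, 22)})
        swapped = counts.rename(columns={"pat_count": "mat_count", "mat_count": "pat_count"})
        res = test_bias(counts)
        res_sw = test_bias(swapped)
        flip = {"paternal": "maternal", "maternal": "paternal", "unbiased": "unbiased"}
        got = dict(zip(res_sw.calls["gene_id"], res_sw.calls["classification"]))
        for gene, cls in zip(res.calls["gene_id"], res.calls["classification"]):
            assert got[gene] == flip[cls]

    def test_q_values_nondecreasing_in_p_rank(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(50):
            n = 40
            k = int(rng.binomial(n, 0.5 + 0.3 * (i % 2)))
            rows.append((f"g{i}", "rep1", k, n - k))
        res = test_bias(depth_rows(rows))
        per = res.per_replicate.sort_values("p")
        assert per["q"].is_monotonic_increasing

    def test_one_failing_replicate_blocks_the_call(self):
        rows = [("g", "rep1", 40, 5), ("g", "rep2", 40, 5), ("g", "rep3", 21, 20)]
        res = test_bias(depth_rows(rows))
        assert res.calls["classification"].iloc[0] == "unbiased"

    def test_per_replicate_q_mode_is_stricter(self):
        # marginal per-replicate evidence that pools into strong evidence:
        # pooled q passes, per-replicate q does not
        counts = counts_for({"g": (17, 5)})
        pooled = test_bias(counts, q_mode="pooled")
        strict = test_bias(counts, q_mode="per_replicate")
        assert pooled.calls["classification"].iloc[0] == "paternal"
        assert strict.calls["classification"].iloc[0] == "unbiased"

    def test_null_false_bias_rate_at_most_alpha(self):
        """200 unbiased genes, 3 replicates at depth 60: the fraction
        classified biased must not exceed the q-level 0.01."""
        rng = np.random.default_rng(42)
        rows = []
        for i in range(200):
            for r in range(1, 4):
                n = rng.poisson(60)
                k = rng.binomial(n, 0.5)
                rows.append((f"g{i}", f"rep{r}", k, n - k))
        res = test_bias(depth_rows(rows))
        frac = (res.calls["classification"] != "unbiased").mean()
        assert frac <= 0.01

    def test_recovery_on_synthetic_cross(self, cross, diagnostics, allele_depths):
        """At the reference conditions, planted-biased genes are recovered
        with sensitivity >= 0.9 and null genes miscalled at <= 0.05."""
        counts = count_alleles(allele_depths, diagnostics)
        res = test_bias(counts)
        truth = cross["truth"].biased_genes
        calls = dict(zip(res.calls["gene_id"], res.calls["classification"]))
        planted = [g for g, lab in truth.items() if lab != "none"]
        nulls = [g for g, lab in truth.items() if lab == "none"]
        sens = np.mean([calls.get(g) == truth[g] for g in planted])
        fpr = np.mean([calls.get(g, "unbiased") != "unbiased" for g in nulls])
        assert sens >= 0.9
        assert fpr <= 0.05


class TestDominance:
    def test_partition_sums_to_shared_total(self):
        bias_p = pd.DataFrame({"gene_id": ["a", "b", "c"], "classification": ["paternal"] * 3})
        bias_m = pd.DataFrame({"gene_id": ["A", "B", "C"], "classification": ["paternal"] * 3})
        orthologs = pd.DataFrame({"paternal_gene": ["a", "b", "c"], "maternal_gene": ["A", "B", "C"]})
        degs = {
            "muscle": pd.DataFrame({"gene_id": ["a", "b", "c"], "status": ["up", "up", "down"]}),
        }
        out = dominance_summary(bias_p, bias_m, degs, orthologs)
        part = out["shared_partition"]
        assert part["up"] + part["down"] + part["mixed"] == out["shared_bias_degs"] == 3
        assert (part["up"], part["down"], part["mixed"]) == (2, 1, 0)

    def test_empty_paternal_bias_set_flags_comparison_undefined(self):
        empty_bias = pd.DataFrame({"gene_id": [], "classification": []})
        degs = {"muscle": pd.DataFrame({"gene_id": ["a"], "status": ["up"]})}
        fpkm = pd.Series({"a": 10.0})
        out = dominance_summary(empty_bias, empty_bias, degs, None, fpkm=fpkm)
        assert out["expression_comparison"]["defined"] is False
        assert out["shared_bias_degs"] == 0

    def test_synthetic_cross_paternal_dominance(self, cross, diagnostics, allele_depths):
        """With more paternal- than maternal-biased genes planted among the
        same DEG universe, the paternal bias-DEG count must exceed the
        maternal one."""
        config = cross["config"]
        truth = cross["truth"].biased_genes
        counts = count_alleles(allele_depths, diagnostics)
        res = test_bias(counts)
        degs = {
            "tissue": pd.DataFrame({"gene_id": list(truth), "status": "up"})
        }
        out = dominance_summary(res.calls, res.calls.iloc[0:0], degs, None)
        tissue = out["per_tissue"]["tissue"]
        n_pat_truth = sum(1 for v in truth.values() if v == "paternal")
        n_mat_truth = sum(1 for v in truth.values() if v == "maternal")
        if n_pat_truth > n_mat_truth:
            assert tissue["paternal_bias_degs"] > tissue["maternal_bias_degs"]
        else:  # default config plants equal fractions; counts must be close
            assert abs(tissue["paternal_bias_degs"] - tissue["maternal_bias_degs"]) <= max(
                5, 0.2 * n_pat_truth
            )
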