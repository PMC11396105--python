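"""Methylation levels, methylcytosine calling and differential calling."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from hybridscope import (
    call_methylcytosines,
    pooled_level,
    methylation_levels,
    region_levels,
    call_dmrs,
    call_dmcs,
    annotate_dmr_genes,
)
from hybridscope.methylation import _fisher_cached


def sites_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "count_M", "count_U"])


def window_sites(chrom, start, context, n_sites, m, u, spacing=10):
    """n_sites cytosines inside the 200-bp tile starting at `start`,
    each with (m, u) counts."""
    return sites_df(
        [(chrom, start + 1 + i * spacing, "+", context, m, u) for i in range(n_sites)]
    )


def fisher_oracle(ma, ua, mb, ub):
    """Hypergeometric enumeration: two-sided Fisher p is the sum of the
    probabilities of all tables (with the same margins) no more likely
    than the observed one."""
    n = ma + ua + mb + ub
    K = ma + mb  # total methylated
    n1 = ma + ua
    p_obs = hypergeom.pmf(ma, n, K, n1)
    ks = np.arange(max(0, K - (n - n1)), min(K, n1) + 1)
    probs = hypergeom.pmf(ks, n, K, n1)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


class TestCallMethylcytosines:
    def test_fully_methylated_site_has_tiny_p(self):
        out = call_methylcytosines(sites_df([("c", 1, "+", "CG", 10, 0)]), conversion_error=0.01)
        assert out["p"].iloc[0] == pytest.approx(0.01 ** 10, rel=1e-9)
        assert out["methylated"].iloc[0]

    def test_unmethylated_site_has_p_one(self):
        out = call_methylcytosines(sites_df([("c", 1, "+", "CG", 0, 50)]))
        assert out["p"].iloc[0] == 1.0
        assert not out["methylated"].iloc[0]

    def test_single_methylated_read_matches_survival_oracle(self):
        out = call_methylcytosines(sites_df([("c", 1, "+", "CG", 1, 99)]), conversion_error=0.01)
        # P(X >= 1 | n=100, p=0.01) = 1 - 0.99^100
        assert out["p"].iloc[0] == pytest.approx(1 - 0.99 ** 100, rel=1e-9)
        assert out["p"].iloc[0] == pytest.approx(0.634, abs=5e-4)
        assert not out["methylated"].iloc[0]

    def test_zero_coverage_site_is_unevaluated(self):
        out = call_methylcytosines(sites_df([("c", 1, "+", "CG", 0, 0)]))
        assert out["unevaluated"].iloc[0]
        assert np.isnan(out["p"].iloc[0])

    def test_invalid_conversion_error_rejected(self):
        with pytest.raises(ValueError):
            call_methylcytosines(sites_df([]), conversion_error=0.0)


class TestLevels:
    def test_pooling_is_coverage_weighted(self):
        s = sites_df([("c", 1, "+", "CG", 3, 1), ("c", 11, "+", "CG", 1, 3)])
        assert pooled_level(s) == pytest.approx(0.5)

    def test_fully_methylated_gives_level_one(self):
        s = sites_df([("c", p, "+", ctx, 5, 0) for p, ctx in [(1, "CG"), (11, "CHH")]])
        lv = methylation_levels(s, by=("context",))
        assert (lv["level"] == 1.0).all()

    def test_uncovered_group_absent_not_zero(self):
        s = sites_df([("c", 1, "+", "CG", 3, 1), ("c", 11, "+", "CHH", 0, 0)])
        lv = methylation_levels(s, by=("context",))
        assert lv["context"].tolist() == ["CG"]

    def test_genome_level_matches_binomial_oracle(self, null_methylome):
        a, _ = null_methylome
        cg = a[a["context"] == "CG"]
        assert pooled_level(cg) == pytest.approx(0.8, abs=0.02)


class TestDmrCalls:
    def test_strong_window_called_with_fisher_oracle_p(self):
        # CG window: A pooled 45 M / 5 U vs B pooled 20 M / 30 U over 5 sites
        a = window_sites("c", 200, "CG", 5, 9, 1)
        b = window_sites("c", 200, "CG", 5, 4, 6)
        out = call_dmrs(a, b)
        cg = out[out["context"] == "CG"].iloc[0]
        assert cg["delta"] == pytest.approx(0.5)
        assert cg["p"] == pytest.approx(fisher_oracle(45, 5, 20, 30), rel=1e-9)
        assert cg["p"] == pytest.approx(1.958312e-7, rel=1e-5)  # verified against R fisher.test
        assert cg["status"] == "hyper"

    def test_window_with_too_few_sites_is_ineligible(self):
        a = window_sites("c", 200, "CG", 4, 10, 0)
        b = window_sites("c", 200, "CG", 4, 0, 10)
        out = call_dmrs(a, b)
        cg = out[out["context"] == "CG"]
        assert (cg["status"] == "none").all()

    def test_context_specific_delta_thresholds(self):
        # delta = 0.20: eligible for CHH (>= 0.15) but not CG (>= 0.25)
        a_chh = window_sites("c", 0, "CHH", 15, 8, 12, spacing=13)
        b_chh = window_sites("c", 0, "CHH", 15, 4, 16, spacing=13)
        out = call_dmrs(a_chh, b_chh)
        chh = out[out["context"] == "CHH"].iloc[0]
        assert chh["delta"] == pytest.approx(0.2)
        assert chh["status"] == "hyper"

        a_cg = window_sites("c", 0, "CG", 15, 8, 12, spacing=13)
        b_cg = window_sites("c", 0, "CG", 15, 4, 16, spacing=13)
        cg = call_dmrs(a_cg, b_cg)
        cg_row = cg[cg["context"] == "CG"].iloc[0]
        assert cg_row["status"] == "none"  # same counts, stricter CG threshold

    def test_low_coverage_sites_excluded(self):
        a = window_sites("c", 0, "CG", 5, 2, 1)  # coverage 3 < 4
        b = window_sites("c", 0, "CG", 5, 1, 2)
        out = call_dmrs(a, b)
        assert out.empty

    def test_group_swap_antisymmetry(self):
        a = window_sites("c", 200, "CG", 6, 9, 1)
        b = window_sites("c", 200, "CG", 6, 3, 7)
        fwd = call_dmrs(a, b)
        rev = call_dmrs(b, a)
        merged = fwd.merge(rev, on=["chrom", "start", "context"], suffixes=("_f", "_r"))
        assert np.allclose(merged["delta_f"], -merged["delta_r"])
        assert np.allclose(merged["p_f"], merged["p_r"])
        flip = {"hyper": "hypo", "hypo": "hyper", "none": "none"}
        assert (merged["status_r"] == merged["status_f"].map(flip)).all()

    def test_pooled_level_identity_with_levels_function(self):
        a = window_sites("c", 0, "CG", 5, 7, 3)
        b = window_sites("c", 0, "CG", 5, 5, 5)
        out = call_dmrs(a, b)
        cg = out[out["context"] == "CG"].iloc[0]
        assert cg["level_a"] == pytest.approx(pooled_level(a))
        assert cg["level_b"] == pytest.approx(pooled_level(b))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_fisher_equals_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            ma, ua, mb, ub = rng.integers(0, 51, size=4)
            got = _fisher_cached(int(ma), int(ua), int(mb), int(ub))
            assert got == pytest.approx(fisher_oracle(ma, ua, mb, ub), rel=1e-8, abs=1e-12)

    def test_type_i_error_controlled_on_null(self, null_methylome):
        a, b = null_methylome
        out = call_dmrs(a, b)
        assert len(out) >= 2000
        rate = (out["status"] != "none").mean()
        assert rate <= 0.05

    def test_planted_dmrs_recovered(self, cross, dmr_calls):
        planted = cross["truth"].dmr_windows
        called = dmr_calls[dmr_calls["status"] != "none"]
        hits = 0
        for chrom, start, end, context, direction in planted:
            ov = called[
                (called["chrom"] == chrom)
                & (called["start"] < end)
                & (called["end"] > start)
                & (called["context"] == context)
            ]
            if len(ov):
                assert (ov["status"] == direction).all()
                hits += 1
        assert hits / len(planted) >= 0.9


class TestDmcCalls:
    def test_opposite_extreme_sites_called(self):
        a = sites_df([("c", 1, "+", "CG", 20, 0)])
        b = sites_df([("c", 1, "+", "CG", 0, 20)])
        out = call_dmcs(a, b)
        row = out.iloc[0]
        assert row["delta"] == pytest.approx(1.0)
        assert row["status"] == "hyper"
        assert row["p"] == pytest.approx(fisher_oracle(20, 0, 0, 20), rel=1e-9)

    def test_identical_counts_not_called(self):
        a = sites_df([("c", 1, "+", "CG", 10, 10)])
        out = call_dmcs(a, a.copy())
        assert out["p"].iloc[0] == 1.0
        assert out["status"].iloc[0] == "none"

    def test_coverage_below_four_excluded(self):
        a = sites_df([("c", 1, "+", "CG", 3, 0)])
        b = sites_df([("c", 1, "+", "CG", 0, 20)])
        assert call_dmcs(a, b).empty


class TestAnnotation:
    models = pd.DataFrame(
        {
            "gene_id": ["geneA"],
            "chrom": ["c"],
            "strand": ["+"],
            "start": [10000],
            "end": [12000],
        }
    )

    def dmr(self, start):
        return pd.DataFrame(
            [{"chrom": "c", "start": start, "end": start + 200, "context": "CG",
              "n_sites": 5, "level_a": 0.3, "level_b": 0.8, "delta": -0.5,
              "p": 1e-9, "q": 1e-8, "status": "hypo"}]
        )

    def test_dmr_inside_gene_body(self):
        out = annotate_dmr_genes(self.dmr(10400), self.models)
        assert out["region"].tolist() == ["gene_body"]

    def test_dmr_one_bp_inside_upstream_boundary(self):
        # upstream region is [8000, 10000); window [7801, 8001) overlaps by 1 bp
        out = annotate_dmr_genes(self.dmr(7801), self.models)
        assert out["region"].tolist() == ["upstream2kb"]

    def test_dmr_beyond_flank_not_associated(self):
        out = annotate_dmr_genes(self.dmr(7300), self.models)  # 2.5 kb upstream
        assert out.empty

    def test_minus_strand_gene_swaps_flank_labels(self):
        minus = self.models.assign(strand="-")
        out = annotate_dmr_genes(self.dmr(12100), minus)
        assert out["region"].tolist() == ["upstream2kb"]
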