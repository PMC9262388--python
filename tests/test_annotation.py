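"""Enrichment, hyper-divergence overlap calls, and group comparisons."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mipmeter.annotation import (bonferroni_threshold, classify_hyperdivergent,
                                 hypergeom_enrichment, split_trait_by_group)
from mipmeter.errors import FormatError


def universe(N, K, n, k, category="dom"):
    """Background of N genes, K carrying ``category``; hit set of n genes with
    k carriers."""
    genes = [f"g{i}" for i in range(N)]
    bg = pd.DataFrame({"gene_id": genes,
                       "category": [category if i < K else "bg_only"
                                    for i in range(N)]})
    hits = genes[:k] + genes[K:K + (n - k)]
    assert len(hits) == n
    return bg, hits


def enumeration_p(N, K, n, k):
    """Exhaustive upper-tail hypergeometric probability via binomial counts."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / total


class TestHypergeomEnrichment:
    def test_single_case_against_hand_enumeration(self):
        # N=10, K=5, n=4, k=4: only C(5,4)=5 of C(10,4)=210 draws qualify
        bg, hits = universe(10, 5, 4, 4)
        res = hypergeom_enrichment(bg, hits, min_hit_count=1)
        dom = [r for r in res if r.category == "dom"][0]
        assert dom.p == pytest.approx(5 / 210)
        assert dom.fold == pytest.approx((4 / 4) / (5 / 10))

    def test_matches_exhaustive_enumeration_for_all_small_instances(self):
        for N in range(4, 13):
            for K in range(1, N):
                for n in range(1, N + 1):
                    for k in range(max(1, n - (N - K)), min(K, n) + 1):
                        bg, hits = universe(N, K, n, k)
                        res = hypergeom_enrichment(bg, hits, min_hit_count=1)
                        dom = [r for r in res if r.category == "dom"][0]
                        assert dom.p == pytest.approx(enumeration_p(N, K, n, k),
                                                      rel=1e-9), (N, K, n, k)

    def test_monotone_nonincreasing_in_hit_count(self):
        ps = [enumeration_p(12, 6, 5, k) for k in range(1, 6)]
        got = []
        for k in range(1, 6):
            bg, hits = universe(12, 6, 5, k)
            res = hypergeom_enrichment(bg, hits, min_hit_count=1)
            got.append([r for r in res if r.category == "dom"][0].p)
        assert got == sorted(got, reverse=True)
        assert np.allclose(got, ps)

    def test_saturated_draw_has_fold_one_and_p_one(self):
        bg, _ = universe(8, 3, 8, 3)
        res = hypergeom_enrichment(bg, list(bg["gene_id"]), min_hit_count=1)
        for r in res:
            assert r.fold == pytest.approx(1.0)
            assert r.p == pytest.approx(1.0)

    def test_low_count_categories_flagged_not_significant(self):
        bg, hits = universe(200, 5, 4, 4)
        res = hypergeom_enrichment(bg, hits, min_hit_count=5)
        dom = [r for r in res if r.category == "dom"][0]
        assert dom.filtered_low_count and not dom.significant
        assert dom.p < dom.alpha_bonferroni  # only the count filter blocked it

    def test_orphan_hits_warned_and_intersected(self):
        bg, hits = universe(10, 5, 4, 4)
        with pytest.warns(UserWarning, match="absent from background"):
            res = hypergeom_enrichment(bg, hits + ["ghost"], min_hit_count=1)
        assert res[0].n_hit == 4

    def test_bonferroni_divisor_is_categories_in_hit_set(self):
        # background has 3 categories but the hit genes only touch 2
        bg = pd.DataFrame({"gene_id": ["a", "b", "c", "d", "e", "f"],
                           "category": ["x", "x", "y", "y", "z", "z"]})
        res = hypergeom_enrichment(bg, ["a", "c"], min_hit_count=1)
        assert {r.category for r in res} == {"x", "y"}
        assert all(r.alpha_bonferroni == pytest.approx(0.05 / 2) for r in res)


class TestBonferroniThreshold:
    def test_102_categories_reports_0_00049(self):
        assert bonferroni_threshold(102) == 0.00049

    def test_full_precision_times_categories_is_alpha(self):
        for n in (1, 7, 102, 570):
            assert bonferroni_threshold(n, sig_figs=None) * n == pytest.approx(0.05)


class TestClassifyHyperdivergent:
    regions = pd.DataFrame([
        {"strain_id": "inside", "chrom": "V", "start": 100, "end": 500},
        {"strain_id": "adjacent", "chrom": "V", "start": 0, "end": 200},
        {"strain_id": "one_base", "chrom": "V", "start": 299, "end": 301},
        {"strain_id": "other_chrom", "chrom": "IV", "start": 100, "end": 500},
    ])
    locus = ("V", 200, 300)

    def test_overlap_calls(self):
        calls = classify_hyperdivergent(self.regions, self.locus)
        assert calls["inside"]          # locus fully inside region
        assert not calls["adjacent"]    # half-open: end == locus start
        assert calls["one_base"]        # single-base overlap counts
        assert not calls["other_chrom"]

    def test_agrees_with_base_set_intersection_oracle(self):
        rng = np.random.default_rng(12)
        rows = [{"strain_id": f"s{i}", "chrom": "V",
                 "start": int(a), "end": int(a + w)}
                for i, (a, w) in enumerate(zip(rng.integers(0, 400, 40),
                                               rng.integers(1, 120, 40)))]
        df = pd.DataFrame(rows)
        calls = classify_hyperdivergent(df, self.locus)
        locus_bases = set(range(200, 300))
        for row in df.itertuples(index=False):  # one interval per strain here
            brute = bool(set(range(row.start, row.end)) & locus_bases)
            assert calls[row.strain_id] == brute, row

    def test_symmetric_under_region_locus_swap(self):
        region = ("V", 100, 500)
        as_region = classify_hyperdivergent(
            pd.DataFrame([{"strain_id": "s", "chrom": "V", "start": 200, "end": 300}]),
            region)
        as_locus = classify_hyperdivergent(
            pd.DataFrame([{"strain_id": "s", "chrom": region[0],
                           "start": region[1], "end": region[2]}]),
            ("V", 200, 300))
        assert as_region["s"] == as_locus["s"]

    def test_malformed_interval_rejected(self):
        bad = pd.DataFrame([{"strain_id": "s", "chrom": "V", "start": 5, "end": 5}])
        with pytest.raises(FormatError, match="start"):
            classify_hyperdivergent(bad, self.locus)


class TestSplitTraitByGroup:
    def traits(self, values, strains=None):
        strains = strains or [f"s{i}" for i in range(len(values))]
        return pd.DataFrame({"strain_id": strains, "slope": values})

    def test_identical_groups_t_zero_p_one(self):
        tr = self.traits([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=tr["strain_id"])
        res = split_trait_by_group(tr, groups)
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        tr = self.traits([0.0, 0.01, -0.01, 1.0, 1.01, 0.99])
        groups = pd.Series(["lo"] * 3 + ["hi"] * 3, index=tr["strain_id"])
        res = split_trait_by_group(tr, groups)
        assert abs(res.group_means["hi"] - res.group_means["lo"]) == pytest.approx(1.0)
        assert res.p_value < 0.001

    def test_matches_hand_computed_welch_statistic(self):
        a = np.array([0.12, 0.05, 0.30, 0.21])
        b = np.array([-0.02, 0.04, -0.11])
        tr = self.traits(list(a) + list(b))
        groups = pd.Series(["A"] * 4 + ["B"] * 3, index=tr["strain_id"])
        res = split_trait_by_group(tr, groups)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_hand = (a.mean() - b.mean()) / math.sqrt(va + vb)
        assert res.t_statistic == pytest.approx(t_hand, abs=1e-6)

    def test_tiny_group_warns_without_pvalue(self):
        tr = self.traits([0.1, 0.2, 0.3])
        groups = pd.Series(["a", "b", "b"], index=tr["strain_id"])
        with pytest.warns(UserWarning, match="<2 strains"):
            res = split_trait_by_group(tr, groups)
        assert res.p_value is None and res.group_means["a"] == pytest.approx(0.1)
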