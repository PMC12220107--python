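import math
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tescope.context import (
    classify_region,
    expression_variance_association,
    fisher_exact,
    go_enrichment,
    nearest_gene,
    ocr_enrichment,
    region_fractions,
    standardized_variance,
    wilcoxon_rank_sum,
)
from tescope.models import GeneModel, GenomicInterval


def fisher_oracle(a, b, c, d):
    """Exact-rational two-sided Fisher p: sum of hypergeometric
    probabilities not exceeding the observed table's."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    weights = {x: comb(c1, x) * comb(n - c1, r1 - x) for x in range(lo, hi + 1)}
    w_obs = weights[a]
    total = sum(weights.values())
    p = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(p, total))


def ranksum_oracle(x, y):
    """DP enumeration over all rank assignments (no ties): two-sided p =
    min(1, 2*min(P(W<=w), P(W>=w))) for the rank sum W of x."""
    n, m = len(x), len(y)
    combined = sorted(x + y)
    assert len(set(combined)) == n + m, "oracle requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    w_obs = sum(ranks[v] for v in x)
    total = n + m
    # counts[k][s] = number of k-subsets of {1..total} with rank sum s
    max_sum = total * (total + 1) // 2
    counts = [[0] * (max_sum + 1) for _ in range(n + 1)]
    counts[0][0] = 1
    for r in range(1, total + 1):
        for k in range(min(r, n), 0, -1):
            row_k, row_km1 = counts[k], counts[k - 1]
            for s in range(max_sum, r - 1, -1):
                row_k[s] += row_km1[s - r]
    dist = counts[n]
    denom = comb(total, n)
    p_le = sum(dist[: w_obs + 1])
    p_ge = sum(dist[w_obs:])
    return min(1.0, 2.0 * min(p_le, p_ge) / denom)


class TestFisherExact:
    def test_single_discordant_pair(self):
        assert fisher_exact([[1, 0], [0, 1]]) == 1.0

    def test_two_by_two_diagonal(self):
        assert fisher_exact([[2, 0], [0, 2]]) == pytest.approx(1 / 3, abs=1e-12)

    def test_zero_margin(self):
        assert fisher_exact([[0, 5], [0, 7]]) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [0, 2]])

    def test_matches_enumeration_oracle_small(self):
        for n in range(0, 16):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        got = fisher_exact([[a, b], [c, d]])
                        want = fisher_oracle(a, b, c, d)
                        assert got == pytest.approx(want, abs=1e-12), (a, b, c, d)

    @given(st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetric_under_row_and_column_swaps(self, a, b, c, d):
        p = fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(fisher_exact([[c, d], [a, b]]), abs=1e-12)
        assert p == pytest.approx(fisher_exact([[b, a], [d, c]]), abs=1e-12)


class TestWilcoxonRankSum:
    def test_spec_example_small(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(2 / 6, abs=1e-12)

    def test_single_identical_values(self):
        assert wilcoxon_rank_sum([5], [5]) == 1.0

    def test_all_identical_degenerate(self):
        assert wilcoxon_rank_sum([3, 3, 3], [3, 3]) == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1])

    def test_exact_matches_enumeration(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 10))
            m = int(rng.integers(1, 10))
            vals = rng.choice(1000, size=n + m, replace=False).astype(float)
            x, y = list(vals[:n]), list(vals[n:])
            assert wilcoxon_rank_sum(x, y) == pytest.approx(
                ranksum_oracle(x, y), abs=1e-12
            )

    def test_normal_approximation_close_to_exact(self, rng):
        # tie-corrected normal with continuity vs the exact path. At the
        # largest exact sample size (10 vs 10) the deviation stays within
        # 0.01 over every achievable rank sum; smaller groups drift a
        # little further near p ~ 0.5.
        from scipy import stats

        def approx_p(x, y):
            return stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            ).pvalue

        n = m = 10
        ranks = list(range(1, 21))
        for w in range(sum(ranks[:n]), sum(ranks[-n:]) + 1):
            x = _ranks_with_sum(n, 20, w)
            if x is None:
                continue
            y = [float(r) for r in ranks if r not in set(x)]
            x = [float(r) for r in x]
            assert abs(wilcoxon_rank_sum(x, y) - approx_p(x, y)) <= 0.0105
        deltas = []
        for _ in range(200):
            n = int(rng.integers(6, 11))
            m = int(rng.integers(6, 11))
            vals = rng.choice(10_000, size=n + m, replace=False).astype(float)
            deltas.append(abs(wilcoxon_rank_sum(vals[:n], vals[n:])
                              - approx_p(vals[:n], vals[n:])))
        assert max(deltas) <= 0.02


def _ranks_with_sum(k, total, target):
    """Greedy pick of k distinct ranks from 1..total summing to target."""
    picked = []
    remaining = target
    ceiling = total
    for slots in range(k, 0, -1):
        found = False
        for r in range(ceiling, 0, -1):
            rest_min = (slots - 1) * slots // 2
            rest_max = sum(range(r - 1, r - slots, -1)) if slots > 1 else 0
            if rest_min <= remaining - r <= rest_max:
                picked.append(r)
                remaining -= r
                ceiling = r - 1
                found = True
                break
        if not found:
            return None
    return picked if remaining == 0 else None


GENES = [
    GeneModel("g1", GenomicInterval("chr1", 1000, 9000, "+"),
              exons=(GenomicInterval("chr1", 1000, 1500, "+"),
                     GenomicInterval("chr1", 8000, 9000, "+"))),
    GeneModel("g2", GenomicInterval("chr1", 20000, 25000, "-"),
              exons=(GenomicInterval("chr1", 20000, 21000, "-"),)),
]


class TestRegions:
    def test_exon_intron_intergenic(self):
        assert classify_region(GenomicInterval("chr1", 1100, 1101), GENES) == "exon"
        assert classify_region(GenomicInterval("chr1", 2000, 2001), GENES) == "intron"
        assert classify_region(GenomicInterval("chr1", 50000, 50001), GENES) == \
            "intergenic"

    def test_exon_priority_on_boundary_span(self):
        iv = GenomicInterval("chr1", 1400, 1600)  # spans exon/intron junction
        assert classify_region(iv, GENES) == "exon"

    def test_fractions_sum_to_one(self):
        ivs = [GenomicInterval("chr1", p, p + 1) for p in
               (1100, 2000, 50000, 60000)]
        fr = region_fractions(ivs, GENES)
        assert sum(fr.values()) == pytest.approx(1.0)


class TestNearestGene:
    def test_overlap_distance_zero(self):
        assert nearest_gene(GenomicInterval("chr1", 1100, 1200), GENES) == ("g1", 0)

    def test_downstream_of_plus_gene_positive(self):
        gene_id, dist = nearest_gene(GenomicInterval("chr1", 10000, 10001), GENES)
        assert gene_id == "g1" and dist == 1000

    def test_upstream_of_plus_gene_negative(self):
        gene_id, dist = nearest_gene(GenomicInterval("chr1", 500, 501), GENES)
        assert gene_id == "g1" and dist == -499

    def test_upstream_of_minus_gene_negative(self):
        # right of a minus-strand gene is its 5' side
        gene_id, dist = nearest_gene(GenomicInterval("chr1", 26000, 26001), GENES)
        assert gene_id == "g2" and dist == -1000

    def test_equidistant_resolves_leftmost(self):
        mid = GenomicInterval("chr1", 14499, 14501)  # 5499 bp from both
        gene_id, _ = nearest_gene(mid, GENES)
        assert gene_id == "g1"

    def test_no_gene_on_chrom(self):
        assert nearest_gene(GenomicInterval("chr9", 0, 1), GENES) is None


class TestOcrEnrichment:
    def test_fraction_and_reference(self):
        ocrs = [GenomicInterval("chr1", 0, 1000)]
        sets = {
            "shared": [GenomicInterval("chr1", p, p + 1) for p in
                       (100, 5000, 6000, 7000)],
            "specific:i-cell": [GenomicInterval("chr1", p, p + 1) for p in
                                (200, 300)],
        }
        res = ocr_enrichment(sets, ocrs)
        assert res["shared"].fraction == 0.25
        assert res["specific:i-cell"].fraction == 1.0
        assert res["shared"].p_value is None
        want = fisher_oracle(2, 0, 1, 3)
        assert res["specific:i-cell"].p_value == pytest.approx(want, abs=1e-12)

    def test_empty_category_sentinel(self):
        res = ocr_enrichment({"shared": [GenomicInterval("chr1", 0, 1)],
                              "x": []}, [])
        assert math.isnan(res["x"].fraction) and res["x"].p_value is None

    def test_missing_reference_fatal(self):
        with pytest.raises(ValueError):
            ocr_enrichment({"a": []}, [], reference="shared")


class TestGoEnrichment:
    def test_hypergeometric_tail(self):
        from scipy import stats
        bg = {f"g{i}" for i in range(100)}
        fg = {f"g{i}" for i in range(10)}
        term_genes = {f"g{i}" for i in range(5)} | {"g50", "g51", "g52", "g53",
                                                    "g54"}
        df = go_enrichment(fg, bg, {"T": term_genes})
        want = float(stats.hypergeom.sf(4, 100, 10, 10))
        assert df.loc[0, "p"] == pytest.approx(want, rel=1e-12)

    def test_term_absent_from_foreground_not_enriched(self):
        bg = {f"g{i}" for i in range(40)}
        fg = {f"g{i}" for i in range(10)}
        df = go_enrichment(fg, bg, {"T": {"g30", "g31"}})
        assert df.loc[0, "p"] >= 0.5

    def test_foreground_equals_background_p_one(self):
        bg = {f"g{i}" for i in range(20)}
        df = go_enrichment(bg, bg, {"T": {"g0", "g1"}})
        assert df.loc[0, "p"] == pytest.approx(1.0)

    def test_empty_background_term_skipped(self):
        bg = {"a", "b"}
        df = go_enrichment({"a"}, bg, {"T": {"zzz"}})
        assert len(df) == 0

    def test_foreground_must_be_subset(self):
        with pytest.raises(ValueError):
            go_enrichment({"x"}, {"a"}, {})


class TestExpressionVariance:
    def test_constant_gene_zero_cv2(self):
        expr = pd.DataFrame([[5.0, 5.0, 5.0]], index=["g1"])
        assert standardized_variance(expr)["g1"] == 0.0

    def test_hand_computed_cv2(self):
        expr = pd.DataFrame([[2.0, 4.0]], index=["g1"])
        # population variance 1, mean 3 -> CV^2 = 1/9
        assert standardized_variance(expr)["g1"] == pytest.approx(1 / 9)

    def test_zero_mean_gene_excluded(self):
        expr = pd.DataFrame([[0.0, 0.0], [1.0, 3.0]], index=["g0", "g1"])
        cv2 = standardized_variance(expr)
        assert list(cv2.index) == ["g1"]

    def test_group_comparison(self, rng):
        n_genes, n_cells = 60, 50
        base = rng.gamma(2.0, 5.0, size=(n_genes, n_cells))
        noisy = base.copy()
        noisy[:30] *= rng.lognormal(0, 0.8, size=(30, n_cells))  # inflate CV2
        expr = pd.DataFrame(noisy, index=[f"g{i}" for i in range(n_genes)])
        near = {f"g{i}" for i in range(30)}
        far = {f"g{i}" for i in range(30, 60)}
        cv2, med_near, med_far, p = expression_variance_association(expr, near, far)
        assert med_near > med_far and p < 0.01

    def test_overlapping_sets_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g1"])
        with pytest.raises(ValueError):
            expression_variance_association(expr, {"g1"}, {"g1"})
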