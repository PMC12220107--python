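"""Genomic context of insertions and the associated enrichment statistics.

Covers region assignment (exon > intron > intergenic), nearest-gene
lookup, Fisher's exact test (two-sided, summation of hypergeometric
probabilities no larger than the observed table's), open-chromatin
overlap enrichment, GO-term overrepresentation (one-sided hypergeometric)
and the association between nearby insertions and single-cell expression
variability (CV^2, compared by Wilcoxon rank-sum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .models import GeneModel, GenomicInterval

_REL_SLACK = 1e-7  # relative slack when comparing table probabilities


def classify_region(
    interval: GenomicInterval, genes: Sequence[GeneModel]
) -> str:
    """'exon' if any bp overlaps an exon, else 'intron' if within a gene
    span, else 'intergenic'."""
    trees = _gene_trees(genes)
    return _classify_with_trees(interval, trees)


def _gene_trees(genes: Sequence[GeneModel]):
    exon_trees: Dict[str, IntervalTree] = {}
    gene_trees: Dict[str, IntervalTree] = {}
    for g in genes:
        gene_trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, g.gene_id
        )
        for e in g.exons:
            exon_trees.setdefault(e.chrom, IntervalTree()).addi(
                e.start, e.end, g.gene_id
            )
    return exon_trees, gene_trees


def _classify_with_trees(interval, trees) -> str:
    exon_trees, gene_trees = trees
    if interval.chrom in exon_trees and exon_trees[interval.chrom].overlap(
        interval.start, interval.end
    ):
        return "exon"
    if interval.chrom in gene_trees and gene_trees[interval.chrom].overlap(
        interval.start, interval.end
    ):
        return "intron"
    return "intergenic"


def region_fractions(
    intervals: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> Dict[str, float]:
    trees = _gene_trees(genes)
    counts = {"exon": 0, "intron": 0, "intergenic": 0}
    for iv in intervals:
        counts[_classify_with_trees(iv, trees)] += 1
    total = sum(counts.values())
    return {k: (v / total if total else math.nan) for k, v in counts.items()}


def nearest_gene(
    interval: GenomicInterval, genes: Sequence[GeneModel]
) -> Optional[Tuple[str, int]]:
    """Closest gene on the interval's chromosome and the signed gap.

    Distance 0 on overlap; otherwise the minimal end-to-start gap.
    Equidistant genes resolve to the leftmost by start coordinate. Sign
    convention: negative when the insertion lies upstream of the gene's
    5' end on the gene's strand, positive otherwise. None when the
    chromosome has no genes.
    """
    on_chrom = [g for g in genes if g.interval.chrom == interval.chrom]
    if not on_chrom:
        return None
    best: Optional[Tuple[int, int, str, GeneModel]] = None
    for g in on_chrom:
        iv = g.interval
        if interval.start < iv.end and iv.start < interval.end:
            gap = 0
        elif interval.end <= iv.start:
            gap = iv.start - interval.end
        else:
            gap = interval.start - iv.end
        key = (gap, iv.start, g.gene_id)
        if best is None or key < (best[0], best[1], best[2]):
            best = (gap, iv.start, g.gene_id, g)
    gap, _, gene_id, g = best
    if gap == 0:
        return gene_id, 0
    iv = g.interval
    insertion_left_of_gene = interval.end <= iv.start
    if iv.strand == "-":
        upstream = not insertion_left_of_gene
    else:
        upstream = insertion_left_of_gene
    return gene_id, -gap if upstream else gap


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact test on a 2x2 table.

    P-value is the sum of hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's (within 1e-7 relative slack). A table with a zero margin has
    a single possible configuration, hence p = 1.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _REL_SLACK)].sum())
    return min(p, 1.0)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided rank-sum (Mann-Whitney) p-value.

    Exact permutation null when n+m <= 20 with no ties; otherwise normal
    approximation with tie-corrected variance and continuity correction.
    Degenerate input (all values identical across both samples) gives 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


@dataclass
class EnrichmentResult:
    category: str
    n: int
    n_overlapping: int
    fraction: float             # NaN for empty categories
    p_value: Optional[float]    # None for the reference itself / empty


def ocr_enrichment(
    insertion_sets: Dict[str, Sequence[GenomicInterval]],
    ocrs: Sequence[GenomicInterval],
    reference: str = "shared",
) -> Dict[str, EnrichmentResult]:
    """Per-category open-chromatin overlap fraction and Fisher p vs the
    reference category (any-bp intersection)."""
    if reference not in insertion_sets:
        raise ValueError(f"reference category {reference!r} missing")
    trees: Dict[str, IntervalTree] = {}
    for ocr in ocrs:
        trees.setdefault(ocr.chrom, IntervalTree()).addi(ocr.start, ocr.end)

    def count_overlap(intervals):
        k = 0
        for iv in intervals:
            t = trees.get(iv.chrom)
            if t is not None and t.overlap(iv.start, iv.end):
                k += 1
        return k

    counts = {
        cat: (len(ivs), count_overlap(ivs)) for cat, ivs in insertion_sets.items()
    }
    n_ref, k_ref = counts[reference]
    results = {}
    for cat, (n, k) in counts.items():
        if n == 0:
            results[cat] = EnrichmentResult(cat, 0, 0, math.nan, None)
            continue
        p = None
        if cat != reference and n_ref > 0:
            p = fisher_exact([[k, n - k], [k_ref, n_ref - k_ref]])
        results[cat] = EnrichmentResult(cat, n, k, k / n, p)
    return results


def go_enrichment(
    foreground: Set[str],
    background: Set[str],
    term_to_genes: Dict[str, Set[str]],
) -> pd.DataFrame:
    """One-sided (greater) hypergeometric overrepresentation per term.

    ``foreground`` must be a subset of ``background``. Terms with no
    background members are skipped. Returns a DataFrame with raw p and
    Benjamini-Hochberg q values.
    """
    if not foreground <= background:
        raise ValueError("foreground must be a subset of background")
    n_bg = len(background)
    n_fg = len(foreground)
    rows = []
    for term, genes in sorted(term_to_genes.items()):
        members = genes & background
        if not members:
            continue
        k_fg = len(genes & foreground)
        p = float(stats.hypergeom.sf(k_fg - 1, n_bg, len(members), n_fg))
        rows.append((term, k_fg, len(members), p))
    df = pd.DataFrame(rows, columns=["term", "fg_count", "bg_count", "p"])
    if len(df):
        df["q"] = _benjamini_hochberg(df["p"].to_numpy())
    else:
        df["q"] = []
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def standardized_variance(expr: pd.DataFrame) -> pd.Series:
    """Per-gene CV^2: population variance across cells over squared mean,
    for genes with positive mean expression (genes x cells input)."""
    values = expr.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression values must be non-negative")
    means = values.mean(axis=1)
    variances = values.var(axis=1)  # population variance
    keep = means > 0
    cv2 = variances[keep] / means[keep] ** 2
    return pd.Series(cv2, index=expr.index[keep], name="cv2")


def expression_variance_association(
    expr: pd.DataFrame,
    genes_near: Set[str],
    genes_far: Set[str],
) -> Tuple[pd.Series, float, float, float]:
    """Compare CV^2 of genes near insertions vs genes without.

    Returns ``(per-gene CV^2, median near, median far, Wilcoxon p)``.
    Gene sets must be disjoint subsets of the matrix index; zero-mean
    genes are excluded (by :func:`standardized_variance`).
    """
    if genes_near & genes_far:
        raise ValueError("gene sets must be disjoint")
    missing = (genes_near | genes_far) - set(expr.index)
    if missing:
        raise ValueError(f"genes not in matrix: {sorted(missing)[:5]}...")
    cv2 = standardized_variance(expr)
    near = cv2[cv2.index.isin(genes_near)]
    far = cv2[cv2.index.isin(genes_far)]
    p = wilcoxon_rank_sum(near.to_numpy(), far.to_numpy())
    return cv2, float(near.median()), float(far.median()), p
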