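"""Differential TE coverage between two assemblies and active-family calls.

An "active" family (A-TE) is one whose genome coverage in assembly A
exceeds that in assembly B by strictly more than a bp threshold. On the
full-size Hydra haplotypes the threshold is 2.5 Mb; on scaled synthetic
genomes it must be rescaled by the same factor as the genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from .landscape import CoverageProfile, DivergenceLandscape

#: bp-delta cutoff defining A-TE families on the full-size assemblies.
DEFAULT_DELTA_THRESHOLD = 2_500_000


@dataclass(frozen=True)
class DifferentialRecord:
    family: str
    cov_a: int
    cov_b: int
    delta: int
    log2_fc: float  # +/-inf when one side is 0; nan when both are
    is_active: bool = False


def differential_table(
    profile_a: CoverageProfile, profile_b: CoverageProfile
) -> List[DifferentialRecord]:
    """One record per family over the union of the two family universes
    (absent = 0 bp). Sorted by descending delta, then name."""
    families = set(profile_a.per_family) | set(profile_b.per_family)
    records = []
    for fam in families:
        a = profile_a.per_family.get(fam, 0)
        b = profile_b.per_family.get(fam, 0)
        if a > 0 and b > 0:
            fc = math.log2(a / b)
        elif a == 0 and b == 0:
            fc = math.nan
        elif a == 0:
            fc = -math.inf
        else:
            fc = math.inf
        records.append(DifferentialRecord(fam, a, b, a - b, fc))
    records.sort(key=lambda r: (-r.delta, r.family))
    return records


def call_active_families(
    table: Sequence[DifferentialRecord],
    delta_threshold: int = DEFAULT_DELTA_THRESHOLD,
) -> Set[str]:
    """Families with coverage delta strictly greater than the threshold."""
    if delta_threshold <= 0:
        raise ValueError("delta_threshold must be > 0")
    return {r.family for r in table if r.delta > delta_threshold}


def mark_active(
    table: Sequence[DifferentialRecord],
    delta_threshold: int = DEFAULT_DELTA_THRESHOLD,
) -> List[DifferentialRecord]:
    active = call_active_families(table, delta_threshold)
    return [
        DifferentialRecord(r.family, r.cov_a, r.cov_b, r.delta, r.log2_fc,
                           r.family in active)
        for r in table
    ]


def attribution_statistic(
    table: Sequence[DifferentialRecord], size_a: int, size_b: int
) -> Tuple[int, float]:
    """Total TE coverage delta and the percent of the assembly-size
    difference it accounts for.

    Only family deltas whose sign agrees with the assembly-size
    difference are summed (positive-direction-consistent summation): with
    size_a > size_b, families that shrank in A do not offset the
    expansion being attributed. Returns ``(delta_bp, percent)``; percent
    is NaN when the assemblies are equal-sized.
    """
    size_delta = size_a - size_b
    sign = 1 if size_delta > 0 else -1
    te_delta = sum(r.delta for r in table if sign * r.delta > 0)
    if size_delta == 0:
        return te_delta, math.nan
    return te_delta, 100.0 * te_delta / size_delta


def differential_landscape(
    landscape_a: DivergenceLandscape, landscape_b: DivergenceLandscape
) -> Dict[str, np.ndarray]:
    """Cellwise bp difference (A - B) of two divergence landscapes."""
    if landscape_a.bin_width != landscape_b.bin_width or (
        landscape_a.n_bins != landscape_b.n_bins
    ):
        raise ValueError("landscape bin definitions differ")
    families = set(landscape_a.matrix) | set(landscape_b.matrix)
    n = landscape_a.n_bins + 1
    zeros = np.zeros(n, dtype=np.int64)
    return {
        fam: landscape_a.matrix.get(fam, zeros) - landscape_b.matrix.get(fam, zeros)
        for fam in families
    }


def write_differential_table(table, path, delta_threshold=None) -> None:
    with open(path, "w") as fh:
        if delta_threshold is not None:
            fh.write(f"# delta_threshold_bp={delta_threshold}\n")
        fh.write("family\tcov_a\tcov_b\tdelta\tlog2_fc\tis_active\n")
        for r in table:
            fc = "nan" if math.isnan(r.log2_fc) else f"{r.log2_fc:.4f}"
            fh.write(f"{r.family}\t{r.cov_a}\t{r.cov_b}\t{r.delta}\t{fc}\t"
                     f"{int(r.is_active)}\n")
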