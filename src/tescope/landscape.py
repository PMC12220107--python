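"""Per-family genome coverage, Kimura divergence and divergence landscapes.

The divergence statistic is the Kimura two-parameter distance between a
repeat copy and its family consensus,

    K = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)],

with P and Q the transition and transversion proportions over ungapped
aligned columns. K is the expected number of substitutions per site under
a two-rate (transition/transversion) model and serves as a proxy for copy
age: recently active families accumulate coverage in low-K bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .models import (
    AlignmentBlock,
    RepeatHit,
    SaturationError,
    TE_LIKE_CLASSES,
)

#: Divergence axis of a standard repeat landscape: 1-point bins over
#: [0, 55) percent plus an overflow bin for saturated/older copies.
DEFAULT_BIN_WIDTH = 1.0
DEFAULT_MAX_PCT = 55.0
OVERFLOW = "overflow"


def kimura_divergence(block: AlignmentBlock, cpg_mode: str = "include") -> float:
    """Kimura two-parameter distance for one alignment block.

    ``cpg_mode`` only matters for blocks built from gapped strings (CpG
    columns are excluded at counting time); count-based blocks are used
    as-is. Raises :class:`SaturationError` outside the estimator domain
    (1-2P-Q <= 0 or 1-2Q <= 0).
    """
    if block.n_sites < 1:
        raise ValueError("block has no aligned sites")
    p, q = block.p, block.q
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(p, q)
    return -0.5 * math.log(w1 * math.sqrt(w2))


def merged_length(intervals: Iterable[Tuple[str, int, int]]) -> int:
    """Total bp covered by the union of (chrom, start, end) intervals."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    total = 0
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


@dataclass
class CoverageProfile:
    """Per-family and per-class covered bp for one assembly."""

    assembly_id: str
    genome_length: int
    per_family: Dict[str, int] = field(default_factory=dict)
    per_class: Dict[str, int] = field(default_factory=dict)
    te_union: int = 0

    def te_fraction(self) -> float:
        return self.te_union / self.genome_length if self.genome_length else 0.0


def family_coverage(
    hits: Sequence[RepeatHit],
    genome_length: int,
    assembly_id: str = "assembly",
) -> CoverageProfile:
    """Overlap-merged covered bp per family, per class, and the TE union.

    Overlapping hits of different families each get full credit in their
    family's tally but count once in ``te_union``; non-TE classes are
    excluded from the union. Hits beyond genome bounds are rejected with
    a warning (dropped).
    """
    in_bounds: List[RepeatHit] = []
    for h in hits:
        if h.interval.end > genome_length or h.interval.start < 0:
            import logging
            logging.getLogger(__name__).warning(
                "hit %s beyond genome bounds, dropped", h.interval
            )
            continue
        in_bounds.append(h)
    per_family: Dict[str, int] = {}
    fam_spans: Dict[str, list] = {}
    class_spans: Dict[str, list] = {}
    te_spans = []
    for h in in_bounds:
        iv = (h.interval.chrom, h.interval.start, h.interval.end)
        fam_spans.setdefault(h.family, []).append(iv)
        class_spans.setdefault(h.te_class, []).append(iv)
        if h.te_class in TE_LIKE_CLASSES:
            te_spans.append(iv)
    for fam, spans in fam_spans.items():
        per_family[fam] = merged_length(spans)
    per_class = {cls: merged_length(spans) for cls, spans in class_spans.items()}
    te_union = merged_length(te_spans) if te_spans else 0
    return CoverageProfile(
        assembly_id=assembly_id,
        genome_length=genome_length,
        per_family=per_family,
        per_class=per_class,
        te_union=te_union,
    )


@dataclass
class DivergenceLandscape:
    """family x divergence-bin matrix of covered bp."""

    assembly_id: str
    bin_width: float
    bin_edges: np.ndarray          # percent; len = n_bins + 1
    matrix: Dict[str, np.ndarray]  # family -> bp per bin (+ trailing overflow)
    n_without_divergence: int = 0

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def bin_labels(self) -> List[str]:
        labels = [
            f"[{self.bin_edges[i]:g},{self.bin_edges[i + 1]:g})"
            for i in range(self.n_bins)
        ]
        return labels + [OVERFLOW]

    def family_row_sum(self, family: str) -> int:
        return int(self.matrix[family].sum())


def divergence_landscape(
    hits: Sequence[RepeatHit],
    blocks: Optional[Dict[str, AlignmentBlock]] = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_pct: float = DEFAULT_MAX_PCT,
    cpg_mode: str = "include",
) -> DivergenceLandscape:
    """Assign each hit's merged length to the divergence bin holding its K.

    K (in percent, K x 100) comes from the hit's alignment block when one
    is linked via ``hit_id``; otherwise the hit's ``divergence_pct`` is
    used directly. Bins are half-open ``[i*w, (i+1)*w)``; saturated copies
    and K >= ``max_pct`` land in the trailing overflow bin. Hits with no
    divergence signal at all are excluded and counted.

    Within a family and bin, overlapping hit intervals are merged so the
    landscape row sums reproduce family coverage of divergence-bearing
    hits exactly.
    """
    edges = np.arange(0.0, max_pct + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    per_cell: Dict[str, Dict[int, list]] = {}
    n_missing = 0
    for h in hits:
        pct = None
        if blocks and h.hit_id is not None and h.hit_id in blocks:
            try:
                pct = 100.0 * kimura_divergence(blocks[h.hit_id], cpg_mode=cpg_mode)
            except SaturationError:
                pct = math.inf
        elif h.divergence_pct is not None:
            pct = h.divergence_pct
        if pct is None:
            n_missing += 1
            continue
        idx = n_bins if pct >= max_pct else int(pct // bin_width)
        per_cell.setdefault(h.family, {}).setdefault(idx, []).append(
            (h.interval.chrom, h.interval.start, h.interval.end)
        )
    matrix: Dict[str, np.ndarray] = {}
    for fam, cells in per_cell.items():
        row = np.zeros(n_bins + 1, dtype=np.int64)
        for idx, spans in cells.items():
            row[idx] = merged_length(spans)
        matrix[fam] = row
    return DivergenceLandscape(
        assembly_id="assembly",
        bin_width=bin_width,
        bin_edges=edges,
        matrix=matrix,
        n_without_divergence=n_missing,
    )


def genome_te_fraction(profile: CoverageProfile) -> float:
    """Fraction of the genome covered by any TE-class hit."""
    return profile.te_fraction()


def write_profile(profile: CoverageProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# assembly={profile.assembly_id}\tgenome_length={profile.genome_length}"
                 f"\tte_union={profile.te_union}\n")
        fh.write("family\tcovered_bp\n")
        for fam in sorted(profile.per_family):
            fh.write(f"{fam}\t{profile.per_family[fam]}\n")


def read_profile(path) -> CoverageProfile:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(
            kv.split("=") for kv in header.lstrip("# ").split("\t")
        )
        fh.readline()  # column header
        per_family = {}
        for line in fh:
            fam, bp = line.rstrip("\n").split("\t")
            per_family[fam] = int(bp)
    return CoverageProfile(
        assembly_id=meta["assembly"],
        genome_length=int(meta["genome_length"]),
        per_family=per_family,
        per_class={},
        te_union=int(meta["te_union"]),
    )


def write_landscape(ls: DivergenceLandscape, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# assembly={ls.assembly_id}\tbin_width={ls.bin_width:g}"
                 f"\tn_without_divergence={ls.n_without_divergence}\n")
        fh.write("family\t" + "\t".join(ls.bin_labels()) + "\n")
        for fam in sorted(ls.matrix):
            fh.write(fam + "\t" + "\t".join(str(int(v)) for v in ls.matrix[fam]) + "\n")
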