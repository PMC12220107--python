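"""Local alignment of query sequences against a consensus repeat library.

The engine is an exact Smith-Waterman (Biopython's PairwiseAligner in
local mode) with match +2, mismatch -3, gap open -5, gap extend -2. The
"span" of a hit is the length of the local alignment in columns, i.e. the
aligned stretch including internal gaps. An optional edit-distance
prescreen (edlib) ranks (family, strand) candidates first so the exact
alignment only runs on the few plausible ones; exhaustive mode aligns
against every consensus on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import edlib
from Bio import Align

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -3, -5, -2

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="local")
    a.match_score = MATCH
    a.mismatch_score = MISMATCH
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    return a


_ALIGNER = _aligner()


@dataclass(frozen=True)
class LocalHit:
    family: str
    strand: str
    span: int     # alignment columns, gaps included
    score: float


def _sw_hit(seq: str, consensus: str, family: str, strand: str) -> LocalHit:
    target = consensus if strand == "+" else revcomp(consensus)
    alignments = _ALIGNER.align(seq, target)
    score = float(alignments.score)
    if score <= 0:
        return LocalHit(family, strand, 0, 0.0)
    aln = alignments[0]
    return LocalHit(family, strand, int(aln.shape[1]), score)


def _edlib_distance(seq: str, target: str) -> float:
    """Normalized infix edit distance of the shorter sequence within the
    longer one."""
    if len(target) <= len(seq):
        query, ref = target, seq
    else:
        query, ref = seq, target
    d = edlib.align(query, ref, mode="HW", task="distance")["editDistance"]
    return d / max(len(query), 1)


def _rank_candidates(seq: str, library: Dict[str, str]) -> List[Tuple[str, str]]:
    """(family, strand) pairs sorted by normalized edit distance."""
    scored = []
    for family, consensus in sorted(library.items()):
        for strand, cand in (("+", consensus), ("-", revcomp(consensus))):
            scored.append((_edlib_distance(seq, cand), family, strand))
    scored.sort()
    return [(family, strand) for _, family, strand in scored]


def scan_library(
    seq: str,
    library: Dict[str, str],
    prescreen_k: Optional[int] = None,
) -> Dict[str, LocalHit]:
    """Best local hit per evaluated family.

    ``prescreen_k`` limits the exact alignment to the k most plausible
    (family, strand) candidates from the edit-distance prescreen;
    ``None`` aligns every family on both strands (exact mode).
    """
    if not library:
        raise ValueError("consensus library is empty")
    if prescreen_k is None:
        candidates = [
            (family, strand)
            for family in sorted(library)
            for strand in ("+", "-")
        ]
    else:
        candidates = _rank_candidates(seq, library)[:max(prescreen_k, 1)]
    hits: Dict[str, LocalHit] = {}
    for family, strand in candidates:
        hit = _sw_hit(seq, library[family], family, strand)
        prev = hits.get(family)
        if prev is None or (hit.span, hit.score) > (prev.span, prev.score):
            hits[family] = hit
    return hits


def best_hit(
    seq: str,
    library: Dict[str, str],
    min_span: int,
    strict: bool = False,
    prescreen_k: Optional[int] = None,
) -> Tuple[Optional[str], int, Dict[str, LocalHit]]:
    """Best-family call against the library.

    Returns ``(family or None, best span, all evaluated per-family
    hits)``. The winning family has the longest span meeting the
    threshold; ties break by higher alignment score, then lexicographic
    family name. ``strict=True`` uses a strictly-greater span threshold
    ("over"), ``strict=False`` an inclusive one ("or more").
    """
    hits = scan_library(seq, library, prescreen_k=prescreen_k)
    ranked = sorted(
        hits.values(), key=lambda h: (-h.span, -h.score, h.family)
    )
    top = ranked[0]
    passes = top.span > min_span if strict else top.span >= min_span
    return (top.family if passes else None), top.span, hits
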