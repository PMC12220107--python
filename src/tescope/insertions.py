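"""Classify multi-sample insertion calls by stem-cell lineage and annotate
them as TE/non-TE, with optional target-site-duplication detection.

In a clonally propagated animal the three stem-cell lineages accumulate
insertions independently: an insertion carried only by the samples of one
lineage is lineage-specific, one carried by every sample reflects shared
(germline / strain-background) variation. Only calls where every sample
has a genotype and the insertion is larger than 1 kb enter typing;
TE identity requires a local alignment of at least 500 bp against a
consensus library.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from . import align
from .models import InsertionCall, classify_family

MIN_INSERTION_LENGTH = 1000   # strict: "larger than 1 kb"
MIN_ALIGNMENT_BP = 500        # inclusive: "500 bp or more"


@dataclass(frozen=True)
class AnnotatedInsertion:
    call: InsertionCall
    category: str                     # "specific:<L>" | "shared" | "shared-subset:<...>" | "excluded"
    reason: Optional[str] = None      # set when excluded
    te_family: Optional[str] = None
    te_class: Optional[str] = None
    aligned_span: int = 0
    tsd: Optional[str] = None


def filter_calls(
    calls: Sequence[InsertionCall],
    min_length: int = MIN_INSERTION_LENGTH,
) -> Tuple[List[InsertionCall], List[Tuple[InsertionCall, str]]]:
    """Keep calls genotyped in every sample and strictly longer than
    ``min_length``; return (kept, excluded-with-reason)."""
    kept, excluded = [], []
    for c in calls:
        if not c.is_fully_genotyped():
            excluded.append((c, "incomplete-genotype"))
        elif c.length <= min_length:
            excluded.append((c, "too-short"))
        else:
            kept.append(c)
    return kept, excluded


def classify_by_genotype(call: InsertionCall, lineages: Dict[str, str]) -> str:
    """Category of one fully genotyped call.

    ``lineages`` maps sample name -> lineage label. A call is
    ``specific:<L>`` when its carriers are exactly the samples of lineage
    L; ``shared`` when every sample carries it; any other non-empty
    carrier pattern is reported losslessly as ``shared-subset:<L1+L2>``
    over the carrier lineages; a call no sample carries is
    ``absent`` (reference-only record).
    """
    carriers = call.carriers()
    samples = frozenset(lineages)
    if set(call.genotypes) != samples:
        raise ValueError("call roster does not match lineage roster")
    if not carriers:
        return "absent"
    if carriers == samples:
        return "shared"
    carrier_lineages = {lineages[s] for s in carriers}
    for lin in carrier_lineages:
        members = frozenset(s for s, l in lineages.items() if l == lin)
        if carriers == members and len(carrier_lineages) == 1:
            return f"specific:{lin}"
    return "shared-subset:" + "+".join(sorted(carrier_lineages))


def annotate_insertion_te(
    sequence: Optional[str],
    library: Dict[str, str],
    min_aln: int = MIN_ALIGNMENT_BP,
    prescreen_k: Optional[int] = None,
    classification_map: Optional[dict] = None,
) -> Tuple[Optional[str], int, Optional[str]]:
    """TE family of an inserted sequence, or None.

    Returns ``(family, best aligned span, te_class)``. The family is that
    of the library consensus with the longest local alignment of at least
    ``min_aln`` columns (both strands considered; ties by score, then
    name). ``prescreen_k`` enables the fast candidate prescreen.
    """
    if sequence is None:
        return None, 0, None
    family, span, _ = align.best_hit(
        sequence, library, min_span=min_aln, strict=False, prescreen_k=prescreen_k
    )
    te_class = classify_family(family, None, classification_map) if family else None
    return family, span, te_class


def detect_tsd(
    left_flank: str,
    right_flank: str,
    min_len: int = 4,
    max_len: int = 25,
    max_mismatch: int = 0,
) -> Optional[str]:
    """Longest suffix of ``left_flank`` matching a prefix of
    ``right_flank`` (at most ``max_mismatch`` substitutions) with length
    in [min_len, max_len]; None if no such duplication exists."""
    if len(left_flank) < max_len or len(right_flank) < max_len:
        raise ValueError("flanks must be at least max_len long")
    left = left_flank.upper()
    right = right_flank.upper()
    for k in range(max_len, min_len - 1, -1):
        suffix = left[-k:]
        prefix = right[:k]
        mismatches = sum(a != b for a, b in zip(suffix, prefix))
        if mismatches <= max_mismatch:
            return suffix
    return None


def annotate_cohort(
    calls: Sequence[InsertionCall],
    lineages: Dict[str, str],
    library: Optional[Dict[str, str]] = None,
    flanks: Optional[Dict[str, Tuple[str, str]]] = None,
    min_length: int = MIN_INSERTION_LENGTH,
    min_aln: int = MIN_ALIGNMENT_BP,
    prescreen_k: Optional[int] = 2,
    classification_map: Optional[dict] = None,
) -> List[AnnotatedInsertion]:
    """Full typing pass: completeness/length filter, genotype
    classification, TE annotation, and TSD detection when flanks are
    supplied (keyed by call_id: (tail of inserted sequence, reference
    bases 3' of the anchor))."""
    kept, excluded = filter_calls(calls, min_length=min_length)
    out: List[AnnotatedInsertion] = []
    for call, reason in excluded:
        out.append(AnnotatedInsertion(call=call, category="excluded", reason=reason))
    for call in kept:
        category = classify_by_genotype(call, lineages)
        family, span, te_class = (None, 0, None)
        if library:
            family, span, te_class = annotate_insertion_te(
                call.sequence, library, min_aln=min_aln,
                prescreen_k=prescreen_k, classification_map=classification_map,
            )
        tsd = None
        if flanks and call.call_id in flanks:
            left, right = flanks[call.call_id]
            tsd = detect_tsd(left, right)
        out.append(
            AnnotatedInsertion(
                call=call, category=category, te_family=family,
                te_class=te_class, aligned_span=span, tsd=tsd,
            )
        )
    return out


def category_counts(annotated: Sequence[AnnotatedInsertion]) -> Counter:
    return Counter(a.category for a in annotated)


def family_counts(
    annotated: Sequence[AnnotatedInsertion], category: Optional[str] = None
) -> Counter:
    return Counter(
        a.te_family
        for a in annotated
        if a.te_family is not None and (category is None or a.category == category)
    )


def write_annotated(annotated: Sequence[AnnotatedInsertion], path) -> None:
    with open(path, "w") as fh:
        fh.write("call_id\tchrom\tpos\tlength\tcategory\treason\t"
                 "te_family\tte_class\taligned_span\ttsd\n")
        for a in annotated:
            c = a.call
            fh.write(
                f"{c.call_id or '.'}\t{c.chrom}\t{c.pos}\t{c.length}\t"
                f"{a.category}\t{a.reason or '.'}\t{a.te_family or '.'}\t"
                f"{a.te_class or '.'}\t{a.aligned_span}\t{a.tsd or '.'}\n"
            )
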