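"""Long-read TE-transcript calling: TE-derived read classification,
spliced-leader detection, and expression-rank membership.

A long (Iso-Seq-style) read is TE-derived when its best single-consensus
local alignment spans strictly more than 1 kb. Trans-spliced leader (SL)
detection looks for the configured SL motif near the 5' end of the read;
the motif is organism-specific and must be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Set, Tuple

import pandas as pd

from . import align

MIN_TE_SPAN = 1000  # strict: "over 1 kb"


@dataclass(frozen=True)
class ReadHomologyRecord:
    read_id: str
    read_length: int
    best_family: Optional[str]
    best_span: int
    spans: dict = field(default_factory=dict)  # family -> span

    def __post_init__(self):
        if self.best_span > self.read_length:
            raise ValueError("aligned span cannot exceed read length")


def scan_read(
    read_id: str,
    sequence: str,
    library: Dict[str, str],
    prescreen_k: Optional[int] = 2,
) -> ReadHomologyRecord:
    """Align one read against the consensus library (same exact
    Smith-Waterman engine as insertion annotation)."""
    hits = align.scan_library(sequence, library, prescreen_k=prescreen_k)
    spans = {fam: h.span for fam, h in hits.items()}
    best = sorted(hits.values(), key=lambda h: (-h.span, -h.score, h.family))[0]
    return ReadHomologyRecord(
        read_id=read_id,
        read_length=len(sequence),
        best_family=best.family if best.span > 0 else None,
        best_span=min(best.span, len(sequence)),
        spans=spans,
    )


def classify_te_read(record: ReadHomologyRecord, min_span: int = MIN_TE_SPAN) -> bool:
    """TE-derived iff the best single-consensus span is strictly greater
    than ``min_span``."""
    return record.best_span > min_span


def detect_spliced_leader(
    sequence: str,
    sl_motif: str,
    window: int = 30,
    max_mismatch: int = 1,
) -> bool:
    """True iff the SL motif occurs within the first ``window`` bases with
    at most ``max_mismatch`` substitutions."""
    if len(sl_motif) < 6:
        raise ValueError("SL motif must be at least 6 bases")
    seq = sequence.upper()
    motif = sl_motif.upper()
    k = len(motif)
    last_start = min(window - 1, len(seq) - k)
    for start in range(0, last_start + 1):
        mismatches = sum(a != b for a, b in zip(seq[start:start + k], motif))
        if mismatches <= max_mismatch:
            return True
    return False


def sl_fraction(
    reads: Sequence[Tuple[str, str]],
    records: Dict[str, ReadHomologyRecord],
    sl_motif: str,
    min_span: int = MIN_TE_SPAN,
    window: int = 30,
    max_mismatch: int = 1,
) -> Tuple[float, float]:
    """SL-bearing fraction among TE-derived and non-TE reads.

    ``reads`` is (read_id, sequence) pairs; ``records`` holds their
    homology scans. Returns (fraction among TE reads, among non-TE reads);
    NaN when a group is empty.
    """
    te_sl = te_n = non_sl = non_n = 0
    for read_id, seq in reads:
        is_te = classify_te_read(records[read_id], min_span=min_span)
        has_sl = detect_spliced_leader(seq, sl_motif, window, max_mismatch)
        if is_te:
            te_n += 1
            te_sl += has_sl
        else:
            non_n += 1
            non_sl += has_sl
    return (
        te_sl / te_n if te_n else float("nan"),
        non_sl / non_n if non_n else float("nan"),
    )


def expression_rank_membership(
    expression: Dict[str, float], quantile: float = 0.2
) -> Set[str]:
    """Families at or above the (1 - quantile) empirical expression
    quantile; ties at the cutoff are included."""
    if len(expression) < 5:
        raise ValueError("need at least five families")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    series = pd.Series(expression)
    cutoff = series.quantile(1 - quantile, interpolation="higher")
    return set(series.index[series >= cutoff])


def write_read_report(
    reads: Sequence[Tuple[str, str]],
    records: Dict[str, ReadHomologyRecord],
    sl_motif: Optional[str],
    path,
    min_span: int = MIN_TE_SPAN,
) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tlength\tbest_family\tbest_span\tte_derived\tsl\n")
        for read_id, seq in reads:
            r = records[read_id]
            te = classify_te_read(r, min_span=min_span)
            sl = (
                detect_spliced_leader(seq, sl_motif) if sl_motif is not None else False
            )
            fh.write(
                f"{read_id}\t{r.read_length}\t{r.best_family or '.'}\t"
                f"{r.best_span}\t{int(te)}\t{int(sl)}\n"
            )
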