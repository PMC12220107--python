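"""Core domain types shared across the pipeline.

All genomic coordinates inside the package are 0-based, half-open
(``[start, end)``). External formats that use other conventions
(RepeatMasker ``.out``: 1-based inclusive; VCF ``POS``: 1-based) are
converted at the parsing boundary and nowhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

TE_CLASSES = ("DNA", "LINE", "SINE", "LTR", "RC", "Unknown", "non-TE")

#: Classes counted as transposable elements (everything except non-TE).
#: "Unknown" repeats are kept as TEs, mirroring common repeat-annotation
#: practice where unclassified interspersed repeats are mostly decayed TEs.
TE_LIKE_CLASSES = frozenset(("DNA", "LINE", "SINE", "LTR", "RC", "Unknown"))


class SaturationError(ValueError):
    """Raised when observed substitution proportions exceed the domain of
    the two-parameter distance estimator."""

    def __init__(self, p: float, q: float):
        self.p = p
        self.q = q
        super().__init__(
            f"divergence estimator saturated: P={p:.4f}, Q={q:.4f} "
            f"(requires 1-2P-Q > 0 and 1-2Q > 0)"
        )


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class RepeatHit:
    """One annotated repeat interval on a genome."""

    interval: GenomicInterval
    family: str
    te_class: str
    divergence_pct: Optional[float] = None
    score: Optional[float] = None
    hit_id: Optional[str] = None

    def __post_init__(self):
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown te_class {self.te_class!r}")
        if self.divergence_pct is not None and self.divergence_pct < 0:
            raise ValueError("divergence_pct must be >= 0")


_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_GAPS = frozenset("-.")


def _site_kind(a: str, b: str) -> Optional[str]:
    """Classify one ungapped aligned column: 'same'/'ts'/'tv', None if either
    base is ambiguous."""
    if a == b:
        return "same"
    in_pur = a in _PURINES, b in _PURINES
    in_pyr = a in _PYRIMIDINES, b in _PYRIMIDINES
    if not ((in_pur[0] or in_pyr[0]) and (in_pur[1] or in_pyr[1])):
        return None
    if (all(in_pur)) or (all(in_pyr)):
        return "ts"
    return "tv"


@dataclass(frozen=True)
class AlignmentBlock:
    """Counts summarizing one genome-copy vs consensus pairwise alignment.

    Holds either precomputed counts over ungapped aligned columns, or is
    built from a gapped alignment pair via :meth:`from_gapped`.
    """

    hit_id: str
    n_sites: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self):
        if self.n_sites < 0 or self.n_transitions < 0 or self.n_transversions < 0:
            raise ValueError("counts must be non-negative")
        if self.n_transitions + self.n_transversions > self.n_sites:
            raise ValueError("transitions + transversions exceed aligned sites")

    @classmethod
    def from_gapped(
        cls,
        hit_id: str,
        query_gapped: str,
        consensus_gapped: str,
        cpg_mode: str = "include",
    ) -> "AlignmentBlock":
        """Count ungapped aligned columns and substitution types.

        Gap columns never count as sites. ``cpg_mode='exclude'`` removes
        columns where the consensus base starts a CpG dinucleotide (the C
        and the following G, gaps ignored when pairing them).
        """
        if len(query_gapped) != len(consensus_gapped):
            raise ValueError("gapped strings must have equal length")
        if cpg_mode not in ("include", "exclude"):
            raise ValueError("cpg_mode must be 'include' or 'exclude'")
        q = query_gapped.upper()
        c = consensus_gapped.upper()
        skip = set()
        if cpg_mode == "exclude":
            cons_pos = [i for i, ch in enumerate(c) if ch not in _GAPS]
            for j in range(len(cons_pos) - 1):
                i1, i2 = cons_pos[j], cons_pos[j + 1]
                if c[i1] == "C" and c[i2] == "G":
                    skip.add(i1)
                    skip.add(i2)
        n = ts = tv = 0
        for i, (a, b) in enumerate(zip(q, c)):
            if a in _GAPS or b in _GAPS or i in skip:
                continue
            kind = _site_kind(a, b)
            if kind is None:
                continue
            n += 1
            if kind == "ts":
                ts += 1
            elif kind == "tv":
                tv += 1
        return cls(hit_id=hit_id, n_sites=n, n_transitions=ts, n_transversions=tv)

    @property
    def p(self) -> float:
        return self.n_transitions / self.n_sites

    @property
    def q(self) -> float:
        return self.n_transversions / self.n_sites


@dataclass(frozen=True)
class InsertionCall:
    """One multi-sample insertion variant (VCF semantics: pos is 1-based)."""

    chrom: str
    pos: int
    length: int
    genotypes: dict
    sequence: Optional[str] = None
    support: Optional[int] = None
    call_id: Optional[str] = None

    def __post_init__(self):
        if self.sequence is not None:
            if self.length != len(self.sequence):
                raise ValueError("length must equal |sequence| when sequence present")
        elif self.length < 1:
            raise ValueError("length must be >= 1")

    def is_fully_genotyped(self) -> bool:
        return all(g in ("0/0", "0/1", "1/1") for g in self.genotypes.values())

    def carriers(self) -> frozenset:
        return frozenset(
            s for s, g in self.genotypes.items() if g in ("0/1", "1/1")
        )


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    exons: tuple = ()

    def __post_init__(self):
        for e in self.exons:
            if not (
                e.chrom == self.interval.chrom
                and e.start >= self.interval.start
                and e.end <= self.interval.end
            ):
                raise ValueError(f"exon {e} outside gene span of {self.gene_id}")
        ex = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ex, ex[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping exons in {self.gene_id}")


def load_classification_map(path=None) -> dict:
    """family -> te_class map; defaults to the packaged TSV resource."""
    mapping = {}
    if path is None:
        text = (
            resources.files("tescope.data").joinpath("te_classes.tsv").read_text()
        )
        lines = text.splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"malformed classification line: {line!r}")
        family, te_class = fields
        if te_class not in TE_CLASSES:
            raise ValueError(f"unknown te_class {te_class!r} for {family!r}")
        mapping[family] = te_class
    return mapping


_CLASS_FIELD_PREFIXES = {
    "DNA": "DNA",
    "LINE": "LINE",
    "SINE": "SINE",
    "LTR": "LTR",
    "RC": "RC",
    "ROLLING-CIRCLE": "RC",
    "UNKNOWN": "Unknown",
    "UNSPECIFIED": "Unknown",
}


def classify_family(
    family: str, class_field: Optional[str] = None, mapping: Optional[dict] = None
) -> str:
    """Deterministically map a repeat family name to a major TE class.

    Resolution order: explicit RepeatMasker-style ``class/family`` field
    prefix; exact match in the classification map; longest-prefix match in
    the map (handles subfamily suffixes like ``hAT-Tip100_Hv3``); Unknown.
    """
    if mapping is None:
        mapping = _default_map()
    if class_field:
        head = class_field.split("/")[0].upper()
        if head in _CLASS_FIELD_PREFIXES:
            return _CLASS_FIELD_PREFIXES[head]
        if head in ("SIMPLE_REPEAT", "LOW_COMPLEXITY", "SATELLITE", "RRNA",
                    "SNRNA", "SCRNA", "TRNA-GENE", "ARTEFACT"):
            return "non-TE"
    if family in mapping:
        return mapping[family]
    best = None
    for key, cls in mapping.items():
        if family.startswith(key) and (best is None or len(key) > len(best[0])):
            best = (key, cls)
    if best is not None:
        return best[1]
    return "Unknown"


_DEFAULT_MAP = None


def _default_map() -> dict:
    global _DEFAULT_MAP
    if _DEFAULT_MAP is None:
        _DEFAULT_MAP = load_classification_map()
    return _DEFAULT_MAP
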