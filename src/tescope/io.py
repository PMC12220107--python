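"""Readers and writers for every external format the pipeline touches.

Parsing normalizes all coordinates to the internal 0-based half-open
convention; writers convert back at the boundary:

* RepeatMasker ``.out`` (15-column dialect): 1-based inclusive.
* VCF 4.2 (via pysam): ``POS`` 1-based.
* BED3+ and the package's own TSV dialects: already 0-based half-open.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import gffutils
import pysam
from Bio import SeqIO

from .models import (
    AlignmentBlock,
    GenomicInterval,
    GeneModel,
    InsertionCall,
    RepeatHit,
    classify_family,
)

log = logging.getLogger(__name__)

_RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)   repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)

_TSV_COLUMNS = [
    "chrom", "start", "end", "strand", "family",
    "te_class", "divergence_pct", "score", "hit_id",
]


@dataclass
class ParseResult:
    """Parsed records plus per-file diagnostics."""

    records: list
    warnings: List[str] = field(default_factory=list)

    @property
    def n_malformed(self) -> int:
        return len(self.warnings)


def parse_repeat_annotation(
    path, dialect: str = "rm_out", classification_map: Optional[dict] = None
) -> ParseResult:
    """Read a repeat annotation table into :class:`RepeatHit` records.

    ``rm_out`` is the 15-column RepeatMasker ``.out`` layout (1-based
    inclusive coordinates, strand ``C`` for the reverse strand); ``tsv``
    is the package's 0-based half-open dialect. Malformed lines are
    skipped, counted, and reported in the result's ``warnings``.
    """
    if dialect not in ("rm_out", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    hits: List[RepeatHit] = []
    warnings: List[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if dialect == "tsv":
        body = [l for l in lines if l and not l.startswith("#")]
        if body and body[0].split("\t")[0] == "chrom":
            body = body[1:]
        for lineno, line in enumerate(body, 1):
            try:
                hits.append(_hit_from_tsv(line, classification_map))
            except Exception as exc:
                warnings.append(f"line {lineno}: {exc}")
        return ParseResult(hits, warnings)
    for lineno, line in enumerate(lines, 1):
        stripped = line.strip()
        if not stripped or stripped.startswith(("SW", "score", "There were no")):
            continue
        fields = stripped.split()
        if len(fields) < 14:
            warnings.append(f"line {lineno}: expected >=14 columns, got {len(fields)}")
            continue
        try:
            hits.append(_hit_from_rm_fields(fields, classification_map))
        except Exception as exc:
            warnings.append(f"line {lineno}: {exc}")
    return ParseResult(hits, warnings)


def _hit_from_rm_fields(fields, classification_map) -> RepeatHit:
    score = float(fields[0])
    div = float(fields[1])
    chrom = fields[4]
    begin = int(fields[5])
    end = int(fields[6])
    if end < begin:
        raise ValueError(f"end {end} < begin {begin}")
    strand = "+" if fields[8] == "+" else "-"
    family = fields[9]
    class_field = fields[10]
    hit_id = fields[14] if len(fields) > 14 else None
    interval = GenomicInterval(chrom, begin - 1, end, strand)
    te_class = classify_family(family, class_field, classification_map)
    return RepeatHit(
        interval=interval, family=family, te_class=te_class,
        divergence_pct=div, score=score, hit_id=hit_id,
    )


def _hit_from_tsv(line: str, classification_map) -> RepeatHit:
    f = line.split("\t")
    if len(f) != len(_TSV_COLUMNS):
        raise ValueError(f"expected {len(_TSV_COLUMNS)} columns, got {len(f)}")
    chrom, start, end, strand, family, te_class, div, score, hit_id = f
    interval = GenomicInterval(chrom, int(start), int(end), strand)
    if te_class == ".":
        te_class = classify_family(family, None, classification_map)
    return RepeatHit(
        interval=interval,
        family=family,
        te_class=te_class,
        divergence_pct=None if div == "." else float(div),
        score=None if score == "." else float(score),
        hit_id=None if hit_id == "." else hit_id,
    )


def write_repeat_annotation(hits, path, dialect: str = "rm_out") -> None:
    if dialect not in ("rm_out", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write("\t".join(_TSV_COLUMNS) + "\n")
            for h in hits:
                iv = h.interval
                fh.write(
                    "\t".join([
                        iv.chrom, str(iv.start), str(iv.end), iv.strand, h.family,
                        h.te_class,
                        "." if h.divergence_pct is None else f"{h.divergence_pct:g}",
                        "." if h.score is None else f"{h.score:g}",
                        h.hit_id or ".",
                    ]) + "\n"
                )
            return
        fh.write(_RM_HEADER)
        for i, h in enumerate(hits, 1):
            iv = h.interval
            strand = "+" if iv.strand != "-" else "C"
            fh.write(
                f"{h.score if h.score is not None else 0:7.0f} "
                f"{h.divergence_pct if h.divergence_pct is not None else 0.0:5.2f} "
                f" 0.00  0.00  {iv.chrom}  {iv.start + 1}  {iv.end}  (0)  "
                f"{strand}  {h.family}  {h.te_class}/{h.family}  1  {len(iv)}  (0)  "
                f"{h.hit_id or i}\n"
            )


def parse_alignment_blocks(path) -> Dict[str, AlignmentBlock]:
    """TSV of per-hit substitution counts: hit_id, n_sites, n_transitions,
    n_transversions."""
    blocks: Dict[str, AlignmentBlock] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("hit_id"):
                continue
            hit_id, n, ts, tv = line.split("\t")
            blocks[hit_id] = AlignmentBlock(
                hit_id=hit_id, n_sites=int(n),
                n_transitions=int(ts), n_transversions=int(tv),
            )
    return blocks


def write_alignment_blocks(blocks, path) -> None:
    with open(path, "w") as fh:
        fh.write("hit_id\tn_sites\tn_transitions\tn_transversions\n")
        items = blocks.values() if isinstance(blocks, dict) else blocks
        for b in items:
            fh.write(f"{b.hit_id}\t{b.n_sites}\t{b.n_transitions}\t{b.n_transversions}\n")


def _info_field(rec, key):
    # pysam raises on INFO keys absent from the header; treat as missing
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def parse_insertion_calls(path) -> Tuple[List[str], List[InsertionCall], List[str]]:
    """Read a multi-sample VCF, keeping only SVTYPE=INS records.

    Returns ``(sample roster, calls, warnings)``. Genotypes are preserved
    verbatim, including ``./.`` — completeness filtering is a downstream
    stage. Records with neither SVLEN nor an explicit inserted sequence
    are rejected with a warning.
    """
    warnings: List[str] = []
    calls: List[InsertionCall] = []
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        vf = pysam.VariantFile(str(path))
        roster = list(vf.header.samples)
        for rec in vf:
            svtype = _info_field(rec, "SVTYPE")
            if svtype != "INS":
                warnings.append(f"{rec.chrom}:{rec.pos}: dropped SVTYPE={svtype}")
                continue
            sequence = None
            if rec.alts and all(c in "ACGTNacgtn" for c in rec.alts[0]):
                alt = rec.alts[0]
                ref = rec.ref or ""
                # Sniffles-style ALT carries REF anchor base + inserted seq.
                sequence = alt[len(ref):] if alt.startswith(ref) else alt
                if not sequence:
                    sequence = None
            svlen = _info_field(rec, "SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            if svlen is None and sequence is None:
                warnings.append(f"{rec.chrom}:{rec.pos}: no SVLEN and no sequence")
                continue
            length = len(sequence) if sequence is not None else abs(int(svlen))
            genotypes = {}
            for s in roster:
                gt = rec.samples[s].get("GT")
                if gt is None or all(a is None for a in gt):
                    genotypes[s] = "./."
                else:
                    genotypes[s] = "/".join("." if a is None else str(a) for a in gt)
            support = _info_field(rec, "SUPPORT")
            calls.append(
                InsertionCall(
                    chrom=rec.chrom, pos=rec.pos, length=length,
                    sequence=sequence, genotypes=genotypes,
                    support=None if support is None else int(support),
                    call_id=rec.id,
                )
            )
    rosters = {frozenset(c.genotypes) for c in calls}
    if len(rosters) > 1:
        raise ValueError("sample roster mismatch across records")
    return roster, calls, warnings


def write_insertion_calls(
    calls, path, roster, contig_lengths: Optional[Dict[str, int]] = None
) -> None:
    """Write INS records as plain-text VCF 4.2 (ALT carries the sequence
    when known, symbolic ``<INS>`` otherwise)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=tescope\n")
        for chrom, length in sorted((contig_lengths or {}).items()):
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##ALT=<ID=INS,Description="Insertion">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Read support">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(roster) + "\n")
        for i, c in enumerate(calls, 1):
            alt = "N" + c.sequence if c.sequence is not None else "<INS>"
            info = f"SVTYPE=INS;SVLEN={c.length}"
            if c.support is not None:
                info += f";SUPPORT={c.support}"
            gts = "\t".join(c.genotypes[s] for s in roster)
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.call_id or 'ins' + str(i)}\tN\t{alt}\t.\t"
                f"PASS\t{info}\tGT\t{gts}\n"
            )


def parse_features(
    gff_path=None, bed_path=None, fasta_path=None
) -> Tuple[List[GeneModel], List[GenomicInterval], Dict[str, str]]:
    """Load gene models (GFF3), intervals (BED3+) and sequences (FASTA).

    Any of the three paths may be ``None``; the corresponding return slot
    is then empty. Exons without a resolvable parent gene are dropped with
    a warning; duplicate FASTA names are fatal.
    """
    genes: List[GeneModel] = []
    if gff_path is not None:
        db = gffutils.create_db(
            str(gff_path), ":memory:", merge_strategy="create_unique",
            keep_order=True,
        )
        gene_ids = set()
        for g in db.features_of_type("gene"):
            gene_ids.add(g.id)
            exons = tuple(
                GenomicInterval(e.seqid, e.start - 1, e.end, e.strand or ".")
                for e in db.children(g, featuretype="exon", order_by="start")
            )
            genes.append(
                GeneModel(
                    gene_id=g.id,
                    interval=GenomicInterval(g.seqid, g.start - 1, g.end, g.strand or "."),
                    exons=exons,
                )
            )
        for e in db.features_of_type("exon"):
            parents = e.attributes.get("Parent", [])
            if not parents or not any(p in gene_ids for p in parents):
                log.warning("orphan exon %s dropped", e.id)
    intervals: List[GenomicInterval] = []
    if bed_path is not None:
        with open(bed_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                strand = f[5] if len(f) > 5 else "."
                intervals.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    sequences: Dict[str, str] = {}
    if fasta_path is not None:
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            if rec.id in sequences:
                raise ValueError(f"duplicate sequence name {rec.id!r} in FASTA")
            sequences[rec.id] = str(rec.seq).upper()
    return genes, intervals, sequences


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def write_gff3(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            strand = iv.strand if iv.strand != "." else "+"
            fh.write(
                f"{iv.chrom}\ttescope\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{strand}\t.\tID={g.gene_id}\n"
            )
            for j, e in enumerate(g.exons, 1):
                fh.write(
                    f"{e.chrom}\ttescope\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{strand}\t.\tID={g.gene_id}.exon{j};Parent={g.gene_id}\n"
                )


def write_fasta(sequences: Dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
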