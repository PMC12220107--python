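"""Seeded synthetic inputs with the statistical structure the pipeline
assumes: a pair of haplotype "assemblies" whose size difference is driven
by a few expanded TE families, a lineage-structured insertion cohort
(shared background plus lineage-private insertions, optional target-site
duplications), genomic features (genes, open-chromatin regions) with
lineage-dependent insertion overlap rates, distance-decaying contact maps
whose long-range signal tracks per-bin active-TE coverage, and a
cross-species family-retention panel with a planted core block.

Everything is generated at roughly 1/100 of Hydra scale (10 Mb haplotypes,
20 families) so the full pipeline runs on a desk machine; bp thresholds
must be rescaled accordingly. Every emitted record appears in exactly one
truth-table row, and a fixed seed reproduces every file byte for byte.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as tio
from .landscape import CoverageProfile
from .models import (
    AlignmentBlock,
    GeneModel,
    GenomicInterval,
    InsertionCall,
    RepeatHit,
    classify_family,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_TS_PARTNER = np.array([2, 3, 0, 1])           # A<->G, C<->T
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])

#: Spliced-leader motif used by the synthetic transcript reads.
SYNTHETIC_SL_MOTIF = "GGTAATTACCTCAGTTTC"


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class FamilySpec:
    name: str
    te_class: str
    consensus_length: int
    n_copies: int
    divergence_mean: float   # K, substitutions/site
    divergence_sd: float


@dataclass(frozen=True)
class CohortSpec:
    samples: Dict[str, str] = field(
        default_factory=lambda: {"icell": "i-cell", "ecto": "ecto", "endo": "endo"}
    )
    private_counts: Dict[str, int] = field(
        default_factory=lambda: {"i-cell": 73, "ecto": 41, "endo": 52}
    )
    shared_count: int = 300
    missing_fraction: float = 0.1
    short_fraction: float = 0.1          # planted at <= 1 kb (filter exercise)
    te_fraction: float = 0.7             # of non-short insertions
    tsd_probability: float = 0.5
    tsd_min: int = 4
    tsd_max: int = 12
    insertion_divergence: float = 0.02   # K of inserted TE copies
    emit_sequences: bool = True          # False: SVLEN-only records (fast)
    genome_length: int = 2_000_000
    chrom: str = "chrA"
    ocr_multipliers: Dict[str, float] = field(
        default_factory=lambda: {"i-cell": 0.5, "ecto": 1.0, "endo": 1.0,
                                 "shared": 1.0}
    )


@dataclass(frozen=True)
class FeatureSpec:
    n_genes: int = 300
    gene_length: int = 3000
    exons_per_gene: int = 3
    n_ocrs: int = 160
    ocr_length: int = 1000


@dataclass(frozen=True)
class ContactSpec:
    bin_size: int = 100_000
    decay_exponent: float = 1.0
    base_intensity: float = 100.0
    range_multiplier: float = 2.0
    max_sep: int = 40


@dataclass(frozen=True)
class SpeciesSpec:
    n_species: int = 12
    n_core: int = 12
    core_share: float = 0.7
    noise_sd: float = 0.005
    presence_prob: float = 0.8
    total_te_bp: int = 5_000_000


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_length: int = 10_000_000
    families: Tuple[FamilySpec, ...] = ()
    expansion_bp: Dict[str, int] = field(default_factory=dict)
    expansion_divergence: float = 0.02
    ts_tv_ratio: float = 2.0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    features: FeatureSpec = field(default_factory=FeatureSpec)
    contacts: ContactSpec = field(default_factory=ContactSpec)
    species: SpeciesSpec = field(default_factory=SpeciesSpec)

    def __post_init__(self):
        if not self.families:
            object.__setattr__(self, "families", default_families())
        if not self.expansion_bp:
            object.__setattr__(self, "expansion_bp", default_expansion(self.families))
        known = {f.name for f in self.families}
        if not set(self.expansion_bp) <= known:
            raise ValueError("expansion_spec families must be a subset of families")


_ATE_NAMES = [
    "hAT-Ac", "hAT-Charlie", "hAT-hATm", "hAT-Tip100", "TcMar-Tc1",
    "TcMar-Fot1", "Maverick", "Sola-2", "MULE-MuDR", "CMC-EnSpm",
    "CMC-Transib", "CR1", "L2", "Gypsy",
]
_OTHER_NAMES = ["Copia", "Penelope", "RTE", "MIR", "PiggyBac", "Helitron"]


def default_families() -> Tuple[FamilySpec, ...]:
    """20 families mirroring the Hydra A-TE roster plus six bystanders,
    ~40% total TE content on a 10 Mb haplotype."""
    specs = []
    names = _ATE_NAMES + _OTHER_NAMES
    for i, name in enumerate(names):
        specs.append(
            FamilySpec(
                name=name,
                te_class=classify_family(name),
                consensus_length=1200 + 150 * (i % 7),
                n_copies=80 + 13 * (i % 5),
                divergence_mean=0.05 + 0.02 * (i % 6),
                divergence_sd=0.01,
            )
        )
    return tuple(specs)


def default_expansion(families: Sequence[FamilySpec]) -> Dict[str, int]:
    """8 families expanded above the scaled 25 kb A-TE threshold, 4 below
    it, the rest unchanged (1/100 of the 2.5 Mb full-scale cutoff)."""
    supra = [f.name for f in families[:8]]
    sub = [f.name for f in families[8:12]]
    exp = {name: 30_000 + 5_000 * i for i, name in enumerate(supra)}
    exp.update({name: 8_000 + 3_000 * i for i, name in enumerate(sub)})
    return exp


# ---------------------------------------------------------------------------
# K2P mutation engine


def k2p_site_probabilities(target_k: float, ts_tv_ratio: float) -> Tuple[float, float]:
    """Expected (P, Q) per ungapped site after evolving a distance of
    ``target_k`` substitutions/site under the two-parameter model with the
    given expected transition/transversion ratio."""
    if target_k < 0:
        raise ValueError("target_K must be >= 0")
    if ts_tv_ratio <= 0:
        raise ValueError("ts_tv_ratio must be > 0")
    # rates normalized so branch length equals expected substitutions/site:
    # alpha + 2*beta = 1 with alpha/(2*beta) = ts_tv_ratio
    beta = 1.0 / (2.0 * (ts_tv_ratio + 1.0))
    alpha = ts_tv_ratio / (ts_tv_ratio + 1.0)
    e1 = math.exp(-2.0 * (alpha + beta) * target_k)
    e2 = math.exp(-4.0 * beta * target_k)
    p = 0.25 - 0.5 * e1 + 0.25 * e2
    q = 0.5 - 0.5 * e2
    if 1.0 - 2.0 * p - q < 1e-3 or 1.0 - 2.0 * q < 1e-3:
        raise ValueError(
            f"target_K={target_k} is beyond the saturation bound of the "
            "two-parameter model; the distance is not recoverable"
        )
    return p, q


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def mutate_copy(
    consensus: str,
    target_k: float,
    ts_tv_ratio: float = 2.0,
    indel_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> Tuple[str, AlignmentBlock]:
    """Evolve a consensus copy to an expected divergence of ``target_k``.

    Substitutions follow the two-parameter model; each site is deleted
    with probability ``indel_rate/2`` and gains a short random insertion
    after it with probability ``indel_rate/2``. The returned truth block
    carries the exact realized transition/transversion counts over the
    surviving (substitution-eligible) sites.
    """
    if len(consensus) < 50:
        raise ValueError("consensus must be at least 50 bp")
    if rng is None:
        rng = np.random.default_rng(seed)
    p, q = k2p_site_probabilities(target_k, ts_tv_ratio)
    codes = np.frombuffer(consensus.upper().encode(), dtype="S1")
    idx = np.searchsorted(_BASES, codes)
    if not np.all(_BASES[idx] == codes):
        raise ValueError("consensus must contain only ACGT")
    keep = np.ones(len(idx), dtype=bool)
    if indel_rate > 0:
        keep = rng.random(len(idx)) >= indel_rate / 2.0
    kept = idx[keep]
    u = rng.random(len(kept))
    is_ts = u < p
    is_tv = (u >= p) & (u < p + q)
    out = kept.copy()
    out[is_ts] = _TS_PARTNER[kept[is_ts]]
    tv_sites = np.nonzero(is_tv)[0]
    tv_choice = rng.integers(0, 2, size=len(tv_sites))
    out[tv_sites] = _TV_PARTNERS[kept[tv_sites], tv_choice]
    seq = _BASES[out].tobytes().decode()
    if indel_rate > 0:
        pieces = []
        ins_mask = rng.random(len(out)) < indel_rate / 2.0
        lengths = rng.integers(1, 4, size=int(ins_mask.sum()))
        ins_at = np.nonzero(ins_mask)[0]
        prev = 0
        for pos, ln in zip(ins_at, lengths):
            pieces.append(seq[prev:pos + 1])
            pieces.append(random_sequence(rng, int(ln)))
            prev = pos + 1
        pieces.append(seq[prev:])
        seq = "".join(pieces)
    truth = AlignmentBlock(
        hit_id="copy",
        n_sites=int(len(kept)),
        n_transitions=int(is_ts.sum()),
        n_transversions=int(is_tv.sum()),
    )
    return seq, truth


def sample_substitution_counts(
    rng: np.random.Generator, n_sites: int, target_k: float, ts_tv_ratio: float
) -> Tuple[int, int]:
    """Realized (transitions, transversions) for one copy without
    materializing its sequence."""
    p, q = k2p_site_probabilities(target_k, ts_tv_ratio)
    ts, tv, _ = rng.multinomial(n_sites, [p, q, 1.0 - p - q])
    return int(ts), int(tv)


# ---------------------------------------------------------------------------
# haplotype pair


@dataclass
class SimulatedHaplotypes:
    hits_a: List[RepeatHit]
    hits_b: List[RepeatHit]
    blocks_a: Dict[str, AlignmentBlock]
    blocks_b: Dict[str, AlignmentBlock]
    genome_length_a: int
    genome_length_b: int
    truth: pd.DataFrame  # family, cov_a, cov_b, delta, expanded


def simulate_haplotype_pair(config: SimulationConfig) -> SimulatedHaplotypes:
    """Plant non-overlapping family copies on two haplotypes.

    Haplotype B carries each family's base copy complement; haplotype A
    carries the same complement plus the configured expansion copies at
    low divergence, so A's genome length exceeds B's by exactly the
    planted expansion bp and the per-family coverage delta is exact by
    construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    fam_by_name = {f.name: f for f in config.families}
    copies_b: List[Tuple[str, int, float]] = []   # (family, length, K)
    for f in config.families:
        for _ in range(f.n_copies):
            k = max(0.0, rng.normal(f.divergence_mean, f.divergence_sd))
            copies_b.append((f.name, f.consensus_length, k))
    extra_a: List[Tuple[str, int, float]] = []
    realized_expansion: Dict[str, int] = {}
    for name in sorted(config.expansion_bp):
        f = fam_by_name[name]
        n_extra = max(1, round(config.expansion_bp[name] / f.consensus_length))
        realized_expansion[name] = n_extra * f.consensus_length
        for _ in range(n_extra):
            k = max(0.0, rng.normal(config.expansion_divergence, 0.005))
            extra_a.append((name, f.consensus_length, k))
    total_b = sum(length for _, length, _ in copies_b)
    if total_b > config.genome_length:
        raise ValueError("planted copies exceed genome length")
    genome_b = config.genome_length
    genome_a = genome_b + sum(realized_expansion.values())
    hits_b, blocks_b = _place_copies(
        rng, copies_b, genome_b, config.ts_tv_ratio, "B"
    )
    copies_a = copies_b + extra_a
    hits_a, blocks_a = _place_copies(
        rng, copies_a, genome_a, config.ts_tv_ratio, "A"
    )
    rows = []
    cov_b = {f.name: f.n_copies * f.consensus_length for f in config.families}
    for f in config.families:
        ca = cov_b[f.name] + realized_expansion.get(f.name, 0)
        rows.append((f.name, ca, cov_b[f.name], ca - cov_b[f.name],
                     f.name in realized_expansion))
    truth = pd.DataFrame(
        rows, columns=["family", "cov_a", "cov_b", "delta", "expanded"]
    )
    return SimulatedHaplotypes(
        hits_a=hits_a, hits_b=hits_b, blocks_a=blocks_a, blocks_b=blocks_b,
        genome_length_a=genome_a, genome_length_b=genome_b, truth=truth,
    )


def _place_copies(rng, copies, genome_length, ts_tv_ratio, tag):
    """Lay copies end to end with random spacers on one chromosome."""
    order = rng.permutation(len(copies))
    total = sum(length for _, length, _ in copies)
    slack = genome_length - total
    gaps = rng.multinomial(slack, np.full(len(copies) + 1, 1.0 / (len(copies) + 1)))
    hits: List[RepeatHit] = []
    blocks: Dict[str, AlignmentBlock] = {}
    pos = 0
    for rank, i in enumerate(order):
        family, length, k = copies[i]
        pos += gaps[rank]
        hit_id = f"{tag}{rank:06d}"
        ts, tv = sample_substitution_counts(rng, length, k, ts_tv_ratio)
        blocks[hit_id] = AlignmentBlock(hit_id, length, ts, tv)
        strand = "+" if rng.random() < 0.5 else "-"
        hits.append(
            RepeatHit(
                interval=GenomicInterval("chr1", pos, pos + length, strand),
                family=family,
                te_class=classify_family(family),
                divergence_pct=round(100.0 * (ts + tv) / length, 4),
                score=float(length),
                hit_id=hit_id,
            )
        )
        pos += length
    return hits, blocks


# ---------------------------------------------------------------------------
# insertion cohort


@dataclass
class SimulatedCohort:
    roster: List[str]
    lineages: Dict[str, str]
    calls: List[InsertionCall]
    reference: str
    library: Dict[str, str]
    truth: pd.DataFrame
    flanks: Dict[str, Tuple[str, str]]


def _junction_duplication(left: str, right: str, min_len: int, max_len: int) -> bool:
    """Brute-force: does any suffix of ``left`` of length in
    [min_len, max_len] equal the same-length prefix of ``right``?"""
    for k in range(min_len, max_len + 1):
        if left[-k:] == right[:k]:
            return True
    return False


def simulate_insertion_cohort(
    config: SimulationConfig,
    ocrs: Optional[Sequence[GenomicInterval]] = None,
) -> SimulatedCohort:
    """Plant a lineage-structured insertion cohort on a synthetic
    reference.

    Private insertions are carried only by their lineage's sample, shared
    ones by every sample; a configurable fraction of records gets ``./.``
    in one sample to exercise the completeness filter, and a configurable
    fraction is planted at <= 1 kb to exercise the length filter. TE
    insertions are diverged library copies (optionally with a planted
    target-site duplication copied from the reference target site);
    non-TE insertions are random sequence, rejection-sampled so that no
    accidental junction duplication of TSD-detectable length exists.
    When ``ocrs`` are supplied, each lineage's open-chromatin overlap
    rate is its configured multiplier times the OCR genome fraction.
    """
    spec = config.cohort
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    if len(spec.samples) < 2:
        raise ValueError("roster must have at least two samples")
    if not spec.emit_sequences and spec.tsd_probability > 0:
        raise ValueError("TSDs require emit_sequences=True")
    reference = random_sequence(rng, spec.genome_length)
    lib_families = [f for f in config.families[:6]]
    library = {
        f.name: random_sequence(rng, max(f.consensus_length, 1100))
        for f in lib_families
    }
    ocr_union = _merge_intervals(ocrs) if ocrs else []
    ocr_bp = sum(e - s for s, e in ocr_union)
    base_rate = ocr_bp / spec.genome_length if ocr_bp else 0.0

    jobs: List[Tuple[str, str]] = [("shared", "shared")] * spec.shared_count
    for lineage, n in sorted(spec.private_counts.items()):
        if lineage not in set(spec.samples.values()):
            raise ValueError(f"private lineage {lineage!r} not in roster")
        jobs += [(f"specific:{lineage}", lineage)] * n
    calls: List[InsertionCall] = []
    rows = []
    flanks: Dict[str, Tuple[str, str]] = {}
    n_missing = int(round(spec.missing_fraction * len(jobs)))
    missing_ids = set(rng.choice(len(jobs), size=n_missing, replace=False).tolist())
    sample_names = sorted(spec.samples)
    lib_names = sorted(library)
    for i, (category, lineage) in enumerate(jobs):
        call_id = f"ins{i + 1:05d}"
        pos0 = _draw_position(rng, spec, ocr_union, base_rate, lineage)
        is_short = rng.random() < spec.short_fraction
        te_family = None
        tsd = None
        if not spec.emit_sequences:
            if is_short:
                length = int(rng.integers(200, 1001))
            else:
                length = int(rng.integers(1100, 3001))
            seq = None
        elif is_short:
            seq = random_sequence(rng, int(rng.integers(200, 1001)))
        elif rng.random() < spec.te_fraction:
            te_family = lib_names[int(rng.integers(0, len(lib_names)))]
            seq, _ = mutate_copy(
                library[te_family], spec.insertion_divergence,
                ts_tv_ratio=config.ts_tv_ratio, rng=rng,
            )
            if rng.random() < spec.tsd_probability:
                tsd_len = int(rng.integers(spec.tsd_min, spec.tsd_max + 1))
                tsd = reference[pos0:pos0 + tsd_len]
                while len(set(tsd)) == 1 or seq[-1] == tsd[0]:
                    pos0 = _draw_position(rng, spec, ocr_union, base_rate, lineage)
                    tsd = reference[pos0:pos0 + tsd_len]
                seq = seq + tsd
        else:
            seq = random_sequence(rng, int(rng.integers(1100, 3001)))
        right_flank = reference[pos0:pos0 + 50]
        if seq is not None and tsd is None:
            while _junction_duplication(seq, right_flank, 4, 25):
                seq = seq[:-25] + random_sequence(rng, 25)
        genotypes = {}
        for s in sample_names:
            lin = spec.samples[s]
            if category == "shared" or lin == lineage:
                genotypes[s] = "0/1" if rng.random() < 0.5 else "1/1"
            else:
                genotypes[s] = "0/0"
        excluded_reason = "."
        if i in missing_ids:
            victim = sample_names[int(rng.integers(0, len(sample_names)))]
            genotypes[victim] = "./."
            excluded_reason = "incomplete-genotype"
        elif is_short:
            excluded_reason = "too-short"
        call = InsertionCall(
            chrom=spec.chrom, pos=pos0 + 1,
            length=len(seq) if seq is not None else length,
            sequence=seq, genotypes=genotypes,
            support=int(rng.integers(3, 30)), call_id=call_id,
        )
        calls.append(call)
        if seq is not None:
            flanks[call_id] = (seq[-25:], right_flank[:25])
        in_ocr = _in_union(pos0, ocr_union)
        rows.append(
            (call_id, category, te_family or ".", tsd or ".",
             excluded_reason, call.length, int(in_ocr))
        )
    order = rng.permutation(len(calls))
    calls = [calls[i] for i in order]
    calls.sort(key=lambda c: c.pos)
    truth = pd.DataFrame(
        rows,
        columns=["call_id", "category", "te_family", "tsd",
                 "excluded_reason", "length", "in_ocr"],
    ).set_index("call_id")
    return SimulatedCohort(
        roster=sample_names,
        lineages={s: spec.samples[s] for s in sample_names},
        calls=calls,
        reference=reference,
        library=library,
        truth=truth,
        flanks=flanks,
    )


def _merge_intervals(intervals):
    spans = sorted((iv.start, iv.end) for iv in intervals)
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s > merged[-1][1]:
            merged.append([s, e])
        else:
            merged[-1][1] = max(merged[-1][1], e)
    return [tuple(x) for x in merged]


def _in_union(pos: int, union) -> bool:
    if not union:
        return False
    i = bisect.bisect_right(union, (pos, math.inf)) - 1
    return i >= 0 and union[i][0] <= pos < union[i][1]


def _draw_position(rng, spec: CohortSpec, ocr_union, base_rate, lineage) -> int:
    """Anchor position; lineage OCR-overlap rate = multiplier x OCR
    genome fraction, realized by choosing inside/outside the OCR union."""
    margin = 100
    if not ocr_union or base_rate == 0.0:
        return int(rng.integers(margin, spec.genome_length - margin))
    mult = spec.ocr_multipliers.get(lineage, 1.0)
    target = min(1.0, mult * base_rate)
    inside = rng.random() < target
    for _ in range(10_000):
        pos = int(rng.integers(margin, spec.genome_length - margin))
        if _in_union(pos, ocr_union) == inside:
            return pos
    raise RuntimeError("could not place insertion (OCR rejection sampling)")


# ---------------------------------------------------------------------------
# features, contacts, species panel


@dataclass
class SimulatedContext:
    genes: List[GeneModel]
    ocrs: List[GenomicInterval]
    contacts: pd.DataFrame
    n_bins: Dict[str, int]
    bin_coverage: np.ndarray
    species_profiles: Dict[str, CoverageProfile]
    species_core: Tuple[str, ...]


def simulate_context_and_contacts(
    config: SimulationConfig,
    bin_coverage: Optional[np.ndarray] = None,
) -> SimulatedContext:
    """Genes and OCRs on the cohort reference, a distance-decaying
    contact map whose intensity is lifted by per-bin active-TE coverage,
    and a species x family retention panel with a planted core block.

    Contact intensity for bins i, j at separation d is Poisson with mean
    ``base x (d+1)^-decay x sqrt(lift_i x lift_j)`` where
    ``lift = 1 + range_multiplier x coverage``; OCR overlap rates are
    honored when the insertion cohort is simulated with these OCRs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    fspec, cspec, sspec = config.features, config.contacts, config.species
    genome_length = config.cohort.genome_length
    chrom = config.cohort.chrom
    genes = _plant_genes(rng, fspec, chrom, genome_length)
    ocrs = _plant_ocrs(rng, fspec, chrom, genome_length)
    n_bins = {chrom: max(config.genome_length // cspec.bin_size, cspec.max_sep + 2)}
    nb = n_bins[chrom]
    if bin_coverage is None:
        bin_coverage = rng.beta(2.0, 5.0, size=nb)
    if len(bin_coverage) != nb:
        raise ValueError("bin_coverage length must match bin count")
    contacts = _plant_contacts(rng, cspec, chrom, nb, bin_coverage)
    profiles, core = _plant_species_panel(rng, config, sspec)
    return SimulatedContext(
        genes=genes, ocrs=ocrs, contacts=contacts, n_bins=n_bins,
        bin_coverage=np.asarray(bin_coverage), species_profiles=profiles,
        species_core=core,
    )


def _plant_genes(rng, fspec: FeatureSpec, chrom, genome_length) -> List[GeneModel]:
    pitch = genome_length // fspec.n_genes
    if pitch <= fspec.gene_length + 2:
        raise ValueError("genes do not fit in the genome")
    genes = []
    for i in range(fspec.n_genes):
        start = i * pitch + int(rng.integers(0, pitch - fspec.gene_length - 1))
        end = start + fspec.gene_length
        strand = "+" if rng.random() < 0.5 else "-"
        exon_len = fspec.gene_length // (2 * fspec.exons_per_gene)
        exons = []
        for j in range(fspec.exons_per_gene):
            es = start + j * 2 * exon_len
            exons.append(GenomicInterval(chrom, es, es + exon_len, strand))
        genes.append(
            GeneModel(
                gene_id=f"gene{i + 1:04d}",
                interval=GenomicInterval(chrom, start, end, strand),
                exons=tuple(exons),
            )
        )
    return genes


def _plant_ocrs(rng, fspec: FeatureSpec, chrom, genome_length) -> List[GenomicInterval]:
    pitch = genome_length // fspec.n_ocrs
    if pitch <= fspec.ocr_length:
        raise ValueError("OCRs do not fit in the genome")
    ocrs = []
    for i in range(fspec.n_ocrs):
        start = i * pitch + int(rng.integers(0, pitch - fspec.ocr_length))
        ocrs.append(GenomicInterval(chrom, start, start + fspec.ocr_length, "."))
    return ocrs


def _plant_contacts(rng, cspec: ContactSpec, chrom, nb, coverage) -> pd.DataFrame:
    lift = 1.0 + cspec.range_multiplier * np.asarray(coverage)
    rows_i, rows_j, vals = [], [], []
    for d in range(0, cspec.max_sep + 1):
        i = np.arange(0, nb - d)
        j = i + d
        mean = (
            cspec.base_intensity
            * (d + 1.0) ** (-cspec.decay_exponent)
            * np.sqrt(lift[i] * lift[j])
        )
        intensity = rng.poisson(mean)
        keep = intensity > 0
        rows_i.append(i[keep])
        rows_j.append(j[keep])
        vals.append(intensity[keep])
    return pd.DataFrame({
        "chrom": chrom,
        "bin_i": np.concatenate(rows_i),
        "bin_j": np.concatenate(rows_j),
        "intensity": np.concatenate(vals).astype(float),
    }).sort_values(["bin_i", "bin_j"], ignore_index=True)


def _plant_species_panel(rng, config, sspec: SpeciesSpec):
    families = [f.name for f in config.families]
    core = tuple(sorted(families[:sspec.n_core]))
    others = [f for f in families if f not in core]
    profiles: Dict[str, CoverageProfile] = {}
    for s in range(sspec.n_species):
        name = f"species{s + 1:02d}"
        shares = {}
        for fam in core:
            shares[fam] = max(
                1e-4, sspec.core_share / len(core) + rng.normal(0, sspec.noise_sd)
            )
        for fam in others:
            if rng.random() > sspec.presence_prob:
                continue
            shares[fam] = max(
                1e-4,
                (1 - sspec.core_share) / max(len(others), 1)
                + rng.normal(0, sspec.noise_sd),
            )
        total = sum(shares.values())
        per_family = {
            fam: max(1, int(round(v / total * sspec.total_te_bp)))
            for fam, v in shares.items()
        }
        profiles[name] = CoverageProfile(
            assembly_id=name,
            genome_length=sspec.total_te_bp * 2,
            per_family=per_family,
            per_class={},
            te_union=sum(per_family.values()),
        )
    return profiles, core


# ---------------------------------------------------------------------------
# transcript reads


@dataclass
class SimulatedReads:
    reads: List[Tuple[str, str]]
    truth: pd.DataFrame  # read_id, te_family (or .), sl (0/1)
    library: Dict[str, str]
    sl_motif: str


def simulate_te_reads(
    config: SimulationConfig,
    n_te: int = 60,
    n_other: int = 40,
    sl_rate: float = 0.3,
    sl_rate_other: float = 0.48,
) -> SimulatedReads:
    """Transcript-like reads: TE reads embed >1 kb of a diverged library
    consensus; others are random. SL-bearing reads carry the synthetic SL
    motif at the 5' end."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    lib_families = [f for f in config.families[:6]]
    library = {
        f.name: random_sequence(rng, max(f.consensus_length, 1100))
        for f in lib_families
    }
    lib_names = sorted(library)
    reads, rows = [], []
    for i in range(n_te + n_other):
        read_id = f"read{i + 1:04d}"
        is_te = i < n_te
        if is_te:
            family = lib_names[int(rng.integers(0, len(lib_names)))]
            core, _ = mutate_copy(library[family], 0.02, rng=rng)
            seq = (
                random_sequence(rng, int(rng.integers(50, 200)))
                + core
                + random_sequence(rng, int(rng.integers(50, 200)))
            )
            sl = rng.random() < sl_rate
        else:
            family = None
            seq = random_sequence(rng, int(rng.integers(800, 2500)))
            sl = rng.random() < sl_rate_other
        if sl:
            seq = SYNTHETIC_SL_MOTIF + seq
        reads.append((read_id, seq))
        rows.append((read_id, family or ".", int(sl)))
    truth = pd.DataFrame(rows, columns=["read_id", "te_family", "sl"]).set_index(
        "read_id"
    )
    return SimulatedReads(reads=reads, truth=truth, library=library,
                          sl_motif=SYNTHETIC_SL_MOTIF)


# ---------------------------------------------------------------------------
# fixture directory


def write_fixture(config: SimulationConfig, out_dir) -> Dict[str, Path]:
    """Generate the complete synthetic input bundle plus truth TSVs.

    Emits exactly the formats the io module parses; with a fixed seed the
    output is byte-identical across runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    hap = simulate_haplotype_pair(config)
    for tag, hits, blocks, glen in (
        ("a", hap.hits_a, hap.blocks_a, hap.genome_length_a),
        ("b", hap.hits_b, hap.blocks_b, hap.genome_length_b),
    ):
        paths[f"hits_{tag}"] = out / f"haplotype_{tag}.out"
        tio.write_repeat_annotation(hits, paths[f"hits_{tag}"], dialect="rm_out")
        paths[f"blocks_{tag}"] = out / f"haplotype_{tag}.blocks.tsv"
        tio.write_alignment_blocks(blocks, paths[f"blocks_{tag}"])
        (out / f"haplotype_{tag}.length").write_text(f"{glen}\n")
    paths["haplotype_truth"] = out / "truth_haplotypes.tsv"
    hap.truth.to_csv(paths["haplotype_truth"], sep="\t", index=False)

    ctx = simulate_context_and_contacts(config)
    paths["genes"] = out / "genes.gff3"
    tio.write_gff3(ctx.genes, paths["genes"])
    paths["ocrs"] = out / "ocrs.bed"
    tio.write_bed(ctx.ocrs, paths["ocrs"])
    paths["contacts"] = out / "contacts.tsv"
    from .contacts import write_contacts
    write_contacts(ctx.contacts, paths["contacts"])
    paths["bin_coverage"] = out / "bin_coverage.tsv"
    pd.DataFrame({
        "chrom": config.cohort.chrom,
        "bin": np.arange(len(ctx.bin_coverage)),
        "a_te_fraction": ctx.bin_coverage,
    }).to_csv(paths["bin_coverage"], sep="\t", index=False)
    paths["species_matrix_profiles"] = out / "species_profiles.tsv"
    with open(paths["species_matrix_profiles"], "w") as fh:
        fh.write("species\tfamily\tcovered_bp\n")
        for sp in sorted(ctx.species_profiles):
            prof = ctx.species_profiles[sp]
            for fam in sorted(prof.per_family):
                fh.write(f"{sp}\t{fam}\t{prof.per_family[fam]}\n")
    paths["species_core_truth"] = out / "truth_species_core.tsv"
    with open(paths["species_core_truth"], "w") as fh:
        fh.write("family\n")
        for fam in ctx.species_core:
            fh.write(fam + "\n")

    cohort = simulate_insertion_cohort(config, ocrs=ctx.ocrs)
    paths["vcf"] = out / "cohort.vcf"
    tio.write_insertion_calls(
        cohort.calls, paths["vcf"], cohort.roster,
        contig_lengths={config.cohort.chrom: config.cohort.genome_length},
    )
    paths["reference"] = out / "reference.fa"
    tio.write_fasta({config.cohort.chrom: cohort.reference}, paths["reference"])
    paths["library"] = out / "library.fa"
    tio.write_fasta(cohort.library, paths["library"])
    paths["cohort_truth"] = out / "truth_cohort.tsv"
    cohort.truth.to_csv(paths["cohort_truth"], sep="\t")
    paths["lineages"] = out / "lineages.tsv"
    with open(paths["lineages"], "w") as fh:
        fh.write("sample\tlineage\n")
        for s in cohort.roster:
            fh.write(f"{s}\t{cohort.lineages[s]}\n")

    sim_reads = simulate_te_reads(config)
    paths["reads"] = out / "reads.fa"
    tio.write_fasta(dict(sim_reads.reads), paths["reads"])
    paths["reads_truth"] = out / "truth_reads.tsv"
    sim_reads.truth.to_csv(paths["reads_truth"], sep="\t")
    paths["reads_library"] = out / "reads_library.fa"
    tio.write_fasta(sim_reads.library, paths["reads_library"])
    return paths
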