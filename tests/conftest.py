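import numpy as np
import pytest

from tescope.models import GenomicInterval, RepeatHit, classify_family
from tescope.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=11)


def make_hit(chrom, start, end, family="hAT-Tip100", divergence_pct=None,
             hit_id=None, strand="+"):
    return RepeatHit(
        interval=GenomicInterval(chrom, start, end, strand),
        family=family,
        te_class=classify_family(family),
        divergence_pct=divergence_pct,
        hit_id=hit_id,
    )


def random_hits(rng, n_hits, genome_length, families=("famA", "famB", "famC")):
    """Random hit list for coverage-oracle comparisons (families default to
    unknown names, classified Unknown, still TE-like)."""
    hits = []
    for _ in range(n_hits):
        start = int(rng.integers(0, genome_length - 1))
        end = int(rng.integers(start + 1, min(start + 2000, genome_length) + 1))
        fam = families[int(rng.integers(0, len(families)))]
        hits.append(make_hit("chr1", start, end, family=fam))
    return hits


def bitmap_family_coverage(hits, genome_length):
    """Per-base boolean-mask oracle for per-family and union coverage."""
    masks = {}
    union = np.zeros(genome_length, dtype=bool)
    for h in hits:
        m = masks.setdefault(h.family, np.zeros(genome_length, dtype=bool))
        m[h.interval.start:h.interval.end] = True
        if h.te_class != "non-TE":
            union[h.interval.start:h.interval.end] = True
    return {f: int(m.sum()) for f, m in masks.items()}, int(union.sum())
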