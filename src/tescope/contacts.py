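"""Per-bin active-TE coverage vs chromatin-contact interaction range.

Contacts are binned cis records ``(chrom, bin_i, bin_j, intensity)`` at a
fixed bin size. The interaction range of a bin is the farthest separation
at which its observed contact intensity still exceeds theta times the
genome-wide mean intensity at that separation (the distance-decay
background). Bins are then split by active-TE coverage and the two range
distributions compared with the rank-sum test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .context import wilcoxon_rank_sum
from .landscape import merged_length
from .models import RepeatHit

DEFAULT_BIN_SIZE = 100_000
DEFAULT_THETA = 1.5
DEFAULT_QUANTILE = 0.25

_COLUMNS = ["chrom", "bin_i", "bin_j", "intensity"]


def load_contacts(path) -> pd.DataFrame:
    """Read contact triples (TSV: chrom, bin_i, bin_j, intensity) and
    symmetrize: indices canonicalized to bin_i <= bin_j, duplicates
    summed. Total intensity is conserved."""
    df = pd.read_csv(path, sep="\t", comment="#", names=_COLUMNS, dtype={
        "chrom": str, "bin_i": np.int64, "bin_j": np.int64, "intensity": float,
    }, skiprows=_header_rows(path))
    return symmetrize(df)


def _header_rows(path) -> int:
    with open(path) as fh:
        first = fh.readline()
    return 1 if first.startswith("chrom") else 0


def symmetrize(contacts: pd.DataFrame) -> pd.DataFrame:
    if (contacts["intensity"] < 0).any():
        raise ValueError("contact intensities must be non-negative")
    lo = contacts[["bin_i", "bin_j"]].min(axis=1)
    hi = contacts[["bin_i", "bin_j"]].max(axis=1)
    out = contacts.assign(bin_i=lo, bin_j=hi)
    out = (
        out.groupby(["chrom", "bin_i", "bin_j"], as_index=False)["intensity"]
        .sum()
    )
    return out


def write_contacts(contacts: pd.DataFrame, path) -> None:
    contacts.to_csv(path, sep="\t", index=False, columns=_COLUMNS)


def bin_te_coverage(
    n_bins: Dict[str, int],
    hits: Sequence[RepeatHit],
    active_set: Set[str],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> pd.DataFrame:
    """Per-bin fraction of bp covered by hits of active families.

    Within a bin, overlapping active-family hits count once (union).
    Returns a DataFrame with chrom, bin, a_te_fraction for every bin.
    """
    spans: Dict[str, list] = {}
    for h in hits:
        if h.family in active_set:
            spans.setdefault(h.interval.chrom, []).append(
                (h.interval.start, h.interval.end)
            )
    rows = []
    for chrom, nb in sorted(n_bins.items()):
        covered = np.zeros(nb, dtype=np.int64)
        merged = _merge(spans.get(chrom, []))
        for start, end in merged:
            first = start // bin_size
            last = min((end - 1) // bin_size, nb - 1)
            for b in range(first, last + 1):
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size)
                if hi > lo:
                    covered[b] += hi - lo
        for b in range(nb):
            rows.append((chrom, b, covered[b] / bin_size))
    return pd.DataFrame(rows, columns=["chrom", "bin", "a_te_fraction"])


def _merge(spans):
    if not spans:
        return []
    spans = sorted(spans)
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s > merged[-1][1]:
            merged.append([s, e])
        else:
            merged[-1][1] = max(merged[-1][1], e)
    return merged


def decay_background(
    contacts: pd.DataFrame, n_bins: Dict[str, int], max_sep: Optional[int] = None
) -> np.ndarray:
    """Mean cis intensity per bin separation over all possible pairs.

    The denominator at separation d counts every pair of bins d apart on
    each chromosome, so absent records count as zero intensity.
    """
    if max_sep is None:
        max_sep = int((contacts["bin_j"] - contacts["bin_i"]).max())
    sums = np.zeros(max_sep + 1)
    sep = (contacts["bin_j"] - contacts["bin_i"]).to_numpy()
    keep = sep <= max_sep
    np.add.at(sums, sep[keep], contacts["intensity"].to_numpy()[keep])
    denom = np.zeros(max_sep + 1)
    for nb in n_bins.values():
        d = np.arange(0, max_sep + 1)
        denom += np.maximum(nb - d, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, sums / denom, np.nan)


def _dense(contacts: pd.DataFrame, chrom: str, nb: int, max_sep: int) -> np.ndarray:
    """bins x separation matrix of observed intensity for one chromosome
    (mean of the left and right partner where both exist)."""
    sub = contacts[contacts["chrom"] == chrom]
    mat = np.zeros((nb, max_sep + 1))
    i = sub["bin_i"].to_numpy()
    j = sub["bin_j"].to_numpy()
    v = sub["intensity"].to_numpy()
    sep = j - i
    keep = sep <= max_sep
    i, j, v, sep = i[keep], j[keep], v[keep], sep[keep]
    np.add.at(mat, (i, sep), v)
    np.add.at(mat, (j, sep), v)
    # each bin saw intensity from up to two partners at separation d
    counts = np.zeros((nb, max_sep + 1))
    d = np.arange(max_sep + 1)[None, :]
    b = np.arange(nb)[:, None]
    counts += (b - d >= 0)        # left partner exists
    counts += (b + d <= nb - 1)   # right partner exists
    counts[:, 0] = 1
    mat[:, 0] /= 2.0              # (i, i) added twice above
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, mat / counts, np.nan)


def interaction_ranges(
    contacts: pd.DataFrame,
    n_bins: Dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    theta: float = DEFAULT_THETA,
    max_sep: Optional[int] = None,
    background: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Interaction range (bp) for every bin.

    Range = bin_size x max{d >= 1 : observed(bin, d) > theta x mean(d)},
    0 when no separation qualifies, NaN for bins with no cis contacts.
    """
    if max_sep is None:
        max_sep = int((contacts["bin_j"] - contacts["bin_i"]).max())
    if background is None:
        background = decay_background(contacts, n_bins, max_sep)
    rows = []
    for chrom, nb in sorted(n_bins.items()):
        dense = _dense(contacts, chrom, nb, max_sep)
        # a separation qualifies when the bin's observed intensity meets
        # theta x background and is nonzero (an empty separation with an
        # all-zero background must not qualify)
        exceeds = (dense[:, 1:] >= theta * background[None, 1:]) & (
            dense[:, 1:] > 0
        )
        any_contact = np.nansum(dense, axis=1) > 0
        for b in range(nb):
            if not any_contact[b]:
                rows.append((chrom, b, math.nan))
                continue
            qualifying = np.nonzero(exceeds[b])[0]
            d = int(qualifying[-1]) + 1 if len(qualifying) else 0
            rows.append((chrom, b, d * bin_size))
    return pd.DataFrame(rows, columns=["chrom", "bin", "interaction_range"])


def interaction_range(
    chrom: str,
    bin_index: int,
    contacts: pd.DataFrame,
    n_bins: Dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    theta: float = DEFAULT_THETA,
) -> float:
    """Interaction range of a single bin (NaN when the bin has no cis
    contacts)."""
    df = interaction_ranges(contacts, n_bins, bin_size=bin_size, theta=theta)
    row = df[(df["chrom"] == chrom) & (df["bin"] == bin_index)]
    if row.empty:
        raise KeyError(f"bin {chrom}:{bin_index} not found")
    return float(row["interaction_range"].iloc[0])


def bin_profiles(
    contacts: pd.DataFrame,
    hits: Sequence[RepeatHit],
    active_set: Set[str],
    n_bins: Dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    theta: float = DEFAULT_THETA,
    max_sep: Optional[int] = None,
) -> pd.DataFrame:
    """Join per-bin A-TE coverage with interaction ranges."""
    cov = bin_te_coverage(n_bins, hits, active_set, bin_size=bin_size)
    rng = interaction_ranges(
        contacts, n_bins, bin_size=bin_size, theta=theta, max_sep=max_sep
    )
    return cov.merge(rng, on=["chrom", "bin"])


def compare_ranges(
    profiles: pd.DataFrame, quantile: float = DEFAULT_QUANTILE
) -> Tuple[float, float, float]:
    """Median interaction range of high vs low A-TE-coverage bins and the
    two-sided rank-sum p.

    High = bins with a_te_fraction above the (1 - quantile) quantile,
    low = below the quantile; bins without a defined range are dropped.
    """
    df = profiles.dropna(subset=["interaction_range"])
    hi_cut = df["a_te_fraction"].quantile(1 - quantile)
    lo_cut = df["a_te_fraction"].quantile(quantile)
    high = df.loc[df["a_te_fraction"] > hi_cut, "interaction_range"].to_numpy()
    low = df.loc[df["a_te_fraction"] < lo_cut, "interaction_range"].to_numpy()
    if len(high) < 2 or len(low) < 2:
        raise ValueError("need at least two bins per group")
    p = wilcoxon_rank_sum(high, low)
    return float(np.median(high)), float(np.median(low)), p
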