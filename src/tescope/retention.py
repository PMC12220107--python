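"""Cross-species TE-family retention matrices, clustering, and core sets.

Each species row gives the share of that species' total TE coverage
attributed to each family. Hierarchical clustering of the family rows
(average linkage, Euclidean distance on the raw share vectors by default)
exposes blocks of families retained across the panel; the "core"
set is the cluster with the highest mean share whose members hold a
minimum share in a sufficient fraction of species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .landscape import CoverageProfile
from .models import TE_LIKE_CLASSES, classify_family

log = logging.getLogger(__name__)


def build_matrix(
    profiles: Dict[str, CoverageProfile],
    classification_map: Optional[dict] = None,
) -> pd.DataFrame:
    """species x family matrix of per-family shares of total TE coverage.

    Families classifying as non-TE are excluded before normalization;
    species with zero TE coverage are dropped with a warning. Rows sum to
    1 over the family universe (absent family = 0).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two species")
    rows = {}
    for species, profile in profiles.items():
        fam_cov = {
            fam: bp
            for fam, bp in profile.per_family.items()
            if classify_family(fam, None, classification_map) in TE_LIKE_CLASSES
        }
        total = sum(fam_cov.values())
        if total == 0:
            log.warning("species %s has zero TE coverage, dropped", species)
            continue
        rows[species] = {fam: bp / total for fam, bp in fam_cov.items()}
    matrix = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    return matrix.sort_index(axis=0).sort_index(axis=1)


def detect_families(
    profiles: Dict[str, CoverageProfile], min_bp: int = 1000
) -> Dict[str, int]:
    """Number of families with coverage >= min_bp (inclusive) per species."""
    if min_bp < 0:
        raise ValueError("min_bp must be >= 0")
    return {
        sp: sum(1 for bp in prof.per_family.values() if bp >= min_bp)
        for sp, prof in profiles.items()
    }


@dataclass
class CoreResult:
    linkage: np.ndarray
    flat_clusters: pd.Series        # family -> cluster id
    core: Tuple[str, ...]           # core family set, sorted
    overlap_count: Optional[int] = None
    overlap_percent: Optional[float] = None


def overlap_percent(core: Sequence[str], supplied: Set[str]) -> Tuple[int, float]:
    """|core ∩ supplied| and its percentage of |core|."""
    if not core:
        raise ValueError("core set is empty")
    k = len(set(core) & set(supplied))
    return k, 100.0 * k / len(core)


def cluster_and_core(
    matrix: pd.DataFrame,
    n_clusters: Optional[int] = None,
    linkage_method: str = "average",
    metric: str = "euclidean",
    scale_rows: bool = False,
    min_share: float = 0.01,
    prevalence_threshold: float = 0.9,
    supplied: Optional[Set[str]] = None,
) -> CoreResult:
    """Cluster family rows and extract the core family set.

    Families (matrix columns) are clustered on their raw cross-species
    share vectors, so both the retention pattern and the share level
    drive the grouping (``scale_rows`` standardizes each family first,
    which isolates the pattern but lets ubiquitous low-share families
    shadow the high-share core). Flat clusters are
    cut to ``n_clusters`` (default: sqrt of the family count, at least 2).
    The core set is the cluster with the highest mean share whose members
    each hold at least ``min_share`` of TE coverage in at least
    ``prevalence_threshold`` of species. A degenerate all-equal matrix
    yields a single cluster with every family as core (warning).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two families")
    fam_matrix = matrix.T  # families x species
    values = fam_matrix.to_numpy(dtype=float)
    if np.allclose(values, values.flat[0]):
        log.warning("degenerate all-equal matrix: single cluster, core = all")
        families = tuple(sorted(matrix.columns))
        flat = pd.Series(1, index=fam_matrix.index)
        result = CoreResult(np.empty((0, 4)), flat, families)
        if supplied is not None:
            result.overlap_count, result.overlap_percent = overlap_percent(
                families, supplied
            )
        return result
    clustered = values
    if scale_rows:
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        clustered = (values - mu) / sd
    link = hierarchy.linkage(pdist(clustered, metric=metric), method=linkage_method)
    if n_clusters is None:
        n_clusters = max(2, int(round(np.sqrt(matrix.shape[1]))))
    flat = pd.Series(
        hierarchy.fcluster(link, t=n_clusters, criterion="maxclust"),
        index=fam_matrix.index,
    )
    mean_share = matrix.mean(axis=0)
    best_cluster = (
        mean_share.groupby(flat).mean().sort_values(ascending=False).index[0]
    )
    members = flat.index[flat == best_cluster]
    prevalence = (matrix[members] >= min_share).mean(axis=0)
    core = tuple(sorted(m for m in members if prevalence[m] >= prevalence_threshold))
    result = CoreResult(link, flat, core)
    if supplied is not None and core:
        result.overlap_count, result.overlap_percent = overlap_percent(core, supplied)
    return result


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="species", float_format="%.6g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="species")
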