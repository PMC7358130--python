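"""RNA cluster identification (DBSCAN) and per-embryo clustering metrics.

Decomposed molecule coordinates are grouped with DBSCAN in 3D µm space
(anisotropy is already absorbed into the physical coordinates).  Four
per-embryo metrics summarize clustering: total RNA count, number of
clusters, fraction of RNAs inside clusters, and mean molecules per
cluster.  Per-stage aggregation produces the mean ± s.d. tables used for
cross-transcript comparisons.

DBSCAN parameters are not derivable from first principles; the defaults
(eps = 0.75 µm, min_pts = 2) treat any >= 2 resolvable molecules within a
granule-scale radius as a cluster, and both values are echoed into every
output so results are self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .image_model import MoleculeSet

__all__ = [
    "DEFAULT_EPS",
    "DEFAULT_MIN_PTS",
    "DEFAULT_STAGE_BINS",
    "ClusterInfo",
    "ClusterSet",
    "EmbryoClusterStats",
    "dbscan_cluster",
    "embryo_stats",
    "stage_aggregate",
]

DEFAULT_EPS = 0.75  # µm
DEFAULT_MIN_PTS = 2

#: stage groupings by nuclei count: 1–2, 4, 8, 16–24, 26–48, >48 cells
DEFAULT_STAGE_BINS: tuple[tuple[int, int], ...] = (
    (1, 2),
    (3, 4),
    (5, 8),
    (9, 24),
    (25, 48),
    (49, 10**6),
)


@dataclass
class ClusterInfo:
    members: np.ndarray  # molecule indices
    centroid: np.ndarray  # (z, y, x) µm
    molecule_count: int


@dataclass
class ClusterSet:
    """DBSCAN labels over a MoleculeSet plus per-cluster summaries.

    ``labels`` follows sklearn semantics: -1 is noise (an unclustered
    individual molecule); cluster ids are 0..n_clusters-1.
    """

    labels: np.ndarray
    clusters: list[ClusterInfo]
    eps: float
    min_pts: int
    positions: np.ndarray  # (N, 3) µm, the clustered molecules

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def member_positions(self, cluster_id: int) -> np.ndarray:
        return self.positions[self.clusters[cluster_id].members]


@dataclass
class EmbryoClusterStats:
    """The four per-embryo clustering metrics plus metadata."""

    total_rnas: int
    n_clusters: int
    fraction_clustered: float
    mean_molecules_per_cluster: Optional[float]
    stage: int = 1
    condition: str = ""
    transcript: str = ""


def dbscan_cluster(
    molecules: MoleculeSet | np.ndarray,
    eps: float = DEFAULT_EPS,
    min_pts: int = DEFAULT_MIN_PTS,
) -> ClusterSet:
    """Cluster molecule positions with DBSCAN (Euclidean, µm).

    ``min_pts`` counts the molecule itself, so a pair of molecules within
    ``eps`` of each other forms a cluster at the default ``min_pts = 2``.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_pts < 2:
        raise ValueError("min_pts must be >= 2")
    positions = molecules.positions if isinstance(molecules, MoleculeSet) else np.asarray(molecules, dtype=float)
    positions = positions.reshape(-1, 3)
    if len(positions) == 0:
        return ClusterSet(np.empty(0, dtype=int), [], eps, min_pts, positions)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(positions)
    clusters = []
    for cid in range(labels.max() + 1 if labels.size else 0):
        members = np.flatnonzero(labels == cid)
        clusters.append(
            ClusterInfo(
                members=members,
                centroid=positions[members].mean(axis=0),
                molecule_count=len(members),
            )
        )
    return ClusterSet(labels, clusters, eps, min_pts, positions)


def embryo_stats(
    clusters: ClusterSet,
    stage: int = 1,
    condition: str = "",
    transcript: str = "",
) -> EmbryoClusterStats:
    """Compute the four per-embryo metrics from a ClusterSet.

    ``fraction_clustered`` = (Σ cluster sizes) / total molecules.  The mean
    cluster size is undefined (None) when no cluster was found — it is
    reported as missing, never as 0.
    """
    total = len(clusters.labels)
    sizes = [c.molecule_count for c in clusters.clusters]
    clustered = int(sum(sizes))
    return EmbryoClusterStats(
        total_rnas=total,
        n_clusters=len(sizes),
        fraction_clustered=clustered / total if total else 0.0,
        mean_molecules_per_cluster=float(np.mean(sizes)) if sizes else None,
        stage=stage,
        condition=condition,
        transcript=transcript,
    )


METRICS = ("total_rnas", "n_clusters", "fraction_clustered", "mean_molecules_per_cluster")


def _stage_label(stage: int, bins: Sequence[tuple[int, int]]) -> Optional[str]:
    for lo, hi in bins:
        if lo <= stage <= hi:
            return f"{lo}-{hi}" if hi < 10**6 else f">{lo - 1}"
    return None


def stage_aggregate(
    stats: Sequence[EmbryoClusterStats],
    stage_bins: Sequence[tuple[int, int]] = DEFAULT_STAGE_BINS,
) -> pd.DataFrame:
    """Mean ± s.d. of each metric per transcript × stage bin.

    Returns a tidy DataFrame with columns ``transcript``, ``stage_bin``,
    ``metric``, ``mean``, ``sd``, ``n_embryos``.  Population s.d. (ddof=0)
    is used, so a single-embryo group reports s.d. 0.  Embryos whose stage
    falls in no bin are dropped with a warning row omitted.
    """
    rows = []
    for s in stats:
        label = _stage_label(s.stage, stage_bins)
        if label is None:
            continue
        for m in METRICS:
            val = getattr(s, m)
            if val is None:
                continue
            rows.append({"transcript": s.transcript, "stage_bin": label, "metric": m, "value": float(val)})
    if not rows:
        return pd.DataFrame(columns=["transcript", "stage_bin", "metric", "mean", "sd", "n_embryos"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["transcript", "stage_bin", "metric"], sort=False)["value"]
        .agg(mean="mean", sd=lambda v: float(np.std(v, ddof=0)), n_embryos="count")
        .reset_index()
    )
    return out
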