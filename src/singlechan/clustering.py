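"""Frequency–energy histograms of IMF populations and K-means clusters.

The IMF population of one condition is binned on a fixed log–log grid of
(frequency, energy).  Because both axes span several decades, clustering is
performed in (log₁₀ f, log₁₀ E) space: K-means (six clusters by default,
matching the number of visually separable groups in these data) runs on the
non-empty histogram cell centers with the cell counts as weights.  Each
cluster is summarised by a count-weighted centroid (reported back in linear
units), its occupancy — the fraction of all IMFs falling in the cluster —
and the Shannon entropy (bits) of the within-cluster count distribution,
which measures how dispersed the cluster's IMFs are over its cells.

Cluster labels are canonicalized by sorting centroids by (frequency, then
energy), so cluster 0 is the low-frequency low-energy group and cluster 1
the low-frequency high-energy group, regardless of K-means' arbitrary
labelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .containers import Condition
from .emd import IMFFeature
from .entropy import shannon_entropy

__all__ = [
    "HistogramGrid",
    "FeatureHistogram2D",
    "ClusterSummary",
    "feature_histogram_2d",
    "cluster_features",
    "cluster_summaries",
    "cluster_condition",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HistogramGrid:
    """Shared log–log binning grid for (frequency Hz, energy) features."""

    freq_min: float = 1.0
    freq_max: float = 5_000.0
    n_freq: int = 60
    energy_min: float = 1e-8
    energy_max: float = 1.0
    n_energy: int = 60

    def freq_edges(self) -> np.ndarray:
        return np.logspace(np.log10(self.freq_min), np.log10(self.freq_max),
                           self.n_freq + 1)

    def energy_edges(self) -> np.ndarray:
        return np.logspace(np.log10(self.energy_min), np.log10(self.energy_max),
                           self.n_energy + 1)


@dataclass
class FeatureHistogram2D:
    freq_edges: np.ndarray
    energy_edges: np.ndarray
    counts: np.ndarray        # shape (n_freq, n_energy)
    total: int
    condition: Condition = field(default_factory=Condition)

    @property
    def log_freq_centers(self) -> np.ndarray:
        e = np.log10(self.freq_edges)
        return 0.5 * (e[:-1] + e[1:])

    @property
    def log_energy_centers(self) -> np.ndarray:
        e = np.log10(self.energy_edges)
        return 0.5 * (e[:-1] + e[1:])


@dataclass
class ClusterSummary:
    cluster: int
    centroid_frequency: float | None   # Hz (geometric/count-weighted mean)
    centroid_energy: float | None
    occupancy: float
    entropy_bits: float
    condition: Condition = field(default_factory=Condition)

    @property
    def defined(self) -> bool:
        return self.centroid_frequency is not None


def feature_histogram_2d(
    features: list[IMFFeature],
    grid: HistogramGrid | None = None,
) -> FeatureHistogram2D:
    """Bin an IMF feature population on the shared log–log grid.

    Non-positive or below-range values cannot be log-binned; they are mapped
    to the lowest bin of the offending axis and logged.  Values above the
    top edge are mapped to the highest bin.
    """
    if not features:
        raise ValueError("empty feature list")
    if grid is None:
        grid = HistogramGrid()
    fe, ee = grid.freq_edges(), grid.energy_edges()
    f = np.array([ft.frequency for ft in features], dtype=float)
    E = np.array([ft.energy for ft in features], dtype=float)
    n_low = int(np.count_nonzero((f < fe[0]) | (E < ee[0])))
    if n_low:
        log.info("feature_histogram_2d: %d features at/below the lowest bin "
                 "edge mapped to the lowest bin", n_low)
    f = np.clip(f, fe[0], fe[-1])
    E = np.clip(E, ee[0], ee[-1])
    counts, _, _ = np.histogram2d(f, E, bins=[fe, ee])
    return FeatureHistogram2D(fe, ee, counts.astype(int), total=len(features),
                              condition=features[0].condition)


def cluster_features(
    hist: FeatureHistogram2D, k: int = 6, seed: int = 0, n_restarts: int = 20
) -> np.ndarray:
    """Weighted K-means over non-empty histogram cells.

    Returns an integer array shaped like ``hist.counts`` with the cluster
    id of each cell (−1 for empty cells).  Clustering runs on cell centers
    in (log₁₀ f, log₁₀ E) with cell counts as weights; k-means++
    initialisation, best of ``n_restarts`` by inertia, deterministic for a
    fixed seed.  Labels are canonicalized by centroid (frequency, energy).
    """
    occ_i, occ_j = np.nonzero(hist.counts)
    if occ_i.size < k:
        raise ValueError(f"only {occ_i.size} non-empty cells for k={k}")
    pts = np.column_stack([hist.log_freq_centers[occ_i],
                           hist.log_energy_centers[occ_j]])
    w = hist.counts[occ_i, occ_j].astype(float)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(pts, sample_weight=w)
    # canonical order: centroid frequency band first (log10 f rounded to a
    # tenth of a decade, so same-band clusters order by energy), then energy
    band = np.round(km.cluster_centers_[:, 0], 1)
    order = np.lexsort((km.cluster_centers_[:, 1], band))
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    assignment = np.full(hist.counts.shape, -1, dtype=int)
    assignment[occ_i, occ_j] = relabel[raw]
    return assignment


def cluster_summaries(
    hist: FeatureHistogram2D, assignment: np.ndarray
) -> list[ClusterSummary]:
    """Centroid, occupancy and entropy of each cluster.

    Centroids are count-weighted means of member cell centers in log space,
    reported in linear units (Hz, energy).  Occupancy is the member count
    fraction of all IMFs; entropy is the Shannon entropy (bits) of the
    normalized within-cluster count distribution over its member cells.
    An empty cluster gets occupancy 0 and an undefined (None) centroid.
    """
    if assignment.shape != hist.counts.shape:
        raise ValueError("assignment grid does not match histogram grid")
    k = int(assignment.max()) + 1
    total = hist.counts.sum()
    lf = hist.log_freq_centers
    le = hist.log_energy_centers
    out: list[ClusterSummary] = []
    for c in range(k):
        mask = assignment == c
        counts = hist.counts[mask].astype(float)
        n = counts.sum()
        if n == 0:
            out.append(ClusterSummary(c, None, None, 0.0, 0.0,
                                      condition=hist.condition))
            continue
        ii, jj = np.nonzero(mask)
        cf = 10 ** (np.sum(lf[ii] * counts) / n)
        ce = 10 ** (np.sum(le[jj] * counts) / n)
        ent = shannon_entropy(counts / n)
        out.append(ClusterSummary(c, float(cf), float(ce), float(n / total),
                                  float(ent), condition=hist.condition))
    return out


def cluster_condition(
    features: list[IMFFeature],
    grid: HistogramGrid | None = None,
    k: int = 6,
    seed: int = 0,
) -> tuple[FeatureHistogram2D, np.ndarray, list[ClusterSummary]]:
    """Histogram → weighted K-means → summaries, in one call."""
    hist = feature_histogram_2d(features, grid)
    assignment = cluster_features(hist, k=k, seed=seed)
    return hist, assignment, cluster_summaries(hist, assignment)
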