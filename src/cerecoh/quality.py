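"""Spike-cluster quality metrics and putative-pyramidal classification.

Isolation distance and L-ratio are Mahalanobis-based separation measures
computed from any supplied spike-feature matrix (default convention: 8
features, two per tetrode channel).  A unit passes the quality gate when
isolation distance > 15.0 and L-ratio < 0.35 (strict inequalities).

Putative pyramidal cells are identified by broad spikes (trough-to-peak
width above threshold) and low mean firing rate, following standard rodent
cortical conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .config import AnalysisConfig

__all__ = ["FeatureMatrix", "ClusterQuality", "isolation_distance", "l_ratio",
           "cluster_quality", "classify_pyramidal", "PyramidalCall"]


@dataclass
class FeatureMatrix:
    """Per-spike waveform features plus cluster assignments.

    ``labels`` uses -1 for the unsorted noise cloud and small nonnegative
    integers (or strings) for clusters.
    """

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or self.features.shape[1] < 2:
            raise ValueError("feature matrix must be 2-D with >= 2 columns")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature matrix contains missing values")
        if self.labels.shape[0] != self.features.shape[0]:
            raise ValueError("labels must match feature rows")

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    def split(self, unit_id) -> tuple[np.ndarray, np.ndarray]:
        m = self.labels == unit_id
        if not m.any():
            raise KeyError(f"no spikes labelled {unit_id!r}")
        return self.features[m], self.features[~m]


@dataclass
class ClusterQuality:
    unit_id: str
    isolation_distance: float | None   # None when undefined (n_noise < n_cluster)
    l_ratio: float
    n_spikes: int
    passes: bool


def _mahalanobis_sq(cluster: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance of each non-cluster spike from the
    cluster's mean/covariance; singular covariance is ridge-regularized."""
    mu = cluster.mean(axis=0)
    cov = np.cov(cluster, rowvar=False)
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular cluster covariance; regularizing")
        inv = np.linalg.inv(cov + 1e-6 * np.trace(cov) / cov.shape[0]
                            * np.eye(cov.shape[0]))
    d = others - mu
    return np.einsum("ij,jk,ik->i", d, inv, d)


def isolation_distance(features: FeatureMatrix, unit_id) -> float | None:
    """Squared Mahalanobis distance of the n-th closest non-cluster spike,
    n being the cluster size.  Undefined (None) when fewer non-cluster
    spikes than cluster spikes exist."""
    cluster, noise = features.split(unit_id)
    n = cluster.shape[0]
    if noise.shape[0] < n:
        return None
    d2 = np.sort(_mahalanobis_sq(cluster, noise))
    return float(d2[n - 1])


def l_ratio(features: FeatureMatrix, unit_id) -> float:
    """Sum of non-cluster chi-square tail probabilities per cluster spike:
    Σ (1 − CDF_χ²(d)(D²)) / n_cluster; 0 for an empty noise set."""
    cluster, noise = features.split(unit_id)
    if noise.shape[0] == 0:
        return 0.0
    d2 = _mahalanobis_sq(cluster, noise)
    tail = spstats.chi2.sf(d2, df=features.dim)
    return float(tail.sum() / cluster.shape[0])


def cluster_quality(features: FeatureMatrix, unit_id,
                    config: AnalysisConfig | None = None) -> ClusterQuality:
    """Both metrics plus the inclusion gate (iso > 15 and L-ratio < 0.35)."""
    cfg = config or AnalysisConfig()
    iso = isolation_distance(features, unit_id)
    lr = l_ratio(features, unit_id)
    n = int(np.sum(features.labels == unit_id))
    passes = iso is not None and iso > cfg.iso_dist_min and lr < cfg.l_ratio_max
    return ClusterQuality(str(unit_id), iso, lr, n, passes)


@dataclass
class PyramidalCall:
    is_pyramidal: bool
    trough_to_peak_ms: float
    mean_rate_hz: float


def classify_pyramidal(mean_waveform: np.ndarray, mean_rate: float,
                       fs: float = 32000.0,
                       config: AnalysisConfig | None = None) -> PyramidalCall:
    """Putative pyramidal iff trough-to-peak width > width_min AND mean
    rate < rate_max (strict inequalities; threshold-exact values are
    excluded)."""
    cfg = config or AnalysisConfig()
    w = np.asarray(mean_waveform, float)
    if w.size < 8:
        raise ValueError("waveform too short to measure width")
    i_trough = int(np.argmin(w))
    after = w[i_trough:]
    if after.size < 2:
        raise ValueError("waveform ends at the trough; width unmeasurable")
    i_peak = i_trough + int(np.argmax(after))
    width_s = (i_peak - i_trough) / fs
    is_pyr = (width_s > cfg.pyramidal_width_min) and \
        (mean_rate < cfg.pyramidal_rate_max)
    return PyramidalCall(bool(is_pyr), width_s * 1e3, float(mean_rate))
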