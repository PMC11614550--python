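"""Unit characterisation and spike-sorting cluster-quality indices.

Waveform trough-to-peak duration (with parabolic sub-sample interpolation)
and firing rate feed a putative pyramidal/interneuron split; refractory
screening enforces the >= 1 ms single-unit criterion; and the sorting-stage
separation indices (pseudo-F, J3 and Davies-Bouldin) quantify how well
labelled waveform clusters are isolated in PCA feature space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PYRAMIDAL_TTP_MS = 0.30   # strict: pyramidal requires ttp > threshold
PYRAMIDAL_RATE_CEILING_HZ = 20.0
MIN_ISI_MS = 1.0


@dataclass
class UnitFeatures:
    unit_id: str
    trough_to_peak_ms: float
    firing_rate_hz: float
    putative_class: str = ""
    refractory_violation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.trough_to_peak_ms <= 0:
            raise ValueError("trough_to_peak_ms must be positive")
        if self.firing_rate_hz < 0:
            raise ValueError("firing_rate_hz must be >= 0")


@dataclass
class ClusterQuality:
    """Separation indices over a labelled feature matrix."""

    f_stat: float
    j3: float
    davies_bouldin: float
    n_points: int
    n_clusters: int

    def __post_init__(self) -> None:
        if self.j3 <= 0 or self.davies_bouldin < 0 or self.f_stat < 0:
            raise ValueError("invalid cluster-quality values")


class InvalidWaveformError(ValueError):
    pass


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample extremum location via a 3-point parabola around index i."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return i + 0.5 * (y[i - 1] - y[i + 1]) / denom


def trough_to_peak(waveform: np.ndarray, fs: float) -> float:
    """Milliseconds from the global trough to the subsequent local maximum,
    both refined to sub-sample precision."""
    w = np.asarray(waveform, dtype=float)
    if w.size < 3 or w.min() >= 0:
        raise InvalidWaveformError("template must contain a negative trough")
    i_trough = int(np.argmin(w))
    after = w[i_trough:]
    if after.size < 2:
        raise InvalidWaveformError("no samples after the trough")
    i_peak_rel = int(np.argmax(after))
    # a genuine after-wave must be a positive deflection, not baseline return
    if i_peak_rel == 0 or after[i_peak_rel] <= 0.01 * abs(w[i_trough]):
        raise InvalidWaveformError("no post-trough positive peak")
    t_trough = _parabolic_refine(w, i_trough)
    t_peak = _parabolic_refine(w, i_trough + i_peak_rel)
    return float((t_peak - t_trough) / fs * 1000.0)


def refractory_check(
    spike_times_s: np.ndarray, min_isi_ms: float = MIN_ISI_MS
) -> tuple[float, bool]:
    """Fraction of inter-spike intervals below the refractory floor, and a
    pass flag (a clean single unit has zero violations)."""
    t = np.asarray(spike_times_s, dtype=float)
    if t.size < 2:
        return 0.0, True
    isis_ms = np.diff(t) * 1000.0
    frac = float(np.mean(isis_ms < min_isi_ms))
    return frac, frac == 0.0


def classify_unit(
    features: UnitFeatures,
    ttp_threshold_ms: float = PYRAMIDAL_TTP_MS,
    rate_ceiling_hz: float = PYRAMIDAL_RATE_CEILING_HZ,
) -> str:
    """Putative class: broad, slow-firing units are pyramidal; everything
    else interneuron.  Thresholds are configuration, not measured facts."""
    if (
        features.trough_to_peak_ms > ttp_threshold_ms
        and features.firing_rate_hz < rate_ceiling_hz
    ):
        return "pyramidal"
    return "interneuron"


def pca_features(snippets: np.ndarray, n_components: int = 3) -> np.ndarray:
    """Project waveform snippets onto the top principal axes of their
    covariance (components ordered by explained variance; the largest
    loading of each axis is made positive)."""
    x = np.asarray(snippets, dtype=float)
    if x.ndim != 2 or x.shape[0] < n_components:
        raise ValueError(f"need at least {n_components} snippets")
    centred = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if rank < n_components:
        import warnings

        warnings.warn(
            f"only {rank} non-degenerate components; padding with zeros",
            stacklevel=2,
        )
    comps = np.zeros((x.shape[0], n_components))
    for k in range(min(n_components, rank)):
        axis = vt[k]
        if axis[np.argmax(np.abs(axis))] < 0:
            axis = -axis
        comps[:, k] = centred @ axis
    return comps


def cluster_separation(features: np.ndarray, labels: np.ndarray) -> ClusterQuality:
    """Pseudo-F, J3 and Davies-Bouldin over labelled feature clusters.

    J1 = mean squared distance of points to their own centroid;
    J2 = size-weighted mean squared distance of centroids to the grand
    mean; J3 = J2/J1; F = (J2/(k-1)) / (J1/(N-k)).  DB uses the mean
    Euclidean distance to the centroid as the cluster scatter.
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 clusters")
    n = x.shape[0]
    k = uniq.size
    grand = x.mean(axis=0)
    centroids = {}
    within_ss = 0.0
    between_ss = 0.0
    sigmas = {}
    for lab in uniq:
        pts = x[labels == lab]
        if pts.shape[0] < 2:
            raise ValueError(f"cluster {lab!r} has fewer than 2 points")
        c = pts.mean(axis=0)
        centroids[lab] = c
        within_ss += float(((pts - c) ** 2).sum())
        between_ss += pts.shape[0] * float(((c - grand) ** 2).sum())
        sigmas[lab] = float(np.linalg.norm(pts - c, axis=1).mean())
    j1 = within_ss / n
    j2 = between_ss / n
    if j1 == 0:
        raise ValueError("zero within-cluster scatter; J3 undefined")
    j3 = j2 / j1
    f_stat = (between_ss / (k - 1)) / (within_ss / (n - k))
    db_terms = []
    for li in uniq:
        worst = 0.0
        for lj in uniq:
            if li == lj:
                continue
            d = float(np.linalg.norm(centroids[li] - centroids[lj]))
            if d == 0:
                raise ValueError(f"clusters {li!r} and {lj!r} share a centroid; DB undefined")
            worst = max(worst, (sigmas[li] + sigmas[lj]) / d)
        db_terms.append(worst)
    return ClusterQuality(
        f_stat=f_stat,
        j3=j3,
        davies_bouldin=float(np.mean(db_terms)),
        n_points=n,
        n_clusters=k,
    )
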