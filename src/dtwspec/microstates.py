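"""EEG microstate analysis: GFP, peak picking, topographic k-means, back-fitting.

Microstates are quasi-stable scalp topographies.  The pipeline is the
standard one: compute global field power (GFP, the spatial standard deviation
of potentials across channels at each sample), pick its strict local maxima
(where topographic signal-to-noise is highest), cluster the maps at those
peaks with a polarity-invariant k-means (distance 1 - |spatial correlation|),
then back-fit: every sample is labeled with the centroid map of highest
absolute spatial correlation.

The two trial-wise scalars are the length (in samples) of the label run
containing the trial marker, and the mean GFP over that run.

Maps are average-referenced (zero mean across channels) and unit-normalized
before any correlation, matching an average-reference recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EEGRecording, TrialTable

__all__ = [
    "MicrostateConfig",
    "MicrostateModel",
    "global_field_power",
    "detect_gfp_peaks",
    "cluster_maps",
    "backfit",
    "pretrial_measures",
    "fit_microstates",
]


@dataclass
class MicrostateConfig:
    k: int = 12
    restarts: int = 10
    max_iter: int = 100
    seed: int = 0
    polarity_invariant: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class MicrostateModel:
    maps: np.ndarray  # k x channels, unit-norm average-referenced rows
    labels: np.ndarray  # per-sample int in [0, k)
    gfp: np.ndarray  # per-sample nonnegative


def global_field_power(eeg: EEGRecording) -> np.ndarray:
    """Population SD across channels at each sample."""
    if eeg.n_channels < 2:
        raise ValueError("GFP needs >= 2 channels")
    return eeg.data.std(axis=0, ddof=0)


def detect_gfp_peaks(gfp: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima, ascending."""
    g = np.asarray(gfp, dtype=float)
    if g.size < 3:
        raise ValueError("series too short for peak detection")
    interior = np.arange(1, g.size - 1)
    mask = (g[interior] > g[interior - 1]) & (g[interior] > g[interior + 1])
    return interior[mask]


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Average-reference each row then scale to unit norm."""
    m = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return m / norms


def _similarity(maps_a: np.ndarray, maps_b: np.ndarray, polarity_invariant: bool) -> np.ndarray:
    """Spatial correlation matrix between unit-norm average-referenced maps."""
    s = _normalize_maps(maps_a) @ _normalize_maps(maps_b).T
    return np.abs(s) if polarity_invariant else s


def cluster_maps(peak_maps: np.ndarray, cfg: MicrostateConfig) -> np.ndarray:
    """Seeded polarity-invariant k-means over topographic maps.

    Distance is ``1 - |spatial correlation|``; the centroid of a cluster is
    the polarity-aligned mean of its members, re-normalized.  The best of
    ``cfg.restarts`` runs by total within-cluster dissimilarity is returned;
    an emptied cluster is reseeded from the point farthest from its centroid.
    """
    X = _normalize_maps(np.asarray(peak_maps, dtype=float))
    n, _ = X.shape
    if n < cfg.k:
        raise ValueError(f"need at least k={cfg.k} peak maps, got {n}")
    rng = np.random.default_rng(cfg.seed)
    best_obj, best_centroids = np.inf, None
    for _ in range(cfg.restarts):
        centroids = X[rng.choice(n, size=cfg.k, replace=False)].copy()
        labels = np.zeros(n, dtype=int)
        for _ in range(cfg.max_iter):
            sim = _similarity(X, centroids, cfg.polarity_invariant)
            new_labels = sim.argmax(axis=1)
            new_centroids = centroids.copy()
            for j in range(cfg.k):
                members = X[new_labels == j]
                if len(members) == 0:
                    # reseed from the globally worst-fit map
                    worst = sim.max(axis=1).argmin()
                    new_centroids[j] = X[worst]
                    continue
                if cfg.polarity_invariant:
                    signs = np.sign(members @ centroids[j])
                    signs[signs == 0] = 1.0
                    members = members * signs[:, None]
                new_centroids[j] = members.mean(axis=0)
            new_centroids = _normalize_maps(new_centroids)
            if np.array_equal(new_labels, labels) and np.allclose(new_centroids, centroids):
                centroids = new_centroids
                break
            labels, centroids = new_labels, new_centroids
        sim = _similarity(X, centroids, cfg.polarity_invariant)
        obj = float(np.sum(1.0 - sim.max(axis=1)))
        if obj < best_obj:
            best_obj, best_centroids = obj, centroids
    return best_centroids


def cluster_objective(peak_maps: np.ndarray, centroids: np.ndarray, polarity_invariant: bool = True) -> float:
    """Total within-cluster dissimilarity of maps under given centroids."""
    sim = _similarity(np.asarray(peak_maps, float), centroids, polarity_invariant)
    return float(np.sum(1.0 - sim.max(axis=1)))


def backfit(eeg: EEGRecording, maps: np.ndarray, polarity_invariant: bool = True) -> np.ndarray:
    """Label every sample with the best-matching centroid map.

    Ties go to the lowest map index (argmax on the similarity matrix).
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[1] != eeg.n_channels:
        raise ValueError("centroid maps do not match recording channel count")
    sim = _similarity(eeg.data.T, maps, polarity_invariant)
    return sim.argmax(axis=1)


def _run_bounds(labels: np.ndarray, t: int) -> tuple[int, int]:
    """Half-open [start, stop) of the maximal constant-label run containing t."""
    lab = labels[t]
    start = t
    while start > 0 and labels[start - 1] == lab:
        start -= 1
    stop = t + 1
    while stop < len(labels) and labels[stop] == lab:
        stop += 1
    return start, stop


def pretrial_measures(
    labels: np.ndarray,
    gfp: np.ndarray,
    trials: TrialTable,
    gfp_power: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial (run length in samples, mean GFP over the run).

    The run is the maximal stretch of identical labels containing the trial
    sample — the microstate in force at trial time.  With ``gfp_power`` the
    mean of GFP**2 is returned instead of mean GFP.
    """
    labels = np.asarray(labels)
    gfp = np.asarray(gfp, dtype=float)
    if len(labels) != len(gfp):
        raise ValueError("labels and gfp must align")
    ms_length = np.zeros(len(trials), dtype=int)
    mean_gfp = np.zeros(len(trials))
    for idx, t in enumerate(trials.trial_sample):
        if t < 0 or t >= len(labels):
            raise IndexError(f"trial sample {t} outside label series")
        start, stop = _run_bounds(labels, int(t))
        ms_length[idx] = stop - start
        seg = gfp[start:stop]
        mean_gfp[idx] = float(np.mean(seg**2 if gfp_power else seg))
    return ms_length, mean_gfp


def fit_microstates(
    eeg: EEGRecording,
    cfg: MicrostateConfig,
    group_maps: np.ndarray | None = None,
) -> MicrostateModel:
    """Full single-recording pipeline: GFP -> peaks -> k-means -> backfit.

    When ``group_maps`` is given (centroids from pooled multi-subject
    clustering) the clustering step is skipped and only back-fitting runs.
    """
    gfp = global_field_power(eeg)
    if group_maps is None:
        peaks = detect_gfp_peaks(gfp)
        group_maps = cluster_maps(eeg.data[:, peaks].T, cfg)
    labels = backfit(eeg, group_maps, cfg.polarity_invariant)
    return MicrostateModel(maps=np.asarray(group_maps, float), labels=labels, gfp=gfp)
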