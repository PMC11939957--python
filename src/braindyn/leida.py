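"""Leading Eigenvector Dynamics Analysis (LEiDA).

Transforms regional BOLD series into instantaneous-phase leading
eigenvectors, clusters them into recurrent metastable brain states with
city-block k-means, and summarizes each subject by the occurrence
probability of every state (the probabilistic metastable substate space,
PMS).

Pipeline per subject: band-pass filter (0.01-0.08 Hz, zero-phase
Butterworth) -> Hilbert transform -> instantaneous phase -> per-volume
cosine phase-coherence matrix -> leading eigenvector.  Eigenvectors of all
subjects are concatenated and clustered; cluster labels are 1-based and
states are ordered by descending group-level occurrence probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.linalg import eigh
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr, norm

__all__ = [
    "bandpass_filter",
    "hilbert_phase",
    "phase_coherence_matrix",
    "leading_eigenvector",
    "eigenvector_series",
    "cluster_states",
    "assign_to_centroids",
    "occurrence_probabilities",
    "network_correlation",
    "LeadingEigenvectorSet",
    "BrainStateSet",
    "StatePMS",
]

DEFAULT_BAND = (0.01, 0.08)  # Hz


# ---------------------------------------------------------------------------
# signal stages
# ---------------------------------------------------------------------------

def _butter_band(tr: float, low: float, high: float):
    nyq = 0.5 / tr
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq:g})"
        )
    return signal.butter(2, [low / nyq, high / nyq], btype="bandpass")


def bandpass_filter(series: np.ndarray, tr: float, low: float = DEFAULT_BAND[0],
                    high: float = DEFAULT_BAND[1]) -> np.ndarray:
    """Zero-phase band-pass of a regions x volumes matrix.

    Second-order Butterworth applied forward-backward (``filtfilt``), the
    de-facto choice for phase analyses because it leaves phase undistorted.
    Per-region means are removed (the passband excludes DC anyway).
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    b, a = _butter_band(tr, low, high)
    padlen = 3 * max(len(a), len(b))
    if series.shape[1] <= padlen:
        raise ValueError(
            f"series length {series.shape[1]} too short for filter padding ({padlen})"
        )
    demeaned = series - series.mean(axis=1, keepdims=True)
    return signal.filtfilt(b, a, demeaned, axis=1)


def hilbert_phase(filtered: np.ndarray) -> np.ndarray:
    """Instantaneous phase (radians, in (-pi, pi]) of each region's analytic signal."""
    filtered = np.atleast_2d(np.asarray(filtered, dtype=float))
    if np.any(np.all(filtered == 0.0, axis=1)):
        bad = int(np.flatnonzero(np.all(filtered == 0.0, axis=1))[0])
        raise ValueError(f"region {bad} is identically zero; phase undefined")
    theta = np.angle(signal.hilbert(filtered, axis=1))
    theta[theta == -np.pi] = np.pi
    return theta


def phase_coherence_matrix(theta_t: np.ndarray) -> np.ndarray:
    """Cosine phase-coherence matrix for one volume: entry (i,j) = cos(theta_i - theta_j).

    1, -1 and 0 mark in-phase, anti-phase and orthogonal region pairs.
    """
    theta_t = np.asarray(theta_t, dtype=float)
    if not np.all(np.isfinite(theta_t)):
        raise ValueError("non-finite phases")
    return np.cos(theta_t[:, None] - theta_t[None, :])


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Sign convention: majority of components negative; on an exact tie the
    largest-magnitude component is made negative."""
    n_neg = int(np.sum(v < 0))
    n_pos = int(np.sum(v > 0))
    if n_neg < n_pos:
        return -v
    if n_neg == n_pos and v[int(np.argmax(np.abs(v)))] > 0:
        return -v
    return v


def leading_eigenvector(coherence: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the algebraically largest eigenvalue of a symmetric matrix.

    Near-degenerate top eigenvalues fall back on ``eigh``'s deterministic
    (lowest-index) basis; no error is raised.
    """
    coherence = np.asarray(coherence, dtype=float)
    n = coherence.shape[0]
    _, vec = eigh(coherence, subset_by_index=[n - 1, n - 1])
    v = vec[:, 0]
    v = v / np.linalg.norm(v)
    return _fix_sign(v)


def _leading_eigenvectors_rank2(theta: np.ndarray) -> np.ndarray:
    """Leading eigenvectors for every volume of a phase matrix, exploiting the
    rank-2 identity cos(ti - tj) = cos t cos t' + sin t sin t'.

    For each volume the coherence matrix is A A^T with A = [cos theta, sin theta]
    (N x 2), so its top eigenvector is A u with u the top eigenvector of the
    2 x 2 Gram matrix A^T A.  O(N) per volume instead of O(N^3).
    """
    c, s = np.cos(theta), np.sin(theta)          # regions x volumes
    g11 = np.einsum("it,it->t", c, c)
    g22 = np.einsum("it,it->t", s, s)
    g12 = np.einsum("it,it->t", c, s)
    # closed-form top eigenvector of [[g11,g12],[g12,g22]]
    tr_half = 0.5 * (g11 + g22)
    disc = np.sqrt(np.maximum(0.25 * (g11 - g22) ** 2 + g12**2, 0.0))
    lam = tr_half + disc
    # eigenvector (g12, lam - g11) unless g12 ~ 0 (already diagonal)
    u1 = np.where(np.abs(g12) > 1e-14, g12, np.where(g11 >= g22, 1.0, 0.0))
    u2 = np.where(np.abs(g12) > 1e-14, lam - g11, np.where(g11 >= g22, 0.0, 1.0))
    vecs = c * u1[None, :] + s * u2[None, :]     # regions x volumes
    vecs /= np.linalg.norm(vecs, axis=0, keepdims=True)
    out = vecs.T.copy()
    for i in range(out.shape[0]):
        out[i] = _fix_sign(out[i])
    return out


@dataclass
class LeadingEigenvectorSet:
    """Concatenated leading eigenvectors: (total volumes) x regions, with
    per-row subject and volume indices."""

    vectors: np.ndarray
    subject_index: np.ndarray
    time_index: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.vectors.shape[0]


def eigenvector_series(cohort, band=DEFAULT_BAND) -> LeadingEigenvectorSet:
    """Filter, phase-transform and eigen-decompose every subject's series.

    Yields one unit-norm row per volume per subject, in subject order then
    time order.  No edge trimming: the volume count is preserved (filter and
    Hilbert edge bias at the first/last volumes is accepted).
    """
    series_list = cohort.series if hasattr(cohort, "series") else list(cohort)
    if len(series_list) == 0:
        raise ValueError("cohort has no subjects")
    tr = cohort.tr if hasattr(cohort, "tr") else 2.0
    n_regions = np.atleast_2d(series_list[0]).shape[0]
    blocks, subj_idx, time_idx = [], [], []
    for s, series in enumerate(series_list):
        series = np.atleast_2d(series)
        if series.shape[0] != n_regions:
            raise ValueError(
                f"subject {s} has {series.shape[0]} regions, expected {n_regions}"
            )
        theta = hilbert_phase(bandpass_filter(series, tr, band[0], band[1]))
        blocks.append(_leading_eigenvectors_rank2(theta))
        subj_idx.append(np.full(series.shape[1], s))
        time_idx.append(np.arange(series.shape[1]))
    return LeadingEigenvectorSet(
        vectors=np.vstack(blocks),
        subject_index=np.concatenate(subj_idx),
        time_index=np.concatenate(time_idx),
    )


# ---------------------------------------------------------------------------
# city-block k-means
# ---------------------------------------------------------------------------

@dataclass
class BrainStateSet:
    """K metastable states: centroids (K x regions), 1-based per-row labels,
    and the total within-cluster city-block cost of the clustering."""

    centroids: np.ndarray
    k: int
    assignment: np.ndarray
    inertia: float


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = x.shape[0]
    centroids = np.empty((k, x.shape[1]))
    centroids[0] = x[rng.integers(n)]
    d = cdist(x, centroids[:1], metric="cityblock")[:, 0]
    for j in range(1, k):
        w = d**2
        tot = w.sum()
        probs = w / tot if tot > 0 else np.full(n, 1.0 / n)
        centroids[j] = x[rng.choice(n, p=probs)]
        d = np.minimum(d, cdist(x, centroids[j : j + 1], metric="cityblock")[:, 0])
    return centroids


def _kmedians_once(x, k, rng, max_iter=300, tol=1e-6):
    centroids = _kmeanspp_init(x, k, rng)
    prev_cost = np.inf
    labels = np.zeros(x.shape[0], dtype=int)
    for _ in range(max_iter):
        dist = cdist(x, centroids, metric="cityblock")
        labels = dist.argmin(axis=1)
        for j in range(k):
            members = x[labels == j]
            if members.shape[0] == 0:
                # re-seed an emptied centroid at the point farthest from its
                # nearest current centroid; never drop a cluster silently
                far = int(dist.min(axis=1).argmax())
                centroids[j] = x[far]
                labels[far] = j
            else:
                centroids[j] = np.median(members, axis=0)
        cost = float(cdist(x, centroids, metric="cityblock")[np.arange(x.shape[0]), labels].sum())
        if prev_cost - cost < tol:
            break
        prev_cost = cost
    return centroids, labels, cost


def cluster_states(vectors, k: int, n_replicates: int = 100, seed: int = 0) -> BrainStateSet:
    """City-block k-means over leading eigenvectors, best of ``n_replicates`` restarts.

    Centroid update is the component-wise median (the L1 cost minimizer);
    restarts use k-means++-style seeding.  Returned states are relabeled
    1..K by descending occurrence probability on the clustering input.
    """
    x = vectors.vectors if isinstance(vectors, LeadingEigenvectorSet) else np.asarray(vectors, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if x.shape[0] < k:
        raise ValueError(f"{x.shape[0]} rows < k={k}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_replicates):
        centroids, labels, cost = _kmedians_once(x, k, rng)
        if best is None or cost < best[2]:
            best = (centroids, labels, cost)
    centroids, labels, cost = best
    counts = np.bincount(labels, minlength=k)
    order = np.argsort(-counts, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return BrainStateSet(
        centroids=centroids[order],
        k=k,
        assignment=relabel[labels] + 1,
        inertia=cost,
    )


def assign_to_centroids(vectors, states: BrainStateSet | np.ndarray) -> np.ndarray:
    """1-based label of the city-block-nearest centroid for every row; ties
    go to the lowest label."""
    x = vectors.vectors if isinstance(vectors, LeadingEigenvectorSet) else np.atleast_2d(np.asarray(vectors, dtype=float))
    centroids = states.centroids if isinstance(states, BrainStateSet) else np.asarray(states)
    if x.shape[1] != centroids.shape[1]:
        raise ValueError("dimension mismatch between rows and centroids")
    dist = cdist(x, centroids, metric="cityblock")
    return dist.argmin(axis=1) + 1  # argmin takes the lowest index on ties


@dataclass
class StatePMS:
    """Occurrence-probability vector over K states (sums to 1)."""

    probabilities: np.ndarray
    level: str = "subject"

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        s = self.probabilities.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError(f"probabilities sum to {s}, expected 1")


def occurrence_probabilities(sequence, k: int, level: str = "subject") -> StatePMS:
    """Relative frequency of each state label (1..k) in a state sequence."""
    sequence = np.asarray(sequence, dtype=int)
    if sequence.size == 0:
        raise ValueError("empty state sequence")
    if sequence.min() < 1 or sequence.max() > k:
        raise ValueError(f"labels must lie in 1..{k}")
    counts = np.bincount(sequence - 1, minlength=k)
    return StatePMS(counts / sequence.size, level=level)


# ---------------------------------------------------------------------------
# state / network correspondence
# ---------------------------------------------------------------------------

def network_correlation(centroid: np.ndarray, region_table, network: str,
                        alpha: float = 0.05):
    """Pearson r between the rectified centroid and a network's 0/1 indicator.

    Negative centroid components are set to 0 first (only the minority
    "active" community is compared to the network partition).  The 95% CI
    uses the Fisher z-transform; BH correction across networks is up to the
    caller.  Returns ``(r, ci_low, ci_high, p)``.
    """
    centroid = np.asarray(centroid, dtype=float)
    networks = np.asarray(region_table["network"])
    if centroid.shape[0] != networks.shape[0]:
        raise ValueError("centroid length does not match region table")
    rectified = np.maximum(centroid, 0.0)
    if np.ptp(rectified) == 0:
        raise ValueError("rectified centroid has zero variance; correlation undefined")
    indicator = (networks == network).astype(float)
    if np.ptp(indicator) == 0:
        raise ValueError(f"network {network!r} indicator has zero variance")
    r, p = pearsonr(rectified, indicator)
    n = centroid.shape[0]
    z = np.arctanh(r)
    half = norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return float(r), float(np.tanh(z - half)), float(np.tanh(z + half)), float(p)
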