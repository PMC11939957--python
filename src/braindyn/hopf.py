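"""Coupled Stuart-Landau (supercritical Hopf) whole-brain model.

Each region i obeys

    dx_i/dt = (a_i - x_i^2 - y_i^2) x_i - w_i y_i + G sum_j C_ij (x_j - x_i) + s n_i(t)
    dy_i/dt = (a_i - x_i^2 - y_i^2) y_i + w_i x_i + G sum_j C_ij (y_j - y_i) + s n_i(t)

with bifurcation parameter a_i (a<0: noise-driven fluctuations around a
stable focus; a>0: limit cycle of radius sqrt(a)), intrinsic angular
frequency w_i, coupling matrix C scaled by a global coupling G, and
independent Gaussian white noise of amplitude sigma in each component.
x_i is read out as the simulated BOLD signal.

Integration is Euler-Maruyama; the first ``burn_in`` seconds are discarded
and x is subsampled every TR into BOLD-like volumes.  Model fit to data is
scored by the symmetrized-KL ("J-S") distance between simulated and
empirical state-occupancy distributions, swept over G.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .leida import (
    StatePMS,
    assign_to_centroids,
    bandpass_filter,
    hilbert_phase,
    occurrence_probabilities,
    _leading_eigenvectors_rank2,
    DEFAULT_BAND,
)

__all__ = [
    "HopfModelSpec",
    "SimulationConfig",
    "OscillatorTrajectory",
    "estimate_natural_frequencies",
    "normalize_coupling",
    "simulate_hopf",
    "simulated_pms",
    "js_distance",
    "ensemble_pms",
    "sweep_global_coupling",
    "default_g_grid",
]

COUPLING_MAX = 0.2  # normalization ceiling that prevents full synchronization
DEFAULT_A = -0.02
DEFAULT_DT = 0.1     # s; stable for omega <= 2*pi*0.08 rad/s
DEFAULT_SIGMA = 0.02
DEFAULT_BURN_IN = 3000.0  # s


@dataclass
class HopfModelSpec:
    """Parameters of the coupled-oscillator network.

    ``coupling`` may be a symmetric structural matrix or a directed
    effective-connectivity matrix; it is used as-is (callers normalize).
    """

    a: np.ndarray
    omega: np.ndarray
    coupling: np.ndarray
    g: float
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self):
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        self.coupling = np.atleast_2d(np.asarray(self.coupling, dtype=float))
        n = self.a.shape[0]
        if self.omega.shape[0] != n or self.coupling.shape != (n, n):
            raise ValueError("a, omega and coupling dimensions disagree")
        if np.any(self.omega <= 0):
            raise ValueError("omega must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def n_regions(self) -> int:
        return self.a.shape[0]

    def with_g(self, g: float) -> "HopfModelSpec":
        return replace(self, g=g)


@dataclass
class SimulationConfig:
    duration: float
    tr: float = 2.0
    dt: float = DEFAULT_DT
    burn_in: float = DEFAULT_BURN_IN
    seed: int = 0

    def __post_init__(self):
        if self.dt >= self.tr:
            raise ValueError("dt must be smaller than tr")
        n_vol = self.duration / self.tr
        if self.duration <= 0 or abs(n_vol - round(n_vol)) > 1e-9:
            raise ValueError("duration must be a positive multiple of tr")

    @property
    def n_volumes(self) -> int:
        return int(round(self.duration / self.tr))


@dataclass
class OscillatorTrajectory:
    """Simulated network activity: BOLD-like samples at TR (``sampled_x``)
    and, when requested, the full-resolution x/y components."""

    sampled_x: np.ndarray
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    tr: float = 2.0


def estimate_natural_frequencies(cohort, band=DEFAULT_BAND) -> np.ndarray:
    """Per-region intrinsic angular frequency omega_i = 2*pi*f_i, where f_i is
    the across-subject mean in-band spectral peak of the band-filtered series."""
    series_list = cohort.series if hasattr(cohort, "series") else list(cohort)
    if len(series_list) == 0:
        raise ValueError("cohort has no subjects")
    tr = cohort.tr if hasattr(cohort, "tr") else 2.0
    peaks = []
    for series in series_list:
        filtered = bandpass_filter(np.atleast_2d(series), tr, band[0], band[1])
        freqs, power = signal.periodogram(filtered, fs=1.0 / tr, axis=1)
        in_band = (freqs >= band[0]) & (freqs <= band[1])
        if not np.any(in_band):
            raise ValueError("no spectral bins inside the requested band")
        sub = power[:, in_band]
        if np.any(sub.max(axis=1) <= 0):
            raise ValueError("flat in-band spectrum; peak frequency undefined")
        peaks.append(freqs[in_band][sub.argmax(axis=1)])
    return 2.0 * np.pi * np.mean(peaks, axis=0)


def normalize_coupling(matrix: np.ndarray, ceiling: float = COUPLING_MAX) -> np.ndarray:
    """Rescale a non-negative coupling matrix so its maximum entry equals 0.2."""
    matrix = np.asarray(matrix, dtype=float)
    if np.any(matrix < 0):
        raise ValueError("coupling matrix must be non-negative")
    m = matrix.max()
    if m <= 0:
        raise ValueError("all-zero coupling matrix cannot be normalized")
    return matrix * (ceiling / m)


def simulate_hopf(spec: HopfModelSpec, config: SimulationConfig,
                  store_full: bool = False) -> OscillatorTrajectory:
    """Euler-Maruyama integration of the coupled Stuart-Landau network.

    Independent N(0, dt) increments enter x and y of every region.  The
    burn-in segment is discarded; x is subsampled (not averaged) every
    tr/dt steps into ``sampled_x`` with exactly duration/tr columns.
    Deterministic for a fixed seed.
    """
    n = spec.n_regions
    dt = config.dt
    stride = int(round(config.tr / dt))
    if abs(stride * dt - config.tr) > 1e-9:
        raise ValueError("tr must be an integer multiple of dt")
    burn_steps = int(round(config.burn_in / dt))
    n_vol = config.n_volumes
    total_steps = burn_steps + (n_vol - 1) * stride + 1

    rng = np.random.default_rng(config.seed)
    x = 0.1 * rng.standard_normal(n)
    y = 0.1 * rng.standard_normal(n)
    a, omega, g = spec.a, spec.omega, spec.g
    c = spec.coupling
    row_sum = c.sum(axis=1)
    sqrt_dt = np.sqrt(dt)
    sigma = spec.sigma

    sampled = np.empty((n, n_vol))
    full_x = np.empty((n, total_steps - burn_steps)) if store_full else None
    full_y = np.empty((n, total_steps - burn_steps)) if store_full else None

    vol = 0
    for step in range(total_steps):
        if step >= burn_steps:
            post = step - burn_steps
            if store_full:
                full_x[:, post] = x
                full_y[:, post] = y
            if post % stride == 0:
                sampled[:, vol] = x
                vol += 1
        r2 = x * x + y * y
        coup_x = g * (c @ x - row_sum * x)
        coup_y = g * (c @ y - row_sum * y)
        dx = (a - r2) * x - omega * y + coup_x
        dy = (a - r2) * y + omega * x + coup_y
        if sigma > 0:
            noise = rng.standard_normal((2, n))
            x = x + dt * dx + sigma * sqrt_dt * noise[0]
            y = y + dt * dy + sigma * sqrt_dt * noise[1]
        else:
            x = x + dt * dx
            y = y + dt * dy
        if step % 500 == 0 and not np.all(np.abs(x) < 1e6):
            bad = int(np.argmax(np.abs(x)))
            raise FloatingPointError(
                f"numerical blow-up in region {bad} at step {step}"
            )
    return OscillatorTrajectory(sampled_x=sampled, x=full_x, y=full_y, tr=config.tr)


def simulated_pms(trajectory: OscillatorTrajectory, centroids, band=DEFAULT_BAND,
                  tr: float | None = None) -> StatePMS:
    """Occupancy distribution of a simulated series over empirical states.

    The sampled series is pushed through the LEiDA stages (band-pass,
    Hilbert phase, per-volume leading eigenvector) and each volume is
    assigned to its nearest empirical centroid.
    """
    sampled = trajectory.sampled_x if isinstance(trajectory, OscillatorTrajectory) else np.asarray(trajectory)
    tr = tr if tr is not None else getattr(trajectory, "tr", 2.0)
    if sampled.shape[1] < 10:
        raise ValueError("need at least 10 volumes to estimate a PMS")
    cents = centroids.centroids if hasattr(centroids, "centroids") else np.asarray(centroids)
    if sampled.shape[0] != cents.shape[1]:
        raise ValueError("region count does not match centroid dimension")
    theta = hilbert_phase(bandpass_filter(sampled, tr, band[0], band[1]))
    vectors = _leading_eigenvectors_rank2(theta)
    labels = assign_to_centroids(vectors, cents)
    return occurrence_probabilities(labels, cents.shape[0], level="group")


def js_distance(p, q, floor: float = 1e-12) -> float:
    """Symmetrized Kullback-Leibler divergence between two state distributions:

        0.5 * [ sum_i p_i ln(p_i/q_i) + sum_i q_i ln(q_i/p_i) ]

    Probabilities are floored at ``floor`` and renormalized so the formula is
    defined at zeros.  Symmetric, non-negative, zero iff p == q.
    """
    p = p.probabilities if isinstance(p, StatePMS) else np.asarray(p, dtype=float)
    q = q.probabilities if isinstance(q, StatePMS) else np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions have different numbers of states")
    p = np.maximum(p, floor)
    q = np.maximum(q, floor)
    p = p / p.sum()
    q = q / q.sum()
    log_ratio = np.log(p / q)
    return float(0.5 * (np.sum(p * log_ratio) - np.sum(q * log_ratio)))


def ensemble_pms(spec: HopfModelSpec, centroids, config: SimulationConfig,
                 n_runs: int = 1, band=DEFAULT_BAND) -> StatePMS:
    """PMS pooled over ``n_runs`` independent simulation runs.

    With ``n_runs`` = 1 this is a single continuous simulation of
    ``config.duration`` (the fitting default: duration equal to the total
    scanning time).  With ``n_runs`` > 1 the duration is split into that
    many independent runs whose state sequences are pooled, mirroring the
    session structure of a multi-subject cohort (each subject is a separate
    noise realization with its own transient).
    """
    from dataclasses import replace as _replace

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    cents = centroids.centroids if hasattr(centroids, "centroids") else np.asarray(centroids)
    k = cents.shape[0]
    counts = np.zeros(k)
    # each run must span a whole number of volumes
    run_duration = max(1.0, round(config.duration / n_runs / config.tr)) * config.tr
    for run in range(n_runs):
        cfg = _replace(config, duration=run_duration, seed=config.seed + 104729 * run)
        traj = simulate_hopf(spec, cfg)
        pms = simulated_pms(traj, cents, band=band, tr=config.tr)
        counts += pms.probabilities * traj.sampled_x.shape[1]
    return StatePMS(counts / counts.sum(), level="group")


def sweep_global_coupling(template: HopfModelSpec, g_grid, empirical_pms,
                          centroids, config: SimulationConfig, n_reps: int = 1,
                          n_runs: int = 1):
    """Fit G by scanning a grid and minimizing the J-S distance between the
    simulated and empirical PMS (default study grid: 0-0.5 in steps of 0.01).

    ``n_reps`` independent noise realizations per grid point are averaged
    (1 by default); repetition damps the Monte-Carlo noise of the distance
    surface the same way the perturbation protocol repeats its trials.
    ``n_runs`` splits each realization into independent runs pooled as in
    :func:`ensemble_pms`, matching a cohort's session structure.
    Returns ``(best_g, distances)``; ties go to the smallest G.
    """
    from dataclasses import replace as _replace

    g_grid = np.asarray(list(g_grid), dtype=float)
    if g_grid.size == 0:
        raise ValueError("empty G grid")
    distances = np.empty(g_grid.size)
    for i, g in enumerate(g_grid):
        vals = []
        for rep in range(n_reps):
            cfg = config if n_reps == 1 else _replace(config, seed=config.seed + 7919 * rep)
            pms = ensemble_pms(template.with_g(float(g)), centroids, cfg, n_runs=n_runs)
            vals.append(js_distance(empirical_pms, pms))
        distances[i] = float(np.mean(vals))
    best = int(np.argmin(distances))  # argmin returns the first (smallest G) on ties
    return float(g_grid[best]), distances


def default_g_grid() -> np.ndarray:
    """The 51-point fitting grid: G = 0, 0.01, ..., 0.5."""
    return np.round(np.arange(0, 51) * 0.01, 10)
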