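"""Effective-connectivity estimation by gradient descent on functional
statistics with a temporal-nonreversibility constraint.

Pairwise Pearson correlations (FC) are mapped to a mutual-information
scale, FS = -1/2 ln(1 - FC^2), so the optimizer handles only non-negative
quantities.  Time-shifted correlations at lag tau are computed on the
forward series and on the time-reversed series; the difference of their FS
transforms, FS_diff(tau), measures the arrow of time (thermodynamic
nonreversibility): it vanishes for time-reversible dynamics and grows with
directed, hierarchical information flow.

The coupling matrix is updated edge-wise,

    G_ij <- G_ij + eps (FS_ij^emp - FS_ij^mod) - eps' (FS_diff_ij^emp - FS_diff_ij^mod),

restricted to pre-existing structural connections plus both directions of
every interhemispheric homolog pair, clipped non-negative and renormalized
to a maximum of 0.2 after every iteration.  Node-level summaries are the
total information flow (row-sum plus column-sum) and the in/out asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .hopf import (
    COUPLING_MAX,
    HopfModelSpec,
    SimulationConfig,
    normalize_coupling,
    simulate_hopf,
)
from .leida import bandpass_filter

__all__ = [
    "ConnectivityStats",
    "OptimizerConfig",
    "ECResult",
    "pearson_fc",
    "fc_to_fs",
    "shifted_stats",
    "ec_update_step",
    "optimize_ec",
    "total_information_flow",
    "node_asymmetry",
    "build_update_mask",
]

FC_CLIP = 0.9999


@dataclass
class ConnectivityStats:
    fc: np.ndarray
    fs: np.ndarray
    fc_forward_tau: np.ndarray
    fc_reversal_tau: np.ndarray
    fs_forward_tau: np.ndarray
    fs_reversal_tau: np.ndarray
    fs_diff_tau: np.ndarray
    tau: float


@dataclass
class OptimizerConfig:
    epsilon: float = 0.001
    epsilon_prime: float = 0.002
    tau: float = 2.0
    max_iter: int = 200
    tol: float = 1e-3
    mode: str = "fs_plus_fsdiff"  # or "fs_only"
    update_mask: np.ndarray | None = None
    n_sims_per_iter: int = 1  # average model stats over this many realizations

    def __post_init__(self):
        if self.mode not in ("fs_only", "fs_plus_fsdiff"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.mode == "fs_plus_fsdiff" and self.epsilon_prime <= 0:
            raise ValueError("epsilon_prime must be positive in fs_plus_fsdiff mode")


@dataclass
class ECResult:
    ec: np.ndarray
    fit_history: list
    g_total: np.ndarray
    asymmetry: np.ndarray


def pearson_fc(series: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of an N x T series; symmetric, unit diagonal."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = series.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"region {bad} has zero variance")
    fc = np.corrcoef(series)
    np.fill_diagonal(fc, 1.0)
    return fc


def fc_to_fs(fc) -> np.ndarray:
    """Mutual-information transform -1/2 ln(1 - fc^2), |fc| clipped to 0.9999."""
    fc = np.clip(np.abs(np.asarray(fc, dtype=float)), 0.0, FC_CLIP)
    return -0.5 * np.log1p(-(fc**2))


def _cross_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """corr(a_i, b_j) for all pairs; a, b are N x T with matching T."""
    az = (a - a.mean(axis=1, keepdims=True))
    bz = (b - b.mean(axis=1, keepdims=True))
    az /= np.linalg.norm(az, axis=1, keepdims=True)
    bz /= np.linalg.norm(bz, axis=1, keepdims=True)
    return az @ bz.T


def shifted_stats(series: np.ndarray, tau: float, tr: float) -> ConnectivityStats:
    """FC/FS plus forward and time-reversed shifted correlations at lag tau.

    Forward: corr(x_i(t), x_j(t+s)) with s = tau/tr samples; reversal: the
    same on the order-flipped series.  FS_diff = FS_forward - FS_reversal.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    s_float = tau / tr
    s = int(round(s_float))
    if abs(s_float - s) > 1e-9:
        raise ValueError(f"tau={tau} is not an integer multiple of tr={tr}")
    t_len = series.shape[1]
    if t_len <= 2 * s:
        raise ValueError("series too short for the requested shift")
    fc = pearson_fc(series)
    fs = fc_to_fs(fc)
    if s == 0:
        fwd = rev = fc
    else:
        fwd = _cross_corr(series[:, :-s], series[:, s:])
        flipped = series[:, ::-1]
        rev = _cross_corr(flipped[:, :-s], flipped[:, s:])
    fs_fwd, fs_rev = fc_to_fs(fwd), fc_to_fs(rev)
    return ConnectivityStats(
        fc=fc, fs=fs, fc_forward_tau=fwd, fc_reversal_tau=rev,
        fs_forward_tau=fs_fwd, fs_reversal_tau=fs_rev,
        fs_diff_tau=fs_fwd - fs_rev, tau=tau,
    )


def build_update_mask(sc: np.ndarray, region_table=None) -> np.ndarray:
    """Edges the optimizer may touch: existing structural connections plus
    both directions of every homolog pair; never the diagonal."""
    mask = np.asarray(sc) > 0
    if region_table is not None:
        from .cohort import homolog_pairs

        for a, b in homolog_pairs(region_table):
            mask[a, b] = mask[b, a] = True
    np.fill_diagonal(mask, False)
    return mask


def ec_update_step(g: np.ndarray, empirical: ConnectivityStats,
                   model: ConnectivityStats, config: OptimizerConfig) -> np.ndarray:
    """One gradient-descent update of the coupling matrix.

    Masked entries move by eps*(FS gap) - eps'*(FS_diff gap) (the second
    term only in combined mode); unmasked entries are untouched; negatives
    are clipped to 0 and the matrix is renormalized to max 0.2.
    """
    g = np.asarray(g, dtype=float).copy()
    mask = config.update_mask
    if mask is None:
        raise ValueError("OptimizerConfig.update_mask is required")
    delta = config.epsilon * (empirical.fs - model.fs)
    if config.mode == "fs_plus_fsdiff":
        delta = delta - config.epsilon_prime * (empirical.fs_diff_tau - model.fs_diff_tau)
    g[mask] += delta[mask]
    np.clip(g, 0.0, None, out=g)
    return normalize_coupling(g, COUPLING_MAX)


def _offdiag(m: np.ndarray) -> np.ndarray:
    n = m.shape[0]
    return m[~np.eye(n, dtype=bool)]


def _fit_correlations(empirical: ConnectivityStats, model: ConnectivityStats):
    corr_fs = float(np.corrcoef(_offdiag(empirical.fs), _offdiag(model.fs))[0, 1])
    corr_diff = float(np.corrcoef(_offdiag(empirical.fs_diff_tau),
                                  _offdiag(model.fs_diff_tau))[0, 1])
    return corr_fs, corr_diff


def optimize_ec(empirical: ConnectivityStats, initial_sc: np.ndarray,
                spec_template: HopfModelSpec, config: OptimizerConfig,
                sim_config: SimulationConfig, band=(0.01, 0.08),
                filter_series: bool = True) -> ECResult:
    """Iterate simulate -> stats -> update until convergence.

    Each iteration simulates the Hopf model with the current coupling (one
    noise realization, iteration-indexed seed), computes the model's
    FS/FS_diff on the (optionally band-filtered) sampled series, applies
    :func:`ec_update_step`, and records the empirical-model correlations of
    FS and FS_diff.  Stops at ``max_iter`` or when the combined objective
    (1 - corr_FS, plus 1 - corr_FSdiff in combined mode) improves by less
    than ``tol`` over a 5-iteration window.
    """
    ec = normalize_coupling(np.asarray(initial_sc, dtype=float))
    history = []
    objectives = []

    def model_stats(coupling, it):
        spec = replace(spec_template, coupling=coupling)
        acc = None
        for rep in range(config.n_sims_per_iter):
            seed = sim_config.seed + 131 * it + 7 * rep
            traj = simulate_hopf(spec, replace(sim_config, seed=seed))
            x = traj.sampled_x
            if filter_series:
                x = bandpass_filter(x, sim_config.tr, band[0], band[1])
            s = shifted_stats(x, config.tau, sim_config.tr)
            if acc is None:
                acc = s
            else:  # running average of every matrix-valued field
                for name in ("fc", "fs", "fc_forward_tau", "fc_reversal_tau",
                             "fs_forward_tau", "fs_reversal_tau", "fs_diff_tau"):
                    setattr(acc, name, getattr(acc, name) + getattr(s, name))
        if config.n_sims_per_iter > 1:
            for name in ("fc", "fs", "fc_forward_tau", "fc_reversal_tau",
                         "fs_forward_tau", "fs_reversal_tau", "fs_diff_tau"):
                setattr(acc, name, getattr(acc, name) / config.n_sims_per_iter)
        return acc

    def objective(corr_fs, corr_diff):
        obj = 1.0 - corr_fs
        if config.mode == "fs_plus_fsdiff":
            obj += 1.0 - corr_diff
        return obj

    stats = model_stats(ec, 0)
    corr_fs, corr_diff = _fit_correlations(empirical, stats)
    history.append((corr_fs, corr_diff))
    objectives.append(objective(corr_fs, corr_diff))

    for it in range(1, config.max_iter + 1):
        ec = ec_update_step(ec, empirical, stats, config)
        stats = model_stats(ec, it)
        corr_fs, corr_diff = _fit_correlations(empirical, stats)
        history.append((corr_fs, corr_diff))
        objectives.append(objective(corr_fs, corr_diff))
        # stop once the running best has not improved by tol over 5 iterations
        best = np.minimum.accumulate(objectives)
        improvement = best[max(0, it - 5)] - best[it]
        if improvement < config.tol:
            break

    return ECResult(
        ec=ec,
        fit_history=history,
        g_total=total_information_flow(ec),
        asymmetry=node_asymmetry(ec),
    )


def total_information_flow(ec: np.ndarray) -> np.ndarray:
    """Per-node total information flow: sum of outgoing plus incoming weights."""
    ec = np.asarray(ec, dtype=float)
    if ec.ndim != 2 or ec.shape[0] != ec.shape[1]:
        raise ValueError("ec must be square")
    return ec.sum(axis=1) + ec.sum(axis=0)


def node_asymmetry(ec: np.ndarray, normalized: bool = False) -> np.ndarray:
    """Per-node directionality: sum_j |G_ij - G_ji| (optionally divided by the
    node's total flow).  Zero for symmetric matrices; invariant under adding
    any symmetric matrix."""
    ec = np.asarray(ec, dtype=float)
    if ec.ndim != 2 or ec.shape[0] != ec.shape[1]:
        raise ValueError("ec must be square")
    asym = np.abs(ec - ec.T).sum(axis=1)
    if normalized:
        tot = total_information_flow(ec)
        asym = np.divide(asym, tot, out=np.zeros_like(asym), where=tot > 0)
    return asym
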