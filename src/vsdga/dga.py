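"""Galerkin estimation of committors, equilibrium weights, and mean
first-passage times from ensembles of short trajectories.

The statistic of interest f is expanded as ``f = gamma + sum_i v_i phi_i``
with basis functions that vanish on the boundary states.  Substituting the
expansion into the stopped-process operator equation and averaging over
sampled trajectory pairs yields the linear system

    (C_t - C_0) v = -(r_t - r_0),

where ``C_t[i, j]`` is the sampled correlation of phi_i at a start frame
with phi_j at the corresponding stopped end frame, and r carries the guess
function.  With an indicator (cluster one-hot) basis this reduces exactly
to a Markov state model with absorbing boundary conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .states import LABEL_A, LABEL_B, BasisSet, StoppedEnsemble, stop_times
from .synthetic import ShortTrajectoryEnsemble

__all__ = [
    "CorrelationSystem",
    "CommittorField",
    "WeightField",
    "MFPTField",
    "assemble_system",
    "solve_committor",
    "solve_weights",
    "solve_mfpt",
]


@dataclass
class CorrelationSystem:
    C_t: np.ndarray
    C_0: np.ndarray
    r_t: np.ndarray
    r_0: np.ndarray
    lag: int
    n_pairs: int


@dataclass
class CommittorField:
    q_plus: np.ndarray       # clipped to [0, 1], exact on boundary frames
    raw_values: np.ndarray   # pre-clip reconstruction
    lag: int
    condition_number: float = np.nan


@dataclass
class WeightField:
    w: np.ndarray            # per-frame, nonnegative, mean 1
    cluster_weights: np.ndarray | None = None
    lag: int = 1


@dataclass
class MFPTField:
    m: np.ndarray            # per-frame expected time to B, physical units
    lag: int = 1
    condition_number: float = np.nan


def assemble_system(
    basis: BasisSet,
    stopped: StoppedEnsemble,
    guess: np.ndarray | None = None,
) -> CorrelationSystem:
    """Build the stopped-process correlation matrices from trajectory pairs.

    Every valid start frame contributes one (start, stopped-end) pair; all
    averages are over pairs.  ``C_0``/``r_0`` use the start frame at both
    ends (lag-zero limit of the same estimator).
    """
    if stopped.n_pairs == 0:
        raise ValueError("no valid start frames")
    gamma = basis.guess if guess is None else np.asarray(guess, dtype=float)
    phi = basis.values
    s, e = stopped.start_index, stopped.stop_index
    M = stopped.n_pairs
    if M <= basis.n_basis:
        warnings.warn(
            f"only {M} trajectory pairs for {basis.n_basis} basis functions",
            RuntimeWarning,
        )
    Ps, Pe = phi[s], phi[e]
    C_t = _dense(Ps.T @ Pe) / M
    C_0 = _dense(Ps.T @ Ps) / M
    r_t = np.ravel(Ps.T @ gamma[e]) / M
    r_0 = np.ravel(Ps.T @ gamma[s]) / M
    return CorrelationSystem(C_t=C_t, C_0=C_0, r_t=r_t, r_0=r_0,
                             lag=stopped.lag, n_pairs=M)


def _dense(A) -> np.ndarray:
    return np.asarray(A.todense()) if hasattr(A, "todense") else np.asarray(A)


def _solve(system: CorrelationSystem, rhs: np.ndarray, cond: float = 1e-10):
    A = system.C_t - system.C_0
    condition = np.linalg.cond(A)
    if not np.isfinite(condition):
        raise np.linalg.LinAlgError(
            "singular DGA system; try a larger whitening tolerance or lag"
        )
    v, *_ = scipy.linalg.lstsq(A, rhs, cond=cond)
    return v, condition


def solve_committor(
    system: CorrelationSystem,
    basis: BasisSet,
    labels: np.ndarray | None = None,
    guess: np.ndarray | None = None,
) -> CommittorField:
    """Solve for the forward committor and reconstruct it on every frame.

    The reconstruction ``gamma + phi v`` is clipped to [0, 1]; boundary
    frames (labels A/B) are pinned to their exact values.
    """
    gamma = basis.guess if guess is None else np.asarray(guess, dtype=float)
    v, condition = _solve(system, -(system.r_t - system.r_0))
    raw = gamma + np.ravel(basis.values @ v)
    q = np.clip(raw, 0.0, 1.0)
    if labels is not None:
        labels = np.asarray(labels)
        q[labels == LABEL_A] = 0.0
        q[labels == LABEL_B] = 1.0
    return CommittorField(q_plus=q, raw_values=raw, lag=system.lag,
                          condition_number=condition)


def _largest_closed_class(T_counts: np.ndarray) -> np.ndarray:
    """Indices of the largest closed communicating class of a count matrix."""
    import scipy.sparse.csgraph as csgraph

    n = len(T_counts)
    n_comp, comp = csgraph.connected_components(T_counts > 0, directed=True,
                                                connection="strong")
    # a class is closed if no transitions leave it
    best: np.ndarray | None = None
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        outside = np.flatnonzero(comp != c)
        if outside.size and T_counts[np.ix_(members, outside)].sum() > 0:
            continue
        if best is None or members.size > best.size:
            best = members
    if best is None:  # should not happen: a finite chain has a closed class
        best = np.arange(n)
    return best


def solve_weights(
    ensemble: ShortTrajectoryEnsemble,
    basis: BasisSet,
    lag: int = 1,
) -> WeightField:
    """Equilibrium weight factor w = pi/mu from an indicator basis.

    Builds the cluster-level transition matrix from unstopped ``(t, t+lag)``
    pairs, takes its stationary distribution, and assigns each frame the
    ratio of stationary cluster probability to empirical cluster frequency,
    normalized to frame-mean 1.  A reducible empirical matrix falls back to
    its largest closed communicating class with a warning.
    """
    if basis.kind != "indicator" or basis.cluster_labels is None:
        raise ValueError("solve_weights requires an indicator basis")
    clusters = basis.cluster_labels
    k = basis.n_basis
    offsets = ensemble.offsets
    starts, ends = [], []
    for i in range(ensemble.n_traj):
        lo, hi = offsets[i], offsets[i + 1]
        if hi - lo <= lag:
            continue
        starts.append(np.arange(lo, hi - lag))
        ends.append(np.arange(lo + lag, hi))
    if not starts:
        raise ValueError("lag exceeds every trajectory length")
    s = np.concatenate(starts)
    e = np.concatenate(ends)

    counts = np.zeros((k, k))
    np.add.at(counts, (clusters[s], clusters[e]), 1.0)

    live = _largest_closed_class(counts)
    if live.size < k:
        warnings.warn(
            f"empirical transition matrix reducible: using largest closed class "
            f"({live.size}/{k} clusters); frames outside get weight 0",
            RuntimeWarning,
        )
    sub = counts[np.ix_(live, live)]
    T = sub / sub.sum(axis=1, keepdims=True)
    vals, vecs = np.linalg.eig(T.T)
    idx = np.argmin(np.abs(vals - 1.0))
    pi_sub = np.abs(np.real(vecs[:, idx]))
    pi_sub /= pi_sub.sum()

    pi = np.zeros(k)
    pi[live] = pi_sub
    freq = np.bincount(clusters[s], minlength=k).astype(float)
    freq /= freq.sum()
    cluster_w = np.zeros(k)
    nz = freq > 0
    cluster_w[nz] = pi[nz] / freq[nz]

    w = cluster_w[clusters]
    w = w / w.mean()
    return WeightField(w=w, cluster_weights=cluster_w, lag=lag)


def solve_mfpt(
    ensemble: ShortTrajectoryEnsemble,
    basis: BasisSet,
    labels: np.ndarray,
    lag: int = 1,
) -> MFPTField:
    """Mean first-passage time to the product state B via the stopped
    Feynman-Kac linear system.

    The process is stopped on B only; the accumulated reward is the elapsed
    stopped time, so with guess 0 the system is ``(C_t - C_0) v = -tau``
    with ``tau[i]`` the mean of ``phi_i(start) * elapsed``.  Times are
    returned in physical units (frames times save_interval).
    """
    stopped = stop_times(ensemble, labels, lag, stop_on=(LABEL_B,))
    # boundary handling: basis must vanish on B
    onB = np.asarray(labels) == LABEL_B
    b = basis.with_boundary(labels, stop_on=(LABEL_B,))
    b.guess = np.zeros(ensemble.n_frames)
    system = assemble_system(b, stopped)
    elapsed = stopped.elapsed.astype(float) * ensemble.save_interval
    tau = np.ravel(b.values[stopped.start_index].T @ elapsed) / stopped.n_pairs
    v, condition = _solve(system, -tau)
    m = np.maximum(np.ravel(b.values @ v), 0.0)
    m[onB] = 0.0
    return MFPTField(m=m, lag=lag, condition_number=condition)
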