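"""Synthetic dynamics with exactly solvable reference statistics.

This module provides the test bed for every estimator in the package:

* discrete Markov chains with committors, stationary distributions, mean
  first-passage times, and transition-path-theory currents obtained by
  direct linear solves;
* overdamped Langevin dynamics on model energy landscapes (Euler-Maruyama);
* a five-basin surrogate of a voltage-sensing domain, with two slow
  coordinates playing the role of S4 helix translocation and rotation, a
  set of noisy distance-like features coupled to them, and a near-discrete
  displacement-charge-like observable.

All generators take an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "MarkovChainModel",
    "LangevinModel",
    "SurrogateVSDModel",
    "ShortTrajectoryEnsemble",
    "simulate_chain",
    "simulate_langevin",
    "make_vsd_surrogate",
    "exact_committor",
    "exact_stationary",
    "exact_mfpt",
    "exact_tpt",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class ShortTrajectoryEnsemble:
    """Ensemble of fixed-interval trajectories of feature vectors.

    ``trajectories`` is a list of arrays, each of shape ``(n_frames, p)``
    (or ``(n_frames,)`` for scalar state indices).  All trajectories share
    the feature dimensionality and each has at least two frames.
    ``save_interval`` is the physical time between consecutive frames.
    """

    trajectories: list[np.ndarray]
    save_interval: float = 1.0
    start_distribution_tag: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ValueError("ensemble must contain at least one trajectory")
        dims = {t.shape[1:] for t in self.trajectories}
        if len(dims) != 1:
            raise ValueError(f"inconsistent feature dimensionality: {dims}")
        for k, t in enumerate(self.trajectories):
            if len(t) < 2:
                raise ValueError(f"trajectory {k} has fewer than 2 frames")

    @property
    def n_traj(self) -> int:
        return len(self.trajectories)

    @property
    def n_frames(self) -> int:
        return sum(len(t) for t in self.trajectories)

    @property
    def offsets(self) -> np.ndarray:
        """CSR-style frame offsets: ``offsets[k]:offsets[k+1]`` indexes
        trajectory ``k`` in the stacked frame array."""
        lens = [len(t) for t in self.trajectories]
        return np.concatenate([[0], np.cumsum(lens)])

    @property
    def stacked(self) -> np.ndarray:
        return np.concatenate(self.trajectories, axis=0)

    def map_frames(self, func: Callable[[np.ndarray], np.ndarray]) -> "ShortTrajectoryEnsemble":
        """Apply a per-frame map (e.g. a feature map) to every trajectory."""
        return ShortTrajectoryEnsemble(
            trajectories=[np.asarray(func(t)) for t in self.trajectories],
            save_interval=self.save_interval,
            start_distribution_tag=self.start_distribution_tag,
            seed=self.seed,
        )


@dataclass
class MarkovChainModel:
    """Discrete-state Markov chain at a fixed lag.

    ``transition_matrix`` holds per-lag jump probabilities (row-stochastic).
    ``state_labels`` optionally attaches collective-variable coordinates to
    each state so chain trajectories can be projected into CV space.
    """

    transition_matrix: np.ndarray
    state_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(P < 0):
            raise ValueError("transition matrix has negative entries")
        rowsum = P.sum(axis=1)
        bad = np.flatnonzero(np.abs(rowsum - 1.0) > 1e-12)
        if bad.size:
            raise ValueError(
                f"rows {bad.tolist()} of the transition matrix do not sum to 1 "
                f"(sums {rowsum[bad].tolist()})"
            )
        self.transition_matrix = P
        if self.state_labels is not None:
            self.state_labels = np.asarray(self.state_labels, dtype=float)
            if len(self.state_labels) != P.shape[0]:
                raise ValueError("state_labels length must equal n_states")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


@dataclass
class LangevinModel:
    """Overdamped Langevin dynamics on a 1-2 dimensional potential.

    The potential is a vectorized callable returning energies in kT units
    of ``kT`` for an array of shape ``(n, dim)``.  An analytic gradient can
    be supplied; otherwise central differences are used.
    """

    potential: Callable[[np.ndarray], np.ndarray]
    kT: float
    diffusion_coefficient: float = 1.0
    timestep: float = 1e-3
    save_interval: int = 1
    gradient: Callable[[np.ndarray], np.ndarray] | None = None
    grad_eps: float = 1e-5

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion_coefficient must be positive")
        if self.save_interval < 1:
            raise ValueError("save_interval must be >= 1")

    def grad(self, x: np.ndarray) -> np.ndarray:
        if self.gradient is not None:
            return np.asarray(self.gradient(x))
        g = np.empty_like(x)
        for d in range(x.shape[1]):
            xp = x.copy()
            xm = x.copy()
            xp[:, d] += self.grad_eps
            xm[:, d] -= self.grad_eps
            g[:, d] = (self.potential(xp) - self.potential(xm)) / (2 * self.grad_eps)
        return g


# --------------------------------------------------------------------------
# trajectory generators
# --------------------------------------------------------------------------


def simulate_chain(
    model: MarkovChainModel,
    n_traj: int,
    traj_len: int,
    init_dist: np.ndarray,
    seed: int,
    project: bool = False,
) -> ShortTrajectoryEnsemble:
    """Sample ``n_traj`` trajectories of ``traj_len`` frames from the chain.

    Starting states are drawn i.i.d. from ``init_dist``.  With
    ``project=True`` state indices are mapped through ``state_labels``.
    """
    if traj_len < 2:
        raise ValueError("traj_len must be >= 2")
    init_dist = np.asarray(init_dist, dtype=float)
    if init_dist.shape != (model.n_states,) or abs(init_dist.sum() - 1.0) > 1e-10:
        raise ValueError("init_dist must be a probability vector over states")
    rng = np.random.default_rng(seed)
    P = model.transition_matrix
    cum = np.cumsum(P, axis=1)
    states = np.empty((n_traj, traj_len), dtype=np.int64)
    states[:, 0] = rng.choice(model.n_states, size=n_traj, p=init_dist)
    # vectorized over trajectories: one uniform per (traj, step)
    u = rng.random((n_traj, traj_len - 1))
    for t in range(1, traj_len):
        row = cum[states[:, t - 1]]
        states[:, t] = (u[:, t - 1, None] >= row).sum(axis=1)
    trajs: list[np.ndarray]
    if project:
        if model.state_labels is None:
            raise ValueError("project=True requires state_labels")
        trajs = [model.state_labels[s] for s in states]
    else:
        trajs = [s.copy() for s in states]
    return ShortTrajectoryEnsemble(
        trajectories=trajs,
        save_interval=1.0,
        start_distribution_tag="chain-init",
        seed=seed,
    )


def simulate_langevin(
    model: LangevinModel,
    n_traj: int,
    n_steps: int,
    init_points: np.ndarray,
    seed: int,
) -> ShortTrajectoryEnsemble:
    """Integrate the overdamped Langevin equation from the given starts.

    Update rule: ``x <- x - grad(U) * (D/kT) * dt + sqrt(2 D dt) * eta`` with
    U in energy units (the ``potential`` callable returns U/kT scaled by kT).
    Frames are saved every ``save_interval`` steps (the initial point is
    frame 0).  With ``kT == 0`` the dynamics are pure gradient descent.
    """
    init = np.atleast_2d(np.asarray(init_points, dtype=float))
    if init.shape[0] != n_traj:
        raise ValueError(f"init_points has {init.shape[0]} rows, expected n_traj={n_traj}")
    rng = np.random.default_rng(seed)
    dt = model.timestep
    D = model.diffusion_coefficient
    mobility = D / model.kT if model.kT > 0 else D
    noise_amp = np.sqrt(2.0 * D * dt) if model.kT > 0 else 0.0

    g0 = model.grad(init)
    if model.kT > 0:
        du = np.abs((g0 * mobility * dt * g0).sum(axis=1))
        if np.any(du > model.kT):
            warnings.warn(
                "potential changes by more than kT in one step at some starting "
                "points; consider a smaller timestep",
                RuntimeWarning,
            )

    n_saved = n_steps // model.save_interval + 1
    out = np.empty((n_traj, n_saved, init.shape[1]))
    out[:, 0] = init
    x = init.copy()
    isave = 1
    for step in range(1, n_steps + 1):
        f = model.grad(x)
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(f"non-finite force at integration step {step}")
        x = x - f * mobility * dt
        if noise_amp:
            x = x + noise_amp * rng.standard_normal(x.shape)
        if step % model.save_interval == 0:
            out[:, isave] = x
            isave += 1
    return ShortTrajectoryEnsemble(
        trajectories=[out[k] for k in range(n_traj)],
        save_interval=dt * model.save_interval,
        start_distribution_tag="langevin-init",
        seed=seed,
    )


# --------------------------------------------------------------------------
# voltage-sensor surrogate
# --------------------------------------------------------------------------


@dataclass
class SurrogateVSDModel:
    """Five-basin surrogate of a voltage-sensing domain transition.

    The slow space is a (translocation-like, rotation-like) plane carrying
    ``n_basins`` metastable basins along a bent path: rotation relaxes
    first, translocation follows, mimicking the loose coupling of the two
    helix degrees of freedom.  ``feature_map`` produces distance-like
    observables (some monotone along the path, at least one V-shaped, as a
    side chain passing through a hydrophobic plug would produce), and
    ``charge_map`` produces a near-discrete displacement-charge-like
    observable whose two levels differ by ``charge_gap``.
    """

    basin_centers: np.ndarray          # (n_basins, 2) in (d [A], theta [deg])
    basin_depths: np.ndarray           # kT units
    basin_widths: tuple[float, float]  # (sigma_d [A], sigma_theta [deg])
    n_features: int
    noise_scale: float
    charge_base: float                 # e, level in the first (down) basin
    charge_gap: float                  # e, difference up - down
    charge_switch: float               # path progress where the click occurs
    charge_width: float                # smoothness of the click
    confinement: float                 # kT per unit squared scaled distance
    seed: int
    theta_scale: float = 12.0          # deg of rotation equivalent to 1 A

    _coeffs: np.ndarray = field(init=False, repr=False)
    _centers_s: np.ndarray = field(init=False, repr=False)
    _shapes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.basin_centers = np.asarray(self.basin_centers, dtype=float)
        self.basin_depths = np.asarray(self.basin_depths, dtype=float)
        rng = np.random.default_rng(self.seed)
        n = self.n_features
        # feature construction parameters, fixed at build time
        self._coeffs = rng.uniform(0.5, 2.0, size=(n, 2)) * rng.choice([-1, 1], size=(n, 2))
        self._centers_s = rng.uniform(0.25, 0.75, size=n)
        # feature shape: 0 = monotone in path progress, 1 = V-shaped
        shapes = np.zeros(n, dtype=int)
        n_v = max(1, n // 4)
        shapes[rng.choice(n, size=n_v, replace=False)] = 1
        self._shapes = shapes

    # -- geometry of the bent path -------------------------------------

    @property
    def n_basins(self) -> int:
        return len(self.basin_centers)

    def _scaled(self, coords: np.ndarray) -> np.ndarray:
        """Map (d, theta) to isotropic units (theta compressed)."""
        out = np.array(coords, dtype=float)
        out[..., 1] = out[..., 1] / self.theta_scale
        return out

    def path_progress(self, coords: np.ndarray) -> np.ndarray:
        """Progress s in [0, 1] along the piecewise-linear basin path,
        from projection onto the nearest segment."""
        coords = np.atleast_2d(coords)
        pts = self._scaled(coords)
        nodes = self._scaled(self.basin_centers)
        seg_len = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
        cum = np.concatenate([[0], np.cumsum(seg_len)])
        total = cum[-1]
        best_s = np.zeros(len(pts))
        best_d = np.full(len(pts), np.inf)
        for k in range(len(nodes) - 1):
            a, b = nodes[k], nodes[k + 1]
            ab = b - a
            t = np.clip(((pts - a) @ ab) / (ab @ ab), 0.0, 1.0)
            proj = a + t[:, None] * ab
            dist = np.linalg.norm(pts - proj, axis=1)
            better = dist < best_d
            best_d[better] = dist[better]
            best_s[better] = (cum[k] + t[better] * seg_len[k]) / total
        return best_s

    def path_distance(self, coords: np.ndarray) -> np.ndarray:
        """Scaled orthogonal distance to the basin path."""
        coords = np.atleast_2d(coords)
        pts = self._scaled(coords)
        nodes = self._scaled(self.basin_centers)
        best = np.full(len(pts), np.inf)
        for k in range(len(nodes) - 1):
            a, b = nodes[k], nodes[k + 1]
            ab = b - a
            t = np.clip(((pts - a) @ ab) / (ab @ ab), 0.0, 1.0)
            proj = a + t[:, None] * ab
            best = np.minimum(best, np.linalg.norm(pts - proj, axis=1))
        return best

    # -- energetics ----------------------------------------------------

    def slow_potential(self, coords: np.ndarray) -> np.ndarray:
        """Energy (kT units) of the slow (d, theta) coordinates."""
        coords = np.atleast_2d(coords)
        pts = self._scaled(coords)
        sd = self.basin_widths[0]
        st = self.basin_widths[1] / self.theta_scale
        U = np.zeros(len(pts))
        for c, depth in zip(self._scaled(self.basin_centers), self.basin_depths):
            r2 = ((pts[:, 0] - c[0]) / sd) ** 2 + ((pts[:, 1] - c[1]) / st) ** 2
            U -= depth * np.exp(-0.5 * r2)
        U += self.confinement * self.path_distance(coords) ** 2
        return U

    # -- observables ---------------------------------------------------

    def feature_map(self, coords: np.ndarray, seed: int | None = None) -> np.ndarray:
        """Distance-like features of the slow coordinates plus noise.

        Deterministic given ``seed``; with ``seed=None`` the features are
        noiseless.  Monotone features follow the path progress; V-shaped
        ones dip and recover around a feature-specific switch point.
        """
        coords = np.atleast_2d(coords)
        s = self.path_progress(coords)
        n = self.n_features
        base = np.empty((len(coords), n))
        for i in range(n):
            a, b = self._coeffs[i]
            if self._shapes[i] == 0:
                base[:, i] = 8.0 + 4.0 * a * s + 0.3 * b * coords[:, 0]
            else:
                base[:, i] = 4.0 + 6.0 * np.abs(a) * np.abs(s - self._centers_s[i])
        if seed is not None and self.noise_scale > 0:
            rng = np.random.default_rng(seed)
            base = base + self.noise_scale * rng.standard_normal(base.shape)
        return base

    def charge_map(self, coords: np.ndarray) -> np.ndarray:
        """Displacement-charge-like observable: a smoothed two-level step
        ('click') in path progress."""
        s = self.path_progress(coords)
        z = (s - self.charge_switch) / self.charge_width
        return self.charge_base + self.charge_gap / (1.0 + np.exp(-z))

    @property
    def monotone_features(self) -> np.ndarray:
        return np.flatnonzero(self._shapes == 0)

    @property
    def nonmonotone_features(self) -> np.ndarray:
        return np.flatnonzero(self._shapes == 1)

    # -- simulation helpers --------------------------------------------

    def _path_point_scaled(self, s: np.ndarray) -> np.ndarray:
        """Point at fractional arclength s on the path, scaled coords."""
        nodes = self._scaled(self.basin_centers)
        seg_len = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
        cum = np.concatenate([[0], np.cumsum(seg_len)])
        arc = np.asarray(s, dtype=float) * cum[-1]
        k = np.clip(np.searchsorted(cum, arc, side="right") - 1, 0, len(seg_len) - 1)
        t = (arc - cum[k]) / seg_len[k]
        return nodes[k] + t[:, None] * (nodes[k + 1] - nodes[k])

    def unscale(self, y: np.ndarray) -> np.ndarray:
        """Map scaled coordinates back to (d [A], theta [deg])."""
        out = np.array(y, dtype=float)
        out[..., 1] = out[..., 1] * self.theta_scale
        return out

    def sample_starts(self, n: int, seed: int, jitter: float = 0.15) -> np.ndarray:
        """Non-equilibrium start points: uniform along the basin path with
        Gaussian jitter, in scaled coordinates (mimics seeding spread
        between the end states rather than Boltzmann sampling)."""
        rng = np.random.default_rng(seed)
        s = rng.uniform(0.0, 1.0, n)
        pts = self._path_point_scaled(s)
        return pts + jitter * rng.standard_normal(pts.shape)

    def simulate(
        self,
        n_traj: int,
        n_frames: int,
        seed: int,
        kT: float = 1.0,
        timestep: float = 2e-4,
        save_interval: int = 25,
        start_jitter: float = 0.15,
    ) -> ShortTrajectoryEnsemble:
        """Generate short Langevin trajectories of the slow coordinates.

        Dynamics run in scaled coordinates (rotation compressed by
        ``theta_scale``) with isotropic unit diffusion; frames are returned
        as (d, theta) pairs.  ``n_frames`` counts saved frames including
        the start.
        """
        def scaled_potential(y: np.ndarray) -> np.ndarray:
            return kT * self.slow_potential(self.unscale(y))

        lm = LangevinModel(
            potential=scaled_potential,
            kT=kT,
            diffusion_coefficient=1.0,
            timestep=timestep,
            save_interval=save_interval,
            grad_eps=1e-4,
        )
        starts = self.sample_starts(n_traj, seed=seed + 1, jitter=start_jitter)
        ens = simulate_langevin(lm, n_traj, (n_frames - 1) * save_interval,
                                starts, seed=seed)
        ens = ens.map_frames(self.unscale)
        ens.start_distribution_tag = "uniform-path-jitter"
        return ens


def make_vsd_surrogate(
    n_basins: int = 5,
    n_features: int = 20,
    seed: int = 0,
    noise_scale: float = 0.25,
    charge_gap: float = 0.9,
    kT_depth_interior: float = 2.3,
    kT_depth_end: float = 3.3,
) -> SurrogateVSDModel:
    """Build the default five-basin voltage-sensor surrogate.

    Basins are laid along a bent path in the (translocation, rotation)
    plane: the first leg changes rotation at nearly fixed translocation,
    the second leg translocates at nearly fixed rotation.  End basins are
    deepest; the charge observable clicks between two levels separated by
    ``charge_gap`` (default 0.9 e, placing the end levels at -4.2 e and
    -3.3 e as for the down and up states of the Ci-VSD sensor).
    """
    if n_basins < 3:
        raise ValueError("need at least 3 basins")
    # bent path from the down-state-like corner to the up-state-like corner:
    # first leg mostly rotation, second leg mostly translocation
    theta_scale = 12.0
    down = np.array([-4.2, -57.0])
    bend = np.array([-3.9, -6.0])
    up = np.array([-0.5, 4.0])

    def scale(p):
        return np.array([p[0], p[1] / theta_scale])

    leg1 = np.linalg.norm(scale(bend) - scale(down))
    leg2 = np.linalg.norm(scale(up) - scale(bend))
    total = leg1 + leg2
    if n_basins == 5:
        # arc fractions calibrated once against the exact (fine-grid linear
        # solve) committor of this landscape so the three interior basins sit
        # at q+ of 0.25, 0.50 and 0.75 between the two printed state ellipses
        fracs = np.array([0.0, 0.2557, 0.4786, 0.7331, 1.0])
        arcs = fracs * total
    else:
        # uncalibrated rule: equal diffusive resistance per gap, with the end
        # gaps shortened by the absorbing state-ellipse radius along the
        # approach direction
        r_down = 8.0 / theta_scale
        r_up = 0.84
        step = (total - r_down - r_up) / (n_basins - 1)
        arcs = np.concatenate([[0.0],
                               r_down + step * np.arange(1, n_basins - 1),
                               [total]])
    centers = np.empty((n_basins, 2))
    for i, a in enumerate(arcs):
        if a <= leg1:
            p = scale(down) + (scale(bend) - scale(down)) * (a / leg1)
        else:
            p = scale(bend) + (scale(up) - scale(bend)) * ((a - leg1) / leg2)
        centers[i] = [p[0], p[1] * theta_scale]
    depths = np.full(n_basins, kT_depth_interior)
    depths[0] = depths[-1] = kT_depth_end
    # the charge click sits on the barrier between the two basins flanking
    # 60% of the path, expressed in the basin-polyline parameterization
    sc_centers = centers.copy()
    sc_centers[:, 1] /= theta_scale
    seg = np.linalg.norm(np.diff(sc_centers, axis=0), axis=1)
    s_basins = np.concatenate([[0.0], np.cumsum(seg)]) / seg.sum()
    switch = 0.5 * (s_basins[n_basins // 2] + s_basins[n_basins // 2 + 1])
    return SurrogateVSDModel(
        basin_centers=centers,
        basin_depths=depths,
        basin_widths=(0.35, 0.35 * theta_scale),
        n_features=n_features,
        noise_scale=noise_scale,
        charge_base=-4.2,
        charge_gap=charge_gap,
        charge_switch=switch,
        charge_width=0.03,
        confinement=2.0,
        seed=seed,
        theta_scale=theta_scale,
    )


def count_grid_minima(
    potential: Callable[[np.ndarray], np.ndarray],
    xlim: tuple[float, float],
    ylim: tuple[float, float],
    n: int = 200,
) -> int:
    """Count strict local minima of a 2D potential on an n-by-n grid
    (8-neighbour stencil, grid boundary excluded)."""
    x = np.linspace(*xlim, n)
    y = np.linspace(*ylim, n)
    X, Y = np.meshgrid(x, y, indexing="ij")
    U = potential(np.column_stack([X.ravel(), Y.ravel()])).reshape(n, n)
    inner = U[1:-1, 1:-1]
    is_min = np.ones_like(inner, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            is_min &= inner < U[1 + di : n - 1 + di, 1 + dj : n - 1 + dj]
    return int(is_min.sum())


# --------------------------------------------------------------------------
# exact oracles (direct linear solves)
# --------------------------------------------------------------------------


def _as_index_set(states: Sequence[int], n: int, name: str) -> np.ndarray:
    idx = np.asarray(sorted(set(int(s) for s in states)), dtype=int)
    if idx.size == 0:
        raise ValueError(f"state set {name} is empty")
    if idx.min() < 0 or idx.max() >= n:
        raise ValueError(f"state set {name} out of range for {n} states")
    return idx


def exact_committor(model: MarkovChainModel, A: Sequence[int], B: Sequence[int]) -> np.ndarray:
    """Forward committor q+ of the chain by direct linear solve.

    q+ = 0 on A, 1 on B; on interior states it solves
    ``(I - P_CC) q_C = P_CB 1``.
    """
    n = model.n_states
    iA = _as_index_set(A, n, "A")
    iB = _as_index_set(B, n, "B")
    if np.intersect1d(iA, iB).size:
        raise ValueError("A and B must be disjoint")
    P = model.transition_matrix
    q = np.zeros(n)
    q[iB] = 1.0
    interior = np.setdiff1d(np.arange(n), np.concatenate([iA, iB]))
    if interior.size:
        M = np.eye(interior.size) - P[np.ix_(interior, interior)]
        b = P[np.ix_(interior, iB)].sum(axis=1)
        try:
            q[interior] = np.linalg.solve(M, b)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular committor system: some interior states cannot reach A or B"
            ) from err
    return q


def exact_stationary(model: MarkovChainModel) -> np.ndarray:
    """Stationary distribution: the left Perron eigenvector of P."""
    P = model.transition_matrix
    vals, vecs = np.linalg.eig(P.T)
    k = np.argmin(np.abs(vals - 1.0))
    if abs(vals[k] - 1.0) > 1e-8:
        raise ValueError("no unit eigenvalue: matrix is not stochastic?")
    pi = np.real(vecs[:, k])
    pi = pi / pi.sum()
    if np.any(pi <= 0):
        # a zero/negative entry signals reducibility (or a numerically
        # defective eigenvector)
        raise ValueError("chain appears reducible: stationary vector not strictly positive")
    return pi


def exact_mfpt(model: MarkovChainModel, B: Sequence[int]) -> np.ndarray:
    """Mean first-passage time to B (lag-time units) by linear solve:
    m = 0 on B, ``(I - P_CC) m_C = 1`` elsewhere."""
    n = model.n_states
    iB = _as_index_set(B, n, "B")
    interior = np.setdiff1d(np.arange(n), iB)
    m = np.zeros(n)
    if interior.size:
        M = np.eye(interior.size) - model.transition_matrix[np.ix_(interior, interior)]
        try:
            m[interior] = np.linalg.solve(M, np.ones(interior.size))
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError("B is unreachable from some states") from err
        if np.any(m[interior] < 0):
            raise ValueError("negative MFPT: B unreachable from some states")
    return m


@dataclass
class TPTResult:
    """Exact transition-path-theory decomposition of a chain."""

    rate: float                    # reactive flux per lag time
    net_current: np.ndarray        # (n, n) antisymmetric net edge current
    current: np.ndarray            # (n, n) one-way reactive current
    q_plus: np.ndarray
    q_minus: np.ndarray
    pi: np.ndarray

    def cut_flux(self, left: Sequence[int]) -> float:
        """Net reactive flux through the cut (left -> complement)."""
        n = len(self.pi)
        iL = _as_index_set(left, n, "left")
        iR = np.setdiff1d(np.arange(n), iL)
        return float(self.net_current[np.ix_(iL, iR)].sum())


def exact_tpt(model: MarkovChainModel, A: Sequence[int], B: Sequence[int]) -> TPTResult:
    """Reactive rate and per-edge reactive currents of the stationary chain.

    One-way current ``f_ij = pi_i q-_i P_ij q+_j`` with the backward
    committor taken from the time-reversed chain; the net current is
    ``f_ij - f_ji`` clipped at zero for reporting edge direction.
    """
    P = model.transition_matrix
    n = model.n_states
    pi = exact_stationary(model)
    q_plus = exact_committor(model, A, B)
    # time-reversed chain: Pt_ij = pi_j P_ji / pi_i
    Pt = P.T * pi[None, :] / pi[:, None]
    Pt = Pt / Pt.sum(axis=1, keepdims=True)
    q_minus = exact_committor(MarkovChainModel(Pt), B, A)  # reach A before B, reversed
    f = pi[:, None] * q_minus[:, None] * P * q_plus[None, :]
    np.fill_diagonal(f, 0.0)
    net = f - f.T
    iA = _as_index_set(A, n, "A")
    rate = float(np.maximum(net[iA, :], 0.0).sum())
    return TPTResult(rate=rate, net_current=net, current=f,
                     q_plus=q_plus, q_minus=q_minus, pi=pi)


# --------------------------------------------------------------------------
# convenience chains used throughout the tests
# --------------------------------------------------------------------------


def random_walk_chain(n: int, p_up: float = 0.5, reflecting: bool = True) -> MarkovChainModel:
    """Birth-death chain on {0..n-1}: step up with probability ``p_up``,
    down with ``1-p_up``; ends reflect (or self-loop) as configured."""
    P = np.zeros((n, n))
    for i in range(n):
        if i == 0:
            if reflecting:
                P[0, 1] = 1.0  # hard bounce, so m(0) = N^2 for the symmetric walk
            else:
                P[0, 0] = 1.0
        elif i == n - 1:
            if reflecting:
                P[i, i - 1] = 1.0
            else:
                P[i, i] = 1.0
        else:
            P[i, i + 1] = p_up
            P[i, i - 1] = 1 - p_up
    labels = np.arange(n, dtype=float)[:, None]
    return MarkovChainModel(P, state_labels=labels)


def random_irreducible_chain(n: int, seed: int, sparsity: float = 0.5) -> MarkovChainModel:
    """Random dense-enough irreducible chain for oracle comparisons."""
    rng = np.random.default_rng(seed)
    W = rng.random((n, n)) * (rng.random((n, n)) < sparsity)
    # guarantee irreducibility with a weak ring
    for i in range(n):
        W[i, (i + 1) % n] += 0.05
        W[i, i] += 0.05
    P = W / W.sum(axis=1, keepdims=True)
    return MarkovChainModel(P)


def random_reversible_chain(n: int, seed: int) -> MarkovChainModel:
    """Random reversible chain built from a symmetric weight matrix."""
    rng = np.random.default_rng(seed)
    S = rng.random((n, n))
    S = S + S.T + 0.1
    P = S / S.sum(axis=1, keepdims=True)
    return MarkovChainModel(P)
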