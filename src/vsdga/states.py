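"""Reactant/product state definitions, stopped-process bookkeeping, and
basis-set construction for committor and weight estimation.

Two basis families are provided, mirroring common practice for
short-trajectory estimators of conformational kinetics:

* a *distance basis* for the committor, built from feature vectors scaled
  by a boundary-vanishing factor h = dA*dB/(dA+dB)^2 so every basis
  function is exactly zero on the reactant and product states, then
  whitened by SVD;
* an *indicator basis* (one-hot cluster membership, i.e. a Markov state
  model) for equilibrium weights, built by clustering a low-dimensional
  projection of the features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans, MiniBatchKMeans
from sklearn.neighbors import NearestNeighbors

from .synthetic import ShortTrajectoryEnsemble

__all__ = [
    "LABEL_NONE",
    "LABEL_A",
    "LABEL_B",
    "StateDefinition",
    "StoppedEnsemble",
    "BasisSet",
    "assign_states",
    "stop_times",
    "ellipse_boundary_distances",
    "build_distance_basis",
    "build_indicator_basis",
    "indicator_basis_from_states",
]

LABEL_NONE = 0
LABEL_A = 1
LABEL_B = 2


def _wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap angles (degrees) into (-180, 180]."""
    return -((-np.asarray(theta, dtype=float) + 180.0) % 360.0 - 180.0)


@dataclass
class StateDefinition:
    """Metastable state as an ellipse in the (translocation d, rotation
    theta) plane, optionally intersected with per-feature cutoffs.

    The membership test is ``((d-d0)/rd)^2 + (wrap(theta-theta0)/rt)^2 < 1``
    with the angular difference wrapped into (-180, 180], plus every
    configured ``(feature_name, lo, hi)`` interval.
    """

    center: tuple[float, float]     # (d0 [A], theta0 [deg])
    radii: tuple[float, float]      # (rd [A], rt [deg])
    distance_cutoffs: list[tuple[str, float, float]] | None = None

    def __post_init__(self) -> None:
        if self.radii[0] <= 0 or self.radii[1] <= 0:
            raise ValueError("ellipse radii must be positive")

    def ellipse_value(self, d: np.ndarray, theta: np.ndarray) -> np.ndarray:
        dd = (np.asarray(d, dtype=float) - self.center[0]) / self.radii[0]
        dt = _wrap_angle(np.asarray(theta) - self.center[1]) / self.radii[1]
        return dd**2 + dt**2

    def contains(
        self,
        d: np.ndarray,
        theta: np.ndarray,
        features: "dict[str, np.ndarray] | None" = None,
    ) -> np.ndarray:
        inside = self.ellipse_value(d, theta) < 1.0
        for name, lo, hi in self.distance_cutoffs or []:
            if features is None or name not in features:
                raise KeyError(f"state cutoff refers to unknown feature {name!r}")
            x = np.asarray(features[name], dtype=float)
            inside &= (x >= lo) & (x <= hi)
        return inside


def _ellipses_overlap(a: StateDefinition, b: StateDefinition, n: int = 256) -> bool:
    """Numerical overlap test: sample ellipse `a` (boundary + interior rings)
    and check membership in `b`."""
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    for r in (1.0, 0.75, 0.5, 0.25, 0.0):
        d = a.center[0] + r * a.radii[0] * np.cos(phi)
        t = a.center[1] + r * a.radii[1] * np.sin(phi)
        if np.any(b.ellipse_value(d, t) < 1.0):
            return True
    return False


def assign_states(
    cv_table: np.ndarray,
    state_A: StateDefinition,
    state_B: StateDefinition,
    features: "dict[str, np.ndarray] | None" = None,
) -> np.ndarray:
    """Label frames as reactant (A), product (B) or neither.

    ``cv_table`` holds per-frame (d, theta) in its first two columns.
    Raises if the two ellipse definitions overlap.
    """
    if _ellipses_overlap(state_A, state_B) or _ellipses_overlap(state_B, state_A):
        raise ValueError("state definitions overlap in (d, theta) space")
    cv = np.atleast_2d(np.asarray(cv_table, dtype=float))
    d, theta = cv[:, 0], cv[:, 1]
    labels = np.full(len(cv), LABEL_NONE, dtype=np.int8)
    labels[state_A.contains(d, theta, features)] = LABEL_A
    labels[state_B.contains(d, theta, features)] = LABEL_B
    return labels


@dataclass
class StoppedEnsemble:
    """Per-start-frame bookkeeping of the process stopped on A u B.

    All indices are into the stacked frame array of the ensemble.  A start
    frame t is *valid* when t + lag stays inside its trajectory; its stop
    index is t itself if the frame is already in A u B, otherwise the first
    later in-state frame, capped at t + lag.
    """

    start_index: np.ndarray     # (n_pairs,) valid start frames
    stop_index: np.ndarray      # (n_pairs,) stopped end frames
    labels: np.ndarray          # (n_frames,) per-frame state labels
    lag: int
    n_excluded: int             # starts dropped because t + lag left the trajectory

    @property
    def n_pairs(self) -> int:
        return len(self.start_index)

    @property
    def elapsed(self) -> np.ndarray:
        """Stopped elapsed time per pair, in frames."""
        return self.stop_index - self.start_index


def stop_times(
    ensemble: ShortTrajectoryEnsemble,
    labels: np.ndarray,
    lag: int,
    stop_on: tuple[int, ...] = (LABEL_A, LABEL_B),
    boundary_starts: str = "stop",
) -> StoppedEnsemble:
    """Compute first-entry stop indices for every valid start frame.

    ``stop_on`` selects which labels terminate the process (both states for
    committor estimation, product only for first-passage times).
    ``boundary_starts`` controls frames that start inside a stopping state:
    ``"stop"`` freezes them at their own index (the committor convention),
    while ``"evolve"`` lets them run until the first entry *after* the
    start, as required by flux estimators that must count transitions
    leaving the reactant state.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    labels = np.asarray(labels)
    if len(labels) != ensemble.n_frames:
        raise ValueError("labels length must equal total frame count")
    offsets = ensemble.offsets
    starts, stops = [], []
    n_excluded = 0
    in_state = np.isin(labels, stop_on)
    for k in range(ensemble.n_traj):
        lo, hi = offsets[k], offsets[k + 1]
        length = hi - lo
        if lag >= length:
            n_excluded += length
            continue
        loc = in_state[lo:hi]
        # next_entry[t]: first index s >= t with loc[s], else length
        next_entry = np.full(length + 1, length, dtype=np.int64)
        for t in range(length - 1, -1, -1):
            next_entry[t] = t if loc[t] else next_entry[t + 1]
        t_idx = np.arange(length - lag)
        first_after = next_entry[1:length - lag + 1]  # first entry at s > t
        stop_rel = np.minimum(t_idx + lag, first_after)
        if boundary_starts == "stop":
            stop_rel = np.where(loc[t_idx], t_idx, stop_rel)
        elif boundary_starts != "evolve":
            raise ValueError("boundary_starts must be 'stop' or 'evolve'")
        starts.append(t_idx + lo)
        stops.append(stop_rel + lo)
        n_excluded += lag  # the last `lag` frames of each trajectory
    if not starts:
        raise ValueError("lag exceeds every trajectory length; no valid start frames")
    return StoppedEnsemble(
        start_index=np.concatenate(starts),
        stop_index=np.concatenate(stops),
        labels=labels,
        lag=lag,
        n_excluded=n_excluded,
    )


@dataclass
class BasisSet:
    """Per-frame basis function values plus boundary bookkeeping.

    For committor-type bases every column is exactly zero on A u B frames
    and ``guess`` is exactly 0 on A and 1 on B.  Indicator bases are
    one-hot cluster memberships (a Markov state model).
    """

    values: np.ndarray                      # (n_frames, N)
    guess: np.ndarray                       # (n_frames,)
    kind: str                               # "distance" | "indicator"
    d_A: np.ndarray | None = None
    d_B: np.ndarray | None = None
    h: np.ndarray | None = None
    whitening_transform: np.ndarray | None = None
    cluster_labels: np.ndarray | None = None
    n_dropped_columns: int = 0

    @property
    def n_basis(self) -> int:
        return self.values.shape[1]

    def with_boundary(self, labels: np.ndarray,
                      stop_on: tuple[int, ...] = (LABEL_A, LABEL_B)) -> "BasisSet":
        """Return a committor-ready copy: rows on the stopping states
        zeroed, guess set to the product-state indicator."""
        boundary = np.isin(labels, stop_on)
        if hasattr(self.values, "toarray"):  # scipy sparse
            import scipy.sparse as sp

            keep = sp.diags((~boundary).astype(float))
            values = (keep @ self.values).tocsc()
            live = np.flatnonzero(np.ravel(np.abs(values).sum(axis=0)) > 0)
            values = values[:, live].tocsr()
        else:
            values = self.values.copy()
            values[boundary] = 0.0
            live = np.flatnonzero(np.abs(values).sum(axis=0) > 0)
            values = values[:, live]
        guess = (np.asarray(labels) == LABEL_B).astype(float)
        return BasisSet(
            values=values,
            guess=guess,
            kind=self.kind,
            d_A=self.d_A,
            d_B=self.d_B,
            h=self.h,
            whitening_transform=self.whitening_transform,
            cluster_labels=self.cluster_labels,
            n_dropped_columns=self.n_dropped_columns,
        )


def ellipse_boundary_distances(
    cv_table: np.ndarray,
    state_A: StateDefinition,
    state_B: StateDefinition,
) -> tuple[np.ndarray, np.ndarray]:
    """Distances to the state boundaries measured in ellipse-scaled units:
    ``max(0, sqrt(ellipse_value) - 1)``, exactly zero inside each state.

    A cheap, smooth alternative to nearest-labeled-frame distances for
    large datasets; pass the result to :func:`build_distance_basis`.
    """
    cv = np.atleast_2d(np.asarray(cv_table, dtype=float))
    d, theta = cv[:, 0], cv[:, 1]
    dA = np.maximum(0.0, np.sqrt(state_A.ellipse_value(d, theta)) - 1.0)
    dB = np.maximum(0.0, np.sqrt(state_B.ellipse_value(d, theta)) - 1.0)
    return dA, dB


def build_distance_basis(
    features: np.ndarray,
    labels: np.ndarray,
    whiten_tol: float = 1e-8,
    standardize: bool = True,
    d_A: np.ndarray | None = None,
    d_B: np.ndarray | None = None,
) -> BasisSet:
    """Boundary-conforming distance basis for the committor.

    For each frame, dA (dB) is the Euclidean distance in standardized
    feature space to the nearest A-labeled (B-labeled) frame.  The
    boundary factor ``h = dA*dB/(dA+dB)^2`` vanishes on A u B by
    construction; basis functions are ``phi_i = x_i * h`` and the guess is
    ``gamma = dA^2/(dA^2+dB^2)``.  Columns are SVD-whitened so the
    dataset Gram matrix is the identity; columns with singular value below
    ``whiten_tol`` times the largest are dropped.

    Precomputed boundary distances (e.g. from
    :func:`ellipse_boundary_distances`) may be passed via ``d_A``/``d_B``;
    otherwise nearest-labeled-frame distances are used.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be 2D (frames x p)")
    maskA = labels == LABEL_A
    maskB = labels == LABEL_B
    if not maskA.any() or not maskB.any():
        raise ValueError("need at least one frame labeled A and one labeled B")

    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
    else:
        Z = X

    if d_A is None or d_B is None:
        nnA = NearestNeighbors(n_neighbors=1).fit(Z[maskA])
        nnB = NearestNeighbors(n_neighbors=1).fit(Z[maskB])
        d_A = nnA.kneighbors(Z, return_distance=True)[0][:, 0]
        d_B = nnB.kneighbors(Z, return_distance=True)[0][:, 0]
    else:
        d_A = np.asarray(d_A, dtype=float).copy()
        d_B = np.asarray(d_B, dtype=float).copy()
    # exact zeros on labeled frames (nearest neighbour of a member is itself)
    d_A[maskA] = 0.0
    d_B[maskB] = 0.0

    denom = d_A + d_B
    safe = denom > 0
    h = np.zeros(len(Z))
    h[safe] = d_A[safe] * d_B[safe] / denom[safe] ** 2
    gsq = d_A**2 + d_B**2
    guess = np.zeros(len(Z))
    nz = gsq > 0
    guess[nz] = d_A[nz] ** 2 / gsq[nz]
    guess[maskA] = 0.0
    guess[maskB] = 1.0
    h[maskA | maskB] = 0.0

    phi = Z * h[:, None]
    # SVD whitening: columns orthonormal under the empirical inner product
    U, s, Vt = np.linalg.svd(phi, full_matrices=False)
    keep = s > whiten_tol * s[0]
    n_dropped = int((~keep).sum())
    W = Vt[keep].T / s[keep] * np.sqrt(len(Z))
    values = phi @ W
    return BasisSet(
        values=values,
        guess=guess,
        kind="distance",
        d_A=d_A,
        d_B=d_B,
        h=h,
        whitening_transform=W,
        n_dropped_columns=n_dropped,
    )


def build_indicator_basis(
    features: np.ndarray,
    k: int = 200,
    seed: int = 0,
    ivac_dims: int | None = 10,
    ensemble: ShortTrajectoryEnsemble | None = None,
    ivac_lags: tuple[int, int] = (1, 5),
    mini_batch: bool = False,
    n_restarts: int = 10,
    sparse: bool = False,
) -> BasisSet:
    """Cluster-indicator (Markov state model) basis.

    Features are optionally reduced to ``ivac_dims`` slow coordinates with
    the lag-integrated variational approach (requires the generating
    ensemble for time-lagged pairs), then clustered with k-means; each
    cluster becomes a one-hot basis function.  Empty clusters trigger one
    reseeded retry before raising.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k > len(X):
        raise ValueError(f"k={k} exceeds number of frames {len(X)}")
    if ivac_dims is not None and ivac_dims < X.shape[1] and ensemble is not None:
        from .interpret import fit_ivac

        model = fit_ivac(ensemble, X, min_lag=ivac_lags[0], max_lag=ivac_lags[1],
                         n_dims=ivac_dims)
        X = model.transform(X)

    for attempt in range(2):
        rs = seed + attempt
        if mini_batch:
            km = MiniBatchKMeans(n_clusters=k, random_state=rs, n_init=n_restarts)
        else:
            km = KMeans(n_clusters=k, random_state=rs, n_init=n_restarts)
        assign = km.fit_predict(X)
        counts = np.bincount(assign, minlength=k)
        if np.all(counts > 0):
            break
        warnings.warn(f"empty cluster on attempt {attempt}; reseeding", RuntimeWarning)
    else:
        raise RuntimeError("k-means produced empty clusters on both attempts")

    values = _one_hot(assign, k, sparse=sparse)
    return BasisSet(
        values=values,
        guess=np.zeros(len(X)),
        kind="indicator",
        cluster_labels=assign,
    )


def _one_hot(assign: np.ndarray, k: int, sparse: bool = False):
    n = len(assign)
    if sparse:
        import scipy.sparse as sp

        return sp.csr_matrix(
            (np.ones(n), (np.arange(n), assign)), shape=(n, k)
        )
    values = np.zeros((n, k))
    values[np.arange(n), assign] = 1.0
    return values


def indicator_basis_from_states(state_indices: np.ndarray, n_states: int) -> BasisSet:
    """One-hot basis directly from discrete state indices (for chain data,
    where clustering is unnecessary)."""
    idx = np.asarray(state_indices, dtype=int).ravel()
    values = np.zeros((len(idx), n_states))
    values[np.arange(len(idx)), idx] = 1.0
    return BasisSet(values=values, guess=np.zeros(len(idx)), kind="indicator",
                    cluster_labels=idx)
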