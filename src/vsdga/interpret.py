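"""Sparse, interpretable committor models and slow-mode validation.

The committor is modeled with L1-penalized linear regression (LASSO) on a
small set of physically meaningful collective variables.  Because the
committor can depend non-monotonically on individual variables, the data
are split at the transition state (q+ = 0.5) into two branches and an
inverse-sigmoid transform maps each branch onto the real line, so the
back-transformed predictions stay in (0, 0.5) or (0.5, 1).

The integrated variational approach (lag-integrated time-lagged covariance
eigenproblem) provides slow collective modes, used both to reduce features
before clustering and to validate that the chosen variable subset captures
the transition (the committor should be monotone along the first
nontrivial mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.stats
from sklearn.linear_model import Lasso

from .synthetic import ShortTrajectoryEnsemble

__all__ = [
    "SparseCommittorModel",
    "IVACModel",
    "sample_transition_points",
    "transform_committor",
    "inverse_transform_committor",
    "fit_lasso",
    "lasso_path_supports",
    "fit_ivac",
    "validate_subspace",
]


# --------------------------------------------------------------------------
# transition-region sampling and branch transforms
# --------------------------------------------------------------------------


def sample_transition_points(
    q_plus: np.ndarray,
    weights: np.ndarray,
    n: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Sample frame indices with replacement, probability proportional to
    ``w * q+ * (1 - q+)`` (peaked at the transition state; boundary frames
    are never drawn)."""
    q = np.asarray(q_plus, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q_plus must be clipped to [0, 1] before sampling")
    w = np.asarray(weights, dtype=float)
    p = w * q * (1.0 - q)
    total = p.sum()
    if total <= 0:
        raise ValueError("all sampling probabilities are zero")
    rng = np.random.default_rng(seed)
    return rng.choice(len(q), size=n, replace=True, p=p / total)


def transform_committor(q_plus: np.ndarray, branch: str) -> np.ndarray:
    """Inverse-sigmoid branch transform of the committor onto the real line.

    lower branch (q+ in (0, 0.5)):  ln[2 q+ / (1 - 2 q+)]
    upper branch (q+ in (0.5, 1)):  ln[(2 q+ - 1) / (2 - 2 q+)]

    Values at or outside the branch endpoints map to NaN (to be excluded,
    with the caller reporting the count).  The two branches are mirror
    images: lower(q) == -upper(1 - q).
    """
    q = np.asarray(q_plus, dtype=float)
    out = np.full(q.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        if branch == "lower":
            ok = (q > 0) & (q < 0.5)
            out[ok] = np.log(2 * q[ok] / (1 - 2 * q[ok]))
        elif branch == "upper":
            ok = (q > 0.5) & (q < 1)
            out[ok] = np.log((2 * q[ok] - 1) / (2 - 2 * q[ok]))
        else:
            raise ValueError("branch must be 'lower' or 'upper'")
    return out


def inverse_transform_committor(y: np.ndarray, branch: str) -> np.ndarray:
    """Exact inverse of :func:`transform_committor`; maps the real line
    back into (0, 0.5) or (0.5, 1)."""
    y = np.asarray(y, dtype=float)
    sig = 1.0 / (1.0 + np.exp(-y))
    if branch == "lower":
        return 0.5 * sig
    if branch == "upper":
        return 0.5 * (1.0 + sig)
    raise ValueError("branch must be 'lower' or 'upper'")


# --------------------------------------------------------------------------
# LASSO committor models
# --------------------------------------------------------------------------


@dataclass
class SparseCommittorModel:
    branch: str
    lam: float
    coefficients: np.ndarray       # on standardized features
    intercept: float
    feature_means: np.ndarray
    feature_scales: np.ndarray
    kept_features: np.ndarray      # indices surviving variance screening
    r_squared: float               # on the transformed (fitting) scale
    r_squared_committor: float     # on back-transformed committor values
    feature_names: list[str] | None = None

    @property
    def nonzero(self) -> np.ndarray:
        """Original-feature indices with nonzero coefficients."""
        return self.kept_features[np.abs(self.coefficients) > 1e-12]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict on the transformed scale."""
        X = np.asarray(X, dtype=float)[:, self.kept_features]
        Z = (X - self.feature_means) / self.feature_scales
        return Z @ self.coefficients + self.intercept

    def predict_committor(self, X: np.ndarray) -> np.ndarray:
        return inverse_transform_committor(self.predict(X), self.branch)


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def fit_lasso(
    features: np.ndarray,
    y_transformed: np.ndarray,
    lam: float,
    branch: str = "lower",
    q_true: np.ndarray | None = None,
    feature_names: list[str] | None = None,
    max_iter: int = 50_000,
) -> SparseCommittorModel:
    """L1-penalized fit of the transformed committor.

    The objective is ``sum_k (beta^T x_k - y_k)^2 + lam * ||beta||_1`` on
    features standardized to zero mean and unit variance; ``lam = 0``
    reduces to ordinary least squares.  Zero-variance features are dropped
    with a warning.  R^2 is reported on the fitting (transformed) scale and,
    when the untransformed committor values are supplied, on the committor
    scale after back-transformation.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(y_transformed, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be (n, p) matching y")
    if len(np.unique(X, axis=0)) < 2:
        raise ValueError("need at least 2 distinct feature rows")

    scales = X.std(axis=0)
    kept = np.flatnonzero(scales > 0)
    if kept.size < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - kept.size} zero-variance features",
            RuntimeWarning,
        )
    means = X[:, kept].mean(axis=0)
    sd = scales[kept]
    Z = (X[:, kept] - means) / sd

    n = len(y)
    if lam == 0:
        Zc = np.column_stack([Z, np.ones(n)])
        sol, *_ = np.linalg.lstsq(Zc, y, rcond=None)
        beta, intercept = sol[:-1], float(sol[-1])
    else:
        # sklearn minimizes (1/2n)||y - Xb||^2 + alpha ||b||_1
        model = Lasso(alpha=lam / (2 * n), fit_intercept=True, max_iter=max_iter)
        model.fit(Z, y)
        beta, intercept = model.coef_, float(model.intercept_)

    yhat = Z @ beta + intercept
    r2_t = _r2(y, yhat)
    if q_true is not None:
        qhat = inverse_transform_committor(yhat, branch)
        r2_q = _r2(np.asarray(q_true, dtype=float), qhat)
    else:
        r2_q = _r2(inverse_transform_committor(y, branch),
                   inverse_transform_committor(yhat, branch))
    return SparseCommittorModel(
        branch=branch, lam=float(lam), coefficients=beta, intercept=intercept,
        feature_means=means, feature_scales=sd, kept_features=kept,
        r_squared=r2_t, r_squared_committor=r2_q, feature_names=feature_names,
    )


def lasso_path_supports(
    features: np.ndarray,
    y_transformed: np.ndarray,
    lambdas: np.ndarray,
    branch: str = "lower",
) -> list[tuple[float, np.ndarray]]:
    """Nonzero-coefficient sets along a penalty path (descending sparsity)."""
    out = []
    for lam in lambdas:
        m = fit_lasso(features, y_transformed, lam, branch=branch)
        out.append((float(lam), m.nonzero))
    return out


# --------------------------------------------------------------------------
# IVAC slow modes
# --------------------------------------------------------------------------


@dataclass
class IVACModel:
    min_lag: int
    max_lag: int
    eigenvalues: np.ndarray        # descending, nontrivial modes only
    projections: np.ndarray        # (p_kept, n_dims) on centered kept features
    mean: np.ndarray
    kept_features: np.ndarray
    n_dims: int
    ridge: float = 1e-10

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.kept_features]
        return (X - self.mean) @ self.projections


def fit_ivac(
    ensemble: ShortTrajectoryEnsemble,
    features: np.ndarray,
    min_lag: int,
    max_lag: int,
    n_dims: int,
    ridge: float = 1e-10,
) -> IVACModel:
    """Lag-integrated variational estimate of slow collective modes.

    Solves the symmetric generalized eigenproblem of the integrated
    time-lagged covariance ``sum_{tau=min..max} C(tau)`` against ``C(0)``
    on mean-centered features.  Centering removes the trivial constant
    mode, so the reported eigenvalues/projections are the nontrivial ones;
    constant feature columns are dropped.  C(0) is ridge-regularized when
    needed and the forward/transpose-averaged (symmetrized) estimator is
    used so the spectrum is real.
    """
    if not (1 <= min_lag <= max_lag):
        raise ValueError("need 1 <= min_lag <= max_lag")
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) != ensemble.n_frames:
        raise ValueError("features must cover every ensemble frame")
    scales = X.std(axis=0)
    kept = np.flatnonzero(scales > 0)
    if kept.size == 0:
        raise ValueError("all features are constant")
    mean = X[:, kept].mean(axis=0)
    Z = X[:, kept] - mean
    p = Z.shape[1]

    offsets = ensemble.offsets
    C0 = np.zeros((p, p))
    n0 = 0
    Cint = np.zeros((p, p))
    for k in range(ensemble.n_traj):
        lo, hi = offsets[k], offsets[k + 1]
        Zk = Z[lo:hi]
        C0 += Zk.T @ Zk
        n0 += len(Zk)
    C0 /= n0
    for tau in range(min_lag, max_lag + 1):
        Ct = np.zeros((p, p))
        nt = 0
        for k in range(ensemble.n_traj):
            lo, hi = offsets[k], offsets[k + 1]
            if hi - lo <= tau:
                continue
            A = Z[lo : hi - tau]
            Bm = Z[lo + tau : hi]
            Ct += A.T @ Bm
            nt += len(A)
        if nt == 0:
            raise ValueError(f"no time-lagged pairs at lag {tau}")
        Cint += 0.5 * (Ct + Ct.T) / nt

    used_ridge = 0.0
    C0r = C0.copy()
    if np.linalg.cond(C0r) > 1e12:
        used_ridge = ridge * np.trace(C0) / p
        C0r += used_ridge * np.eye(p)
        warnings.warn(f"rank-deficient C(0): ridge {used_ridge:.2e} applied",
                      RuntimeWarning)
    vals, vecs = scipy.linalg.eigh(Cint, C0r)
    order = np.argsort(vals)[::-1]
    n_dims = min(n_dims, p)
    vals = vals[order][:n_dims]
    vecs = vecs[:, order][:, :n_dims]
    return IVACModel(min_lag=min_lag, max_lag=max_lag, eigenvalues=vals,
                     projections=vecs, mean=mean, kept_features=kept,
                     n_dims=n_dims, ridge=used_ridge)


def validate_subspace(
    model: IVACModel,
    features: np.ndarray,
    q_plus: np.ndarray,
    weights: np.ndarray | None = None,
    n_bins: int = 50,
) -> dict:
    """Check that the committor is monotone along the first nontrivial slow
    mode: bins frames by the first coordinate, reports the weighted mean
    committor per occupied bin and the Spearman correlation between bin
    index and mean committor."""
    coord = model.transform(features)[:, 0]
    q = np.asarray(q_plus, dtype=float)
    w = np.ones(len(q)) if weights is None else np.asarray(weights, dtype=float)
    edges = np.linspace(coord.min(), coord.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, coord, side="right") - 1, 0, n_bins - 1)
    num = np.bincount(idx, weights=w * q, minlength=n_bins)
    den = np.bincount(idx, weights=w, minlength=n_bins)
    occupied = den > 0
    mean_q = np.full(n_bins, np.nan)
    mean_q[occupied] = num[occupied] / den[occupied]
    rho = scipy.stats.spearmanr(np.flatnonzero(occupied), mean_q[occupied]).statistic
    return {
        "bin_mean_q": mean_q,
        "occupied": occupied,
        "spearman_rho": float(rho),
    }
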