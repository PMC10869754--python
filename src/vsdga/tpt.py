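"""Transition-path-theory observables from weights and committors:
potentials of mean force (with voltage tilt), conditional averages,
committor-binned distributions, reactive-current fields projected onto
collective variables, equilibrium time-correlation functions with
biexponential fits, and the sensing charge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.optimize

from .states import LABEL_A, LABEL_B, StoppedEnsemble
from .synthetic import ShortTrajectoryEnsemble

__all__ = [
    "PMFGrid",
    "CurrentField",
    "TCFSeries",
    "BinnedDistribution",
    "KT_300K_KCAL",
    "EMV_TO_KCAL",
    "weighted_pmf",
    "tilt_pmf",
    "conditional_average",
    "committor_binned_distributions",
    "reactive_current",
    "equilibrium_tcf",
    "fit_biexponential",
    "sensing_charge",
    "count_pmf_minima",
]

#: kB * 300 K in kcal/mol, the default thermal energy for PMFs
KT_300K_KCAL = 0.5961
#: 1 e * mV in kcal/mol, for converting voltage tilts of charge PMFs
EMV_TO_KCAL = 0.0230605


@dataclass
class PMFGrid:
    """Free energy on a 1D or 2D grid, min-shifted to zero over occupied
    bins; empty bins are masked rather than set to a sentinel value."""

    bin_edges: list[np.ndarray]
    free_energy: np.ndarray        # NaN on empty bins
    occupied: np.ndarray           # boolean mask
    kT: float
    n_out_of_range: int = 0

    @property
    def bin_centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.bin_edges]


@dataclass
class CurrentField:
    bin_centers: list[np.ndarray]
    current: np.ndarray            # (nx, ny, 2)
    counts: np.ndarray             # reactive deposits per bin
    smoothing_bins: float = 1.0


@dataclass
class TCFSeries:
    lags: np.ndarray               # physical time
    values: np.ndarray             # normalized, values[0] == 1
    fit: tuple[float, float, float, float] | None = None  # (a1, tau1, a2, tau2)
    fit_residual: float | None = None
    degenerate_fit: bool = False


@dataclass
class BinnedDistribution:
    centers: np.ndarray
    halfwidth: float
    median: np.ndarray             # NaN where a bin is empty
    lower_quartile: np.ndarray
    upper_quartile: np.ndarray
    counts: np.ndarray


def _histogram(cvs: np.ndarray, weights: np.ndarray, bins) -> tuple[np.ndarray, list[np.ndarray], int]:
    cvs = np.asarray(cvs, dtype=float)
    if cvs.ndim == 1:
        cvs = cvs[:, None]
    dim = cvs.shape[1]
    if dim not in (1, 2):
        raise ValueError("PMFs support 1 or 2 collective variables")
    if isinstance(bins, np.ndarray) and bins.ndim == 1 and dim == 1:
        bins = [bins]
    hist, edges = np.histogramdd(cvs, bins=bins, weights=weights)
    total_in = np.histogramdd(cvs, bins=[np.asarray(e) for e in edges])[0].sum()
    n_out = len(cvs) - int(total_in)
    return hist, [np.asarray(e) for e in edges], n_out


def weighted_pmf(
    cv_values: np.ndarray,
    weights: np.ndarray,
    bins,
    kT: float = KT_300K_KCAL,
) -> PMFGrid:
    """Potential of mean force ``F = -kT ln(sum of weights per bin)``,
    min-shifted so the deepest occupied bin is zero."""
    w = np.asarray(weights, dtype=float)
    hist, edges, n_out = _histogram(cv_values, w, bins)
    occupied = hist > 0
    if not occupied.any():
        raise ValueError("all frames fall outside the requested bins")
    F = np.full(hist.shape, np.nan)
    F[occupied] = -kT * np.log(hist[occupied])
    F -= np.nanmin(F)
    return PMFGrid(bin_edges=edges, free_energy=F, occupied=occupied, kT=kT,
                   n_out_of_range=n_out)


def tilt_pmf(pmf: PMFGrid, voltage_mV: float) -> PMFGrid:
    """Apply a membrane-potential tilt ``F + Q_d * V`` to a PMF whose axis
    is the displacement charge (units e); V in millivolts."""
    if pmf.free_energy.ndim != 1:
        raise ValueError("voltage tilt applies to a 1D charge PMF")
    q = pmf.bin_centers[0]
    F = pmf.free_energy + q * voltage_mV * EMV_TO_KCAL
    F = F - np.nanmin(F)
    return PMFGrid(bin_edges=pmf.bin_edges, free_energy=F, occupied=pmf.occupied,
                   kT=pmf.kT, n_out_of_range=pmf.n_out_of_range)


def conditional_average(
    observable: np.ndarray,
    cvs: np.ndarray,
    weights: np.ndarray,
    bins,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Weighted mean of an observable on a CV grid; empty bins are NaN."""
    obs = np.asarray(observable, dtype=float)
    w = np.asarray(weights, dtype=float)
    num, edges, _ = _histogram(cvs, w * obs, bins)
    den, _, _ = _histogram(cvs, w, [e for e in edges])
    out = np.full(num.shape, np.nan)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out, edges


def _weighted_quantile(x: np.ndarray, w: np.ndarray, qs) -> np.ndarray:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(qs, cw, x)


def committor_binned_distributions(
    observable: np.ndarray,
    q_plus: np.ndarray,
    weights: np.ndarray,
    centers: np.ndarray | None = None,
    halfwidth: float = 0.05,
) -> BinnedDistribution:
    """Weighted median and quartiles of an observable in committor windows
    ``|q+ - center| <= halfwidth`` (the violin-plot summary)."""
    if centers is None:
        centers = np.arange(0.1, 0.95, 0.1)
    centers = np.asarray(centers, dtype=float)
    q = np.asarray(q_plus, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q_plus must be clipped to [0, 1]")
    obs = np.asarray(observable, dtype=float)
    w = np.asarray(weights, dtype=float)
    med = np.full(len(centers), np.nan)
    lo = np.full(len(centers), np.nan)
    hi = np.full(len(centers), np.nan)
    counts = np.zeros(len(centers), dtype=int)
    for i, c in enumerate(centers):
        mask = np.abs(q - c) <= halfwidth
        counts[i] = int(mask.sum())
        if counts[i] == 0 or w[mask].sum() == 0:
            continue
        lo[i], med[i], hi[i] = _weighted_quantile(obs[mask], w[mask],
                                                  [0.25, 0.5, 0.75])
    return BinnedDistribution(centers=centers, halfwidth=halfwidth, median=med,
                              lower_quartile=lo, upper_quartile=hi, counts=counts)


def reactive_current(
    q_plus: np.ndarray,
    weights: np.ndarray,
    xi: np.ndarray,
    stopped: StoppedEnsemble,
    bins,
    q_minus: np.ndarray | None = None,
    save_interval: float = 1.0,
    smoothing_bins: float = 1.0,
) -> CurrentField:
    """Reactive current projected onto two collective variables.

    Each (start, stopped-end) pair deposits the antisymmetrized reactive
    displacement

        (w/2) * [q-(start) q+(end) - q+(start) q-(end)] * (xi(end)-xi(start)) / lag

    split equally between the start and end bins, averaged over pairs and
    smoothed with a Gaussian kernel of ``smoothing_bins`` bins.  The
    backward committor defaults to ``1 - q+`` (equilibrium, reversible
    dynamics).  Units: xi-units per unit time.
    """
    q = np.asarray(q_plus, dtype=float)
    qm = 1.0 - q if q_minus is None else np.asarray(q_minus, dtype=float)
    w = np.asarray(weights, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if xi.ndim != 2 or xi.shape[1] != 2:
        raise ValueError("xi must be (n_frames, 2)")

    s, e = stopped.start_index, stopped.stop_index
    lag_time = stopped.lag * save_interval
    amp = 0.5 * w[s] * (qm[s] * q[e] - q[s] * qm[e]) / lag_time
    disp = xi[e] - xi[s]
    contrib = amp[:, None] * disp  # (n_pairs, 2)

    # bin geometry
    _, edges, _ = _histogram(xi, np.ones(len(xi)), bins)
    nx, ny = len(edges[0]) - 1, len(edges[1]) - 1
    ix_s = np.clip(np.searchsorted(edges[0], xi[s, 0], side="right") - 1, 0, nx - 1)
    iy_s = np.clip(np.searchsorted(edges[1], xi[s, 1], side="right") - 1, 0, ny - 1)
    ix_e = np.clip(np.searchsorted(edges[0], xi[e, 0], side="right") - 1, 0, nx - 1)
    iy_e = np.clip(np.searchsorted(edges[1], xi[e, 1], side="right") - 1, 0, ny - 1)

    J = np.zeros((nx, ny, 2))
    counts = np.zeros((nx, ny))
    for d in range(2):
        np.add.at(J[..., d], (ix_s, iy_s), 0.5 * contrib[:, d])
        np.add.at(J[..., d], (ix_e, iy_e), 0.5 * contrib[:, d])
    active = amp != 0
    np.add.at(counts, (ix_s[active], iy_s[active]), 1.0)
    J /= stopped.n_pairs
    if smoothing_bins > 0:
        for d in range(2):
            J[..., d] = scipy.ndimage.gaussian_filter(J[..., d], smoothing_bins)
    centers = [0.5 * (e_[1:] + e_[:-1]) for e_ in edges]
    return CurrentField(bin_centers=centers, current=J, counts=counts,
                        smoothing_bins=smoothing_bins)


def equilibrium_tcf(
    observable: np.ndarray,
    weights: np.ndarray,
    ensemble: ShortTrajectoryEnsemble,
    lags: np.ndarray,
    center: bool = False,
) -> TCFSeries:
    """Equilibrium autocorrelation of an observable from reweighted short
    trajectories:  C(tau) = <w O(0) O(tau)> / <w>, normalized by C(0).

    No stopping is applied.  ``lags`` are in frames; the returned series is
    indexed by physical time (frames times save_interval).
    """
    obs = np.asarray(observable, dtype=float)
    w = np.asarray(weights, dtype=float)
    if center:
        obs = obs - np.average(obs, weights=w)
    offsets = ensemble.offsets
    lags = np.asarray(lags, dtype=int)
    max_len = max(offsets[k + 1] - offsets[k] for k in range(ensemble.n_traj))
    if lags.max() >= max_len:
        raise ValueError(f"lag {lags.max()} exceeds every trajectory length")
    vals = np.empty(len(lags))
    for i, tau in enumerate(lags):
        num = 0.0
        den = 0.0
        for k in range(ensemble.n_traj):
            lo, hi = offsets[k], offsets[k + 1]
            if hi - lo <= tau:
                continue
            s = slice(lo, hi - tau)
            e = slice(lo + tau, hi)
            num += float(np.sum(w[s] * obs[s] * obs[e]))
            den += float(np.sum(w[s]))
        if den == 0:
            raise ValueError(f"no pairs at lag {tau}")
        vals[i] = num / den
    c0 = vals[0] if lags[0] == 0 else float(
        np.sum(w * obs * obs) / np.sum(w)
    )
    return TCFSeries(lags=lags * ensemble.save_interval, values=vals / c0)


def fit_biexponential(
    tcf: TCFSeries,
    n_starts: int = 6,
) -> TCFSeries:
    """Fit ``a1 exp(-t/tau1) + (1-a1) exp(-t/tau2)`` to a normalized TCF.

    Multi-start nonlinear least squares with decade-spaced initial time
    constants; returns a copy of the series with ``fit = (a1, tau1, a2,
    tau2)`` sorted so tau1 >= tau2.  Degenerate fits (equal time constants
    or a vanishing amplitude) are flagged; a non-decaying series raises.
    """
    t = np.asarray(tcf.lags, dtype=float)
    y = np.asarray(tcf.values, dtype=float)
    if len(t) < 8:
        raise ValueError("need at least 8 lag points for a biexponential fit")
    if np.ptp(y) < 1e-12:
        raise ValueError("series does not decay: biexponential fit undefined")

    tmax = t[t > 0].max()
    tmin = max(t[t > 0].min(), tmax * 1e-8)

    def model(params):
        a, lt1, lt2 = params
        return a * np.exp(-t / np.exp(lt1)) + (1 - a) * np.exp(-t / np.exp(lt2))

    def resid(params):
        return model(params) - y

    decades = np.linspace(np.log(tmin), np.log(tmax), n_starts)
    best = None
    for i, l1 in enumerate(decades):
        for l2 in decades[: i + 1]:
            res = scipy.optimize.least_squares(
                resid, x0=[0.5, l1, l2],
                bounds=([0.0, np.log(tmin) - 5, np.log(tmin) - 5],
                        [1.0, np.log(tmax) + 5, np.log(tmax) + 5]),
            )
            if best is None or res.cost < best.cost:
                best = res
    if best is None or not best.success and best.cost > 1e-6:
        raise RuntimeError(f"biexponential fit failed to converge (cost {best.cost})")
    a, lt1, lt2 = best.x
    t1, t2 = np.exp(lt1), np.exp(lt2)
    a1, tau1, a2, tau2 = (a, t1, 1 - a, t2) if t1 >= t2 else (1 - a, t2, a, t1)
    degenerate = bool(abs(tau1 - tau2) < 1e-3 * tau1 or min(a1, a2) < 1e-3)
    return TCFSeries(lags=tcf.lags, values=tcf.values,
                     fit=(float(a1), float(tau1), float(a2), float(tau2)),
                     fit_residual=float(np.sqrt(2 * best.cost / len(t))),
                     degenerate_fit=degenerate)


def sensing_charge(
    Qd: np.ndarray,
    weights: np.ndarray,
    labels: np.ndarray,
) -> float:
    """Sensing (gating) charge: difference of the weighted mean displacement
    charge between product (B/up) and reactant (A/down) states."""
    Qd = np.asarray(Qd, dtype=float)
    w = np.asarray(weights, dtype=float)
    labels = np.asarray(labels)
    mA = labels == LABEL_A
    mB = labels == LABEL_B
    if not mA.any() or not mB.any():
        raise ValueError("both states must be populated to compute a sensing charge")
    meanA = np.average(Qd[mA], weights=w[mA])
    meanB = np.average(Qd[mB], weights=w[mB])
    return float(meanB - meanA)


def count_pmf_minima(
    pmf: PMFGrid,
    smooth_bins: float = 0.0,
    interior_mask: np.ndarray | None = None,
    max_free_energy: float | None = None,
    min_prominence: float = 0.5,
) -> int:
    """Count free-energy basins of a PMF grid by topological persistence.

    Occupied bins are swept in order of increasing free energy and merged
    with already-visited neighbours (8-connectivity in 2D); every merge of
    two components kills the younger one, and a basin is counted when its
    persistence (free energy at death minus at birth) is at least
    ``min_prominence`` (same units as the PMF).  This merges spurious
    minima created by bin noise while keeping genuinely separated wells,
    including wells at the grid edge or beside empty regions.

    ``interior_mask`` restricts counting to basins born inside the mask
    (e.g. interior committor bins); ``max_free_energy`` discards basins
    whose floor lies above an absolute cutoff.  Optional mask-aware
    Gaussian pre-smoothing uses occupied bins only.
    """
    F = pmf.free_energy.copy()
    occ = pmf.occupied
    if smooth_bins > 0:
        # normalized convolution: smooth using occupied bins only, so empty
        # regions neither pull values up nor bleed into real basins
        num = scipy.ndimage.gaussian_filter(np.where(occ, F, 0.0), smooth_bins)
        den = scipy.ndimage.gaussian_filter(occ.astype(float), smooth_bins)
        F = np.where(occ, num / np.maximum(den, 1e-12), np.nan)

    if F.ndim == 1:
        shape = (len(F),)
        neighbours = [(-1,), (1,)]
    else:
        shape = F.shape
        neighbours = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                      if not (di == 0 and dj == 0)]

    order = np.argsort(F[occ], kind="stable")
    coords = np.argwhere(occ)[order]
    comp_of: dict[tuple, int] = {}
    birth: list[float] = []
    root: list[int] = []          # union-find over components
    persistence: list[float] = []
    born_interior: list[bool] = []

    def find(c: int) -> int:
        while root[c] != c:
            root[c] = root[root[c]]
            c = root[c]
        return c

    for pos in map(tuple, coords):
        f_here = float(F[pos])
        seen = set()
        for off in neighbours:
            nb = tuple(p + o for p, o in zip(pos, off))
            if any(k < 0 or k >= s for k, s in zip(nb, shape)):
                continue
            if nb in comp_of:
                seen.add(find(comp_of[nb]))
        if not seen:
            comp_of[pos] = len(birth)
            root.append(len(birth))
            persistence.append(np.inf)
            born_interior.append(interior_mask is None
                                 or bool(interior_mask[pos]))
            birth.append(f_here)
            continue
        ranked = sorted(seen, key=lambda c: birth[c])
        winner = ranked[0]
        comp_of[pos] = winner
        for loser in ranked[1:]:
            persistence[loser] = f_here - birth[loser]
            root[loser] = winner

    count = 0
    for c in range(len(birth)):
        if persistence[c] < min_prominence:
            continue
        if not born_interior[c]:
            continue
        if max_free_energy is not None and birth[c] > max_free_energy:
            continue
        count += 1
    return count
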