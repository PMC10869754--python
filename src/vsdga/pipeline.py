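"""End-to-end analysis pipeline on the voltage-sensor surrogate (or on a
user-supplied feature table).

Stages communicate through files in a working directory so they can be run
in one shot (:func:`run_pipeline`) or individually from the command line;
both routes produce identical outputs for the same configuration.  Every
stage appends diagnostics to ``report.json``.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import h5py
import numpy as np

from . import dga, interpret, io, states, synthetic, tpt

logger = logging.getLogger("vsdga")

__all__ = ["run_pipeline", "STAGES"]


def _load_report(workdir: Path) -> dict:
    import json

    p = workdir / "report.json"
    if p.exists():
        with open(p) as fh:
            return json.load(fh)
    return {}


def _update_report(workdir: Path, stage: str, payload: dict) -> None:
    report = _load_report(workdir)
    report[stage] = payload
    io.write_json(workdir / "report.json", report)


def _save_arrays(path: Path, **arrays) -> None:
    with h5py.File(path, "w") as fh:
        for k, v in arrays.items():
            fh.create_dataset(k, data=np.asarray(v))


def _load_arrays(path: Path) -> dict:
    with h5py.File(path, "r") as fh:
        return {k: fh[k][...] for k in fh.keys()}


def _surrogate(cfg: io.PipelineConfig) -> synthetic.SurrogateVSDModel:
    sim = cfg.simulate
    return synthetic.make_vsd_surrogate(
        n_basins=sim.n_basins, n_features=sim.n_features, seed=cfg.seed,
        noise_scale=sim.noise_scale, charge_gap=sim.charge_gap,
    )


def _load_table(workdir: Path):
    ens, cols = io.load_ensemble(workdir / "ensemble.h5")
    stacked = ens.stacked
    cv = stacked[:, :2]
    charge = stacked[:, 2]
    feats = stacked[:, 3:]
    return ens, cv, charge, feats


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def stage_simulate(cfg: io.PipelineConfig, workdir: Path) -> None:
    """Generate surrogate trajectories (or import a feature table) and
    write the interchange ensemble: columns (d, theta, charge, features)."""
    t0 = time.time()
    if cfg.features_path is not None:
        ens, cols = io.ensemble_from_csv(cfg.features_path)
        io.save_ensemble(workdir / "ensemble.h5", ens, column_names=cols)
        _update_report(workdir, "simulate", {
            "source": cfg.features_path, "n_traj": ens.n_traj,
            "n_frames": ens.n_frames, "seconds": time.time() - t0,
        })
        return
    sim = cfg.simulate
    model = _surrogate(cfg)
    ens = model.simulate(
        n_traj=sim.n_traj, n_frames=sim.n_frames, seed=cfg.seed,
        kT=sim.kT, timestep=sim.timestep, save_interval=sim.save_interval,
        start_jitter=sim.start_jitter,
    )
    cv = ens.stacked
    charge = model.charge_map(cv)
    feats = model.feature_map(cv, seed=cfg.seed + 17)
    table = np.column_stack([cv, charge, feats])
    offsets = ens.offsets
    full = synthetic.ShortTrajectoryEnsemble(
        trajectories=[table[offsets[k]:offsets[k + 1]] for k in range(ens.n_traj)],
        save_interval=ens.save_interval,
        start_distribution_tag=ens.start_distribution_tag,
        seed=cfg.seed,
    )
    cols = ["d", "theta", "charge"] + [f"feat_{i}" for i in range(feats.shape[1])]
    io.save_ensemble(workdir / "ensemble.h5", full, column_names=cols)
    logger.info("simulate: %d trajectories x %d frames", ens.n_traj,
                ens.n_frames // ens.n_traj)
    _update_report(workdir, "simulate", {
        "n_traj": full.n_traj, "n_frames": full.n_frames,
        "save_interval": full.save_interval, "seconds": time.time() - t0,
    })


def stage_states(cfg: io.PipelineConfig, workdir: Path) -> None:
    """Assign reactant/product labels from the configured ellipses."""
    ens, cv, charge, feats = _load_table(workdir)
    down = states.StateDefinition(center=cfg.states.down.center,
                                  radii=cfg.states.down.radii)
    up = states.StateDefinition(center=cfg.states.up.center,
                                radii=cfg.states.up.radii)
    labels = states.assign_states(cv, down, up)
    _save_arrays(workdir / "labels.h5", labels=labels)
    nA = int((labels == states.LABEL_A).sum())
    nB = int((labels == states.LABEL_B).sum())
    logger.info("states: %d A, %d B of %d frames", nA, nB, len(labels))
    _update_report(workdir, "states", {
        "n_A": nA, "n_B": nB, "n_frames": len(labels),
    })


def stage_basis(cfg: io.PipelineConfig, workdir: Path) -> None:
    """Committor distance basis (boundary distances from the state
    ellipses) and cluster indicator basis for the weights."""
    t0 = time.time()
    ens, cv, charge, feats = _load_table(workdir)
    labels = _load_arrays(workdir / "labels.h5")["labels"]
    down = states.StateDefinition(center=cfg.states.down.center,
                                  radii=cfg.states.down.radii)
    up = states.StateDefinition(center=cfg.states.up.center,
                                radii=cfg.states.up.radii)
    dA, dB = states.ellipse_boundary_distances(cv, down, up)
    basis = states.build_distance_basis(feats, labels,
                                        whiten_tol=cfg.basis.whiten_tol,
                                        d_A=dA, d_B=dB)
    _save_arrays(workdir / "basis.h5", values=basis.values, guess=basis.guess,
                 d_A=basis.d_A, d_B=basis.d_B, h=basis.h)
    ind = states.build_indicator_basis(
        feats, k=cfg.basis.k, seed=cfg.seed,
        ivac_dims=cfg.basis.ivac_dims, ensemble=ens,
        ivac_lags=(cfg.basis.ivac_min_lag, cfg.basis.ivac_max_lag),
        mini_batch=cfg.basis.mini_batch, sparse=True,
    )
    _save_arrays(workdir / "clusters.h5", cluster_labels=ind.cluster_labels,
                 k=np.array([cfg.basis.k]))
    _update_report(workdir, "basis", {
        "n_distance_basis": basis.n_basis,
        "n_dropped_columns": basis.n_dropped_columns,
        "k_clusters": cfg.basis.k,
        "seconds": time.time() - t0,
    })


def _committor_basis(cfg, workdir):
    arrs = _load_arrays(workdir / "basis.h5")
    return states.BasisSet(values=arrs["values"], guess=arrs["guess"],
                           kind="distance", d_A=arrs["d_A"], d_B=arrs["d_B"],
                           h=arrs["h"])


def _indicator_basis(cfg, workdir):
    arrs = _load_arrays(workdir / "clusters.h5")
    return states.indicator_basis_from_states(arrs["cluster_labels"],
                                              int(arrs["k"][0]))


def stage_committor(cfg: io.PipelineConfig, workdir: Path) -> None:
    t0 = time.time()
    ens, cv, charge, feats = _load_table(workdir)
    labels = _load_arrays(workdir / "labels.h5")["labels"]
    basis = _committor_basis(cfg, workdir)
    stopped = states.stop_times(ens, labels, cfg.lag)
    system = dga.assemble_system(basis, stopped)
    field = dga.solve_committor(system, basis, labels=labels)
    _save_arrays(workdir / "committor.h5", q_plus=field.q_plus,
                 raw=field.raw_values, lag=np.array([cfg.lag]))
    _update_report(workdir, "committor", {
        "lag": cfg.lag, "n_pairs": system.n_pairs,
        "condition_number": field.condition_number,
        "frac_clipped": float(np.mean((field.raw_values < 0)
                                      | (field.raw_values > 1))),
        "seconds": time.time() - t0,
    })


def stage_weights(cfg: io.PipelineConfig, workdir: Path) -> None:
    t0 = time.time()
    ens, *_ = _load_table(workdir)
    basis = _indicator_basis(cfg, workdir)
    field = dga.solve_weights(ens, basis, lag=cfg.lag)
    _save_arrays(workdir / "weights.h5", w=field.w)
    _update_report(workdir, "weights", {
        "lag": cfg.lag, "min_w": float(field.w.min()),
        "max_w": float(field.w.max()), "seconds": time.time() - t0,
    })


def stage_mfpt(cfg: io.PipelineConfig, workdir: Path) -> None:
    t0 = time.time()
    ens, *_ = _load_table(workdir)
    labels = _load_arrays(workdir / "labels.h5")["labels"]
    basis = _indicator_basis(cfg, workdir)
    field = dga.solve_mfpt(ens, basis, labels, lag=cfg.lag)
    _save_arrays(workdir / "mfpt.h5", m=field.m)
    w = _load_arrays(workdir / "weights.h5")["w"]
    mA = labels == states.LABEL_A
    mfpt_from_A = float(np.average(field.m[mA], weights=w[mA])) if mA.any() else np.nan
    _update_report(workdir, "mfpt", {
        "condition_number": field.condition_number,
        "mfpt_from_down_state": mfpt_from_A,
        "seconds": time.time() - t0,
    })


def stage_pmf(cfg: io.PipelineConfig, workdir: Path) -> None:
    """1D charge PMF with voltage tilts, 2D (committor, charge) PMF, and
    2D (translocation, rotation) PMF; also the sensing charge."""
    ens, cv, charge, feats = _load_table(workdir)
    labels = _load_arrays(workdir / "labels.h5")["labels"]
    w = _load_arrays(workdir / "weights.h5")["w"]
    q = _load_arrays(workdir / "committor.h5")["q_plus"]

    pmf_q = tpt.weighted_pmf(charge, w, bins=cfg.bins, kT=cfg.kT)
    tilts = {f"{v:+.0f}mV": tpt.tilt_pmf(pmf_q, v).free_energy
             for v in cfg.voltages_mV}
    pmf_2d = tpt.weighted_pmf(np.column_stack([q, charge]),
                              w, bins=cfg.bins, kT=cfg.kT)
    pmf_cv = tpt.weighted_pmf(cv, w, bins=cfg.bins, kT=cfg.kT)
    dq = tpt.sensing_charge(charge, w, labels)
    _save_arrays(
        workdir / "pmf.h5",
        charge_edges=pmf_q.bin_edges[0], charge_F=pmf_q.free_energy,
        qc_edges_q=pmf_2d.bin_edges[0], qc_edges_c=pmf_2d.bin_edges[1],
        qc_F=pmf_2d.free_energy,
        cv_edges_d=pmf_cv.bin_edges[0], cv_edges_t=pmf_cv.bin_edges[1],
        cv_F=pmf_cv.free_energy,
        **{f"charge_F_{k}": v for k, v in tilts.items()},
    )
    _update_report(workdir, "pmf", {
        "sensing_charge_e": dq,
        "kT": cfg.kT,
        "n_out_of_range": pmf_q.n_out_of_range,
    })


def stage_current(cfg: io.PipelineConfig, workdir: Path) -> None:
    ens, cv, charge, feats = _load_table(workdir)
    labels = _load_arrays(workdir / "labels.h5")["labels"]
    w = _load_arrays(workdir / "weights.h5")["w"]
    q = _load_arrays(workdir / "committor.h5")["q_plus"]
    stopped = states.stop_times(ens, labels, cfg.lag)
    field = tpt.reactive_current(q, w, cv, stopped, bins=cfg.bins,
                                 save_interval=ens.save_interval)
    _save_arrays(workdir / "current.h5",
                 centers_d=field.bin_centers[0], centers_t=field.bin_centers[1],
                 current=field.current, counts=field.counts)
    _update_report(workdir, "current", {
        "n_reactive_bins": int((field.counts > 0).sum()),
        "max_magnitude": float(np.linalg.norm(field.current, axis=-1).max()),
    })


def stage_tcf(cfg: io.PipelineConfig, workdir: Path) -> None:
    ens, cv, charge, feats = _load_table(workdir)
    w = _load_arrays(workdir / "weights.h5")["w"]
    lags = np.asarray(cfg.tcf_lags, dtype=int)
    series = tpt.equilibrium_tcf(charge, w, ens, lags, center=True)
    payload = {"lags": series.lags.tolist(), "values": series.values.tolist()}
    try:
        fitted = tpt.fit_biexponential(series)
        payload["fit_a1_tau1_a2_tau2"] = list(fitted.fit)
        payload["fit_residual"] = fitted.fit_residual
        payload["degenerate_fit"] = fitted.degenerate_fit
    except (ValueError, RuntimeError) as err:
        payload["fit_error"] = str(err)
    _save_arrays(workdir / "tcf.h5", lags=series.lags, values=series.values)
    _update_report(workdir, "tcf", payload)


def stage_sparsefit(cfg: io.PipelineConfig, workdir: Path) -> None:
    """Two-branch LASSO committor models on (slow CVs + features)."""
    ens, cv, charge, feats = _load_table(workdir)
    w = _load_arrays(workdir / "weights.h5")["w"]
    q = _load_arrays(workdir / "committor.h5")["q_plus"]
    X = np.column_stack([cv, feats])
    names = ["d", "theta"] + [f"feat_{i}" for i in range(feats.shape[1])]
    idx = interpret.sample_transition_points(q, w, n=cfg.lasso.n_samples,
                                             seed=cfg.seed + 29)
    out = {}
    for branch, lam in (("lower", cfg.lasso.lambda_lower),
                        ("upper", cfg.lasso.lambda_upper)):
        qi = q[idx]
        sel = (qi <= 0.5) if branch == "lower" else (qi >= 0.5)
        y = interpret.transform_committor(qi[sel], branch)
        ok = np.isfinite(y)
        model = interpret.fit_lasso(X[idx][sel][ok], y[ok], lam, branch=branch,
                                    q_true=qi[sel][ok], feature_names=names)
        out[branch] = {
            "lambda": lam,
            "n_points": int(ok.sum()),
            "n_excluded_endpoint": int((~ok).sum()),
            "nonzero_features": [names[i] for i in model.nonzero],
            "coefficients": model.coefficients.tolist(),
            "r_squared_transformed": model.r_squared,
            "r_squared_committor": model.r_squared_committor,
        }
    _update_report(workdir, "sparsefit", out)


def stage_ivac(cfg: io.PipelineConfig, workdir: Path) -> None:
    ens, cv, charge, feats = _load_table(workdir)
    w = _load_arrays(workdir / "weights.h5")["w"]
    q = _load_arrays(workdir / "committor.h5")["q_plus"]
    model = interpret.fit_ivac(ens, feats, min_lag=cfg.basis.ivac_min_lag,
                               max_lag=cfg.basis.ivac_max_lag,
                               n_dims=min(cfg.basis.ivac_dims, feats.shape[1]))
    check = interpret.validate_subspace(model, feats, q, weights=w)
    _save_arrays(workdir / "ivac.h5", eigenvalues=model.eigenvalues,
                 coords=model.transform(feats)[:, :2])
    _update_report(workdir, "ivac", {
        "eigenvalues": model.eigenvalues.tolist(),
        "spearman_rho": check["spearman_rho"],
    })


def stage_report(cfg: io.PipelineConfig, workdir: Path) -> dict:
    """Summary: counts of PMF minima and the headline scalars."""
    report = _load_report(workdir)
    arrs = _load_arrays(workdir / "pmf.h5")
    pmf_q = tpt.PMFGrid(bin_edges=[arrs["charge_edges"]], free_energy=arrs["charge_F"],
                        occupied=np.isfinite(arrs["charge_F"]), kT=cfg.kT)
    pmf_2d = tpt.PMFGrid(bin_edges=[arrs["qc_edges_q"], arrs["qc_edges_c"]],
                         free_energy=arrs["qc_F"],
                         occupied=np.isfinite(arrs["qc_F"]), kT=cfg.kT)
    n_1d = tpt.count_pmf_minima(pmf_q, max_free_energy=3.0 * cfg.kT,
                                min_prominence=0.75 * cfg.kT)
    centers_q = pmf_2d.bin_centers[0]
    interior = np.zeros(pmf_2d.free_energy.shape, dtype=bool)
    interior[(centers_q > 0.08) & (centers_q < 0.93), :] = True
    n_2d_interior = tpt.count_pmf_minima(pmf_2d, interior_mask=interior,
                                         max_free_energy=3.0 * cfg.kT,
                                         min_prominence=0.75 * cfg.kT)
    summary = {
        "charge_pmf_minima": n_1d,
        "committor_charge_pmf_interior_minima": n_2d_interior,
        "sensing_charge_e": report.get("pmf", {}).get("sensing_charge_e"),
        "lag": cfg.lag,
        "seed": cfg.seed,
    }
    _update_report(workdir, "summary", summary)
    return summary


STAGES = {
    "simulate": stage_simulate,
    "states": stage_states,
    "basis": stage_basis,
    "committor": stage_committor,
    "weights": stage_weights,
    "mfpt": stage_mfpt,
    "pmf": stage_pmf,
    "current": stage_current,
    "tcf": stage_tcf,
    "sparsefit": stage_sparsefit,
    "ivac": stage_ivac,
    "report": stage_report,
}


def run_pipeline(cfg: io.PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in order; deterministic given the configuration.

    Returns the summary dictionary; all artifacts and the JSON report are
    left in ``outdir``.  A stage failure propagates after earlier outputs
    have been persisted, so partial results remain inspectable.
    """
    workdir = Path(outdir)
    workdir.mkdir(parents=True, exist_ok=True)
    io.save_config(cfg, workdir / "config.yaml")
    summary: dict = {}
    for name, stage in STAGES.items():
        logger.info("stage %s", name)
        t0 = time.time()
        try:
            result = stage(cfg, workdir)
        except Exception:
            logger.exception("stage %s failed; partial outputs kept in %s",
                             name, workdir)
            raise
        logger.info("stage %s done in %.1f s", name, time.time() - t0)
        if name == "report":
            summary = result
    return summary
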