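"""Transition-path observables: PMFs, voltage tilts, binned distributions,
reactive currents, time-correlation functions, sensing charge."""

import numpy as np
import pytest

from vsdga import dga
from vsdga import states as st
from vsdga import synthetic as syn
from vsdga import tpt


class TestWeightedPMF:
    def test_uniform_samples_flat(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 40_000)
        pmf = tpt.weighted_pmf(x, np.ones_like(x), bins=20, kT=1.0)
        # Poisson noise bound: sigma_F ~ kT/sqrt(n_per_bin)
        bound = 3.0 / np.sqrt(2000)
        assert np.nanmax(pmf.free_energy) < 3 * bound

    def test_boltzmann_double_well(self):
        """PMF of equilibrium-sampled double-well data matches the potential
        within 0.5 kT on occupied bins."""
        kT = 0.5
        U = lambda x: (x[:, 0] ** 2 - 1) ** 2
        model = syn.LangevinModel(potential=U, kT=kT, timestep=1e-3,
                                  save_interval=10)
        starts = np.concatenate([np.full((30, 1), -1.0), np.full((30, 1), 1.0)])
        ens = syn.simulate_langevin(model, 60, 40_000, starts, seed=1)
        x = ens.stacked[len(ens.stacked) // 10:, :1]
        pmf = tpt.weighted_pmf(x[:, 0], np.ones(len(x)), bins=25, kT=kT)
        centers = pmf.bin_centers[0]
        expected = (centers**2 - 1) ** 2
        expected -= expected[pmf.occupied].min()
        good = pmf.occupied & (expected < 4 * kT)  # well-sampled range
        dev = np.abs(pmf.free_energy[good] - expected[good])
        assert dev.max() < 0.5 * kT

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=5000)
        w = rng.uniform(0.5, 2.0, size=5000)
        a = tpt.weighted_pmf(x, w, bins=15)
        b = tpt.weighted_pmf(x, 2 * w, bins=15)
        np.testing.assert_allclose(a.free_energy[a.occupied],
                                   b.free_energy[b.occupied], atol=1e-12)

    def test_all_out_of_range_raises(self):
        with pytest.raises(ValueError, match="outside"):
            tpt.weighted_pmf(np.full(10, 5.0), np.ones(10),
                             bins=[np.linspace(0, 1, 5)])


class TestTiltPMF:
    def _pmf(self):
        rng = np.random.default_rng(3)
        q = np.concatenate([rng.normal(-4.2, 0.1, 3000),
                            rng.normal(-3.3, 0.1, 3000)])
        return tpt.weighted_pmf(q, np.ones_like(q), bins=30)

    def test_zero_voltage_identity(self):
        pmf = self._pmf()
        tilted = tpt.tilt_pmf(pmf, 0.0)
        np.testing.assert_allclose(tilted.free_energy[pmf.occupied],
                                   pmf.free_energy[pmf.occupied], atol=1e-12)

    def test_tilt_shifts_minima_linearly(self):
        pmf = self._pmf()
        V = 50.0
        tilted = tpt.tilt_pmf(pmf, V)
        c = pmf.bin_centers[0]
        occ = pmf.occupied
        # differences between two occupied bins change by exactly dQ*V
        i, j = np.flatnonzero(occ)[[0, -1]]
        dF0 = pmf.free_energy[j] - pmf.free_energy[i]
        dF1 = tilted.free_energy[j] - tilted.free_energy[i]
        assert dF1 - dF0 == pytest.approx((c[j] - c[i]) * V * tpt.EMV_TO_KCAL,
                                          abs=1e-12)

    def test_tilt_untilt_roundtrip(self):
        pmf = self._pmf()
        back = tpt.tilt_pmf(tpt.tilt_pmf(pmf, 25.0), -25.0)
        np.testing.assert_allclose(back.free_energy[pmf.occupied],
                                   pmf.free_energy[pmf.occupied], atol=1e-12)


class TestConditionalAverage:
    def test_constant_observable(self):
        rng = np.random.default_rng(4)
        cvs = rng.uniform(0, 1, size=(2000, 2))
        out, _ = tpt.conditional_average(np.full(2000, 3.3), cvs,
                                         np.ones(2000), bins=5)
        assert np.allclose(out[np.isfinite(out)], 3.3)

    def test_observable_equals_first_cv(self):
        rng = np.random.default_rng(5)
        cvs = rng.uniform(0, 1, size=(20_000, 2))
        out, edges = tpt.conditional_average(cvs[:, 0], cvs, np.ones(20_000),
                                             bins=8)
        centers = 0.5 * (edges[0][1:] + edges[0][:-1])
        width = edges[0][1] - edges[0][0]
        for i, c in enumerate(centers):
            row = out[i][np.isfinite(out[i])]
            assert np.all(np.abs(row - c) <= 0.5 * width)


class TestCommittorBinnedDistributions:
    def test_self_binning_median_near_center(self):
        rng = np.random.default_rng(6)
        q = rng.uniform(0, 1, 50_000)
        d = tpt.committor_binned_distributions(q, q, np.ones_like(q))
        ok = ~np.isnan(d.median)
        assert np.all(np.abs(d.median[ok] - d.centers[ok]) <= d.halfwidth)

    def test_constant_observable_quartiles_collapse(self):
        rng = np.random.default_rng(7)
        q = rng.uniform(0, 1, 1000)
        d = tpt.committor_binned_distributions(np.full(1000, 2.0), q,
                                               np.ones(1000))
        ok = d.counts > 0
        assert np.all(d.median[ok] == 2.0)
        assert np.all(d.lower_quartile[ok] == d.upper_quartile[ok])

    def test_empty_bin_masked_with_zero_count(self):
        q = np.full(100, 0.5)
        d = tpt.committor_binned_distributions(np.ones(100), q, np.ones(100),
                                               centers=np.array([0.1, 0.5]))
        assert d.counts[0] == 0 and np.isnan(d.median[0])
        assert d.counts[1] == 100


def _reversible_two_channel():
    W = np.zeros((8, 8))
    for a, b in [(0, 1), (1, 2), (2, 3), (3, 7)]:
        W[a, b] = W[b, a] = 3.0
    for a, b in [(0, 4), (4, 5), (5, 6), (6, 7)]:
        W[a, b] = W[b, a] = 1.5
    coords = np.array([[0, 0], [1, 1], [2, 1], [3, 1],
                       [1, -1], [2, -1], [3, -1], [4, 0]], dtype=float)
    return syn.MarkovChainModel(W / W.sum(1, keepdims=True)), coords


class TestReactiveCurrent:
    def _chain_current(self, chain, coords, A, B, bins, seed, n_traj=4000):
        n = chain.n_states
        ens = syn.simulate_chain(chain, n_traj, 26, np.full(n, 1 / n), seed)
        idx = ens.stacked.astype(int)
        labels = np.zeros(len(idx), dtype=np.int8)
        labels[np.isin(idx, A)] = st.LABEL_A
        labels[np.isin(idx, B)] = st.LABEL_B
        basis = st.indicator_basis_from_states(idx, n)
        w = dga.solve_weights(ens, basis, lag=1).w
        q = syn.exact_committor(chain, A, B)[idx]
        stopped = st.stop_times(ens, labels, 1, boundary_starts="evolve")
        return tpt.reactive_current(q, w, coords[idx], stopped, bins=bins,
                                    smoothing_bins=0)

    def test_confined_ensemble_zero_current(self):
        chain = syn.random_walk_chain(9)
        ens = syn.simulate_chain(chain, 100, 20,
                                 np.eye(9)[0], seed=8)
        # trap walkers at the A edge by labeling everything up to state 6 A
        idx = ens.stacked.astype(int)
        labels = np.where(idx <= 6, st.LABEL_A, st.LABEL_NONE).astype(np.int8)
        q = np.zeros(len(idx))  # everything is reactant: no reactive pairs
        w = np.ones(len(idx))
        stopped = st.stop_times(ens, labels, 1, boundary_starts="evolve")
        xi = np.column_stack([idx.astype(float), np.zeros(len(idx))])
        field = tpt.reactive_current(q, w, xi, stopped,
                                     bins=[np.arange(-0.5, 9), np.array([-1., 1.])],
                                     smoothing_bins=0)
        assert np.allclose(field.current, 0.0)

    def test_1d_interior_current_matches_rate(self):
        chain = syn.random_walk_chain(9)
        coords = np.column_stack([np.arange(9, dtype=float), np.zeros(9)])
        ex = syn.exact_tpt(chain, [0], [8])
        field = self._chain_current(chain, coords, [0], [8],
                                    bins=[np.arange(-0.5, 9), np.array([-1., 1.])],
                                    seed=9)
        jx = field.current[:, 0, 0]
        assert np.max(np.abs(jx[1:-1] - ex.rate)) / ex.rate <= 0.15

    def test_two_channel_split_matches_oracle(self):
        chain, coords = _reversible_two_channel()
        ex = syn.exact_tpt(chain, [0], [7])
        split_exact = ex.net_current[0, 1] / ex.rate
        field = self._chain_current(chain, coords, [0], [7],
                                    bins=[np.arange(-0.5, 5),
                                          np.array([-1.5, 0.0, 1.5])],
                                    seed=10)
        jtop, jbot = field.current[2, 1, 0], field.current[2, 0, 0]
        split = jtop / (jtop + jbot)
        assert split == pytest.approx(split_exact, abs=0.15 * split_exact)
        assert (jtop + jbot) == pytest.approx(ex.rate, rel=0.15)


class TestEquilibriumTCF:
    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(11)
        ens = syn.ShortTrajectoryEnsemble(
            [rng.standard_normal((500, 1)) for _ in range(40)])
        obs = ens.stacked[:, 0]
        lags = np.array([0, 1, 2, 5])
        series = tpt.equilibrium_tcf(obs, np.ones(len(obs)), ens, lags)
        n_pairs = np.array([len(obs) - 40 * tau for tau in lags])
        # per-lag fluctuation bound for i.i.d. products (union over 3 lags)
        assert np.all(np.abs(series.values[1:]) < 3.5 / np.sqrt(n_pairs[1:]))

    def test_two_state_chain_closed_form(self):
        p = 0.3
        chain = syn.MarkovChainModel(np.array([[1 - p, p], [p, 1 - p]]))
        ens = syn.simulate_chain(chain, 3000, 40, np.array([0.5, 0.5]), seed=12)
        obs = 2.0 * ens.stacked.astype(float).ravel() - 1.0
        lags = np.arange(0, 7)
        series = tpt.equilibrium_tcf(obs, np.ones(len(obs)), ens, lags)
        expected = (1 - 2 * p) ** lags
        assert np.max(np.abs(series.values - expected)) < 0.02

    def test_unit_weights_equal_plain_autocorrelation(self):
        rng = np.random.default_rng(13)
        ens = syn.ShortTrajectoryEnsemble(
            [rng.standard_normal((100, 1)) for _ in range(5)])
        obs = ens.stacked[:, 0]
        lags = np.array([0, 1, 3])
        series = tpt.equilibrium_tcf(obs, np.ones(len(obs)), ens, lags)
        # independent plain estimator
        plain = []
        off = ens.offsets
        for tau in lags:
            num = den = 0.0
            for k in range(ens.n_traj):
                lo, hi = off[k], off[k + 1]
                num += np.sum(obs[lo:hi - tau or None] * obs[lo + tau:hi])
                den += hi - lo - tau
            plain.append(num / den)
        plain = np.array(plain) / plain[0]
        np.testing.assert_array_equal(series.values, plain)

    def test_lag_exceeding_trajectories_raises(self):
        ens = syn.ShortTrajectoryEnsemble([np.zeros((10, 1))])
        with pytest.raises(ValueError, match="lag"):
            tpt.equilibrium_tcf(np.zeros(10), np.ones(10), ens,
                                np.array([0, 20]))


class TestBiexponentialFit:
    def test_recovers_generator_time_constants(self):
        lags = np.unique(np.geomspace(0.01, 300.0, 60))
        vals = 0.7 * np.exp(-lags / 59.0) + 0.3 * np.exp(-lags / 0.04)
        fitted = tpt.fit_biexponential(tpt.TCFSeries(lags=lags, values=vals))
        a1, tau1, a2, tau2 = fitted.fit
        assert tau1 == pytest.approx(59.0, rel=0.05)
        assert tau2 == pytest.approx(0.04, rel=0.05)
        assert a1 == pytest.approx(0.7, abs=0.01)

    def test_single_exponential_flagged_degenerate(self):
        lags = np.geomspace(0.1, 50, 30)
        vals = np.exp(-lags / 5.0)
        fitted = tpt.fit_biexponential(tpt.TCFSeries(lags=lags, values=vals))
        a1, tau1, a2, tau2 = fitted.fit
        assert fitted.degenerate_fit or abs(tau1 - tau2) / tau1 < 0.05

    def test_constant_series_rejected(self):
        lags = np.linspace(0, 10, 20)
        with pytest.raises(ValueError, match="decay"):
            tpt.fit_biexponential(tpt.TCFSeries(lags=lags, values=np.ones(20)))


class TestSensingCharge:
    def test_printed_state_means(self):
        """Down/up displacement-charge means of -4.2 e and -3.3 e give a
        sensing charge of 0.9 e."""
        Qd = np.concatenate([np.full(100, -4.2), np.full(100, -3.3)])
        labels = np.concatenate([np.full(100, st.LABEL_A, dtype=np.int8),
                                 np.full(100, st.LABEL_B, dtype=np.int8)])
        dq = tpt.sensing_charge(Qd, np.ones(200), labels)
        assert dq == pytest.approx(0.9, abs=1e-12)

    def test_identical_distributions_zero(self):
        rng = np.random.default_rng(14)
        Qd = np.tile(rng.normal(-4.0, 0.1, 100), 2)
        labels = np.repeat([st.LABEL_A, st.LABEL_B], 100).astype(np.int8)
        assert tpt.sensing_charge(Qd, np.ones(200), labels) == pytest.approx(0.0, abs=1e-12)

    def test_empty_state_raises(self):
        with pytest.raises(ValueError, match="populated"):
            tpt.sensing_charge(np.zeros(10), np.ones(10),
                               np.full(10, st.LABEL_A, dtype=np.int8))


class TestCountMinima:
    def test_two_well_1d(self):
        x = np.linspace(-1.6, 1.6, 40)
        F = (x**2 - 1) ** 2
        pmf = tpt.PMFGrid(bin_edges=[np.linspace(-1.6, 1.6, 41)], free_energy=F,
                          occupied=np.ones(40, bool), kT=1.0)
        assert tpt.count_pmf_minima(pmf, min_prominence=0.5) == 2

    def test_shallow_noise_minima_merged(self):
        x = np.linspace(0, 1, 50)
        F = 4 * (x - 0.5) ** 2
        F[10] -= 0.05  # sub-prominence dip
        pmf = tpt.PMFGrid(bin_edges=[np.linspace(0, 1, 51)], free_energy=F,
                          occupied=np.ones(50, bool), kT=1.0)
        assert tpt.count_pmf_minima(pmf, min_prominence=0.3) == 1

    def test_2d_three_wells_with_empty_bins(self):
        n = 30
        xs = np.linspace(0, 1, n)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        F = np.full((n, n), 5.0)
        for cx in (0.2, 0.5, 0.8):
            F = np.minimum(F, 5 * ((X - cx) ** 2 + (Y - 0.5) ** 2) ** 0.5 * 4)
        occ = F < 4.0  # carve out empty high-F regions
        F = np.where(occ, F, np.nan)
        pmf = tpt.PMFGrid(bin_edges=[np.linspace(0, 1, n + 1)] * 2,
                          free_energy=F, occupied=occ, kT=1.0)
        assert tpt.count_pmf_minima(pmf, min_prominence=0.5) == 3
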