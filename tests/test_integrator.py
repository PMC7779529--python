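"""Euler-Maruyama integrator: exactness, reproducibility, noise statistics."""

import numpy as np
import pytest

import ctwc
from ctwc.integrate import _round_half_away
from ctwc.model import afferent_input, local_coupling


def _gain_free(params, D=0.0):
    return params.replace(w_ee=0, w_ei=0, w_ie=0, w_ii=0, w_er=0, w_es=0,
                          w_si=0, w_se=0, w_rs=0, w_sr=0, g=0.0, D=D)


class TestLinearLimit:
    def test_exponential_relaxation_to_constant_inputs(self, params):
        """With all gains and noise off, each population is a decoupled
        linear ODE relaxing to i_p at its effective rate."""
        p = _gain_free(params)
        u0 = p.constant_inputs + 1.0
        run = ctwc.simulate_single_node(p, duration_ms=1050.0, seed=0,
                                        burn_in_ms=1000.0, initial_state=u0)
        # burn-in covers delays; relaxation observed over the first 50 ms after
        n_burn = int(round(1000.0 / p.dt))
        steps = n_burn + np.arange(1, run.time.size + 1)
        t_total_ms = steps * p.dt  # time since the initial condition
        for pi in range(4):
            a = p.alpha_eff[pi]
            # exact discrete closed form of the explicit Euler recursion
            discrete = p.constant_inputs[pi] + (1 - a * p.dt) ** steps * 1.0
            assert np.allclose(run.traces[pi, 0], discrete, rtol=0, atol=1e-12)
            # and the continuous exponential to first-order accuracy
            cont = p.constant_inputs[pi] + np.exp(-a * t_total_ms)
            assert np.allclose(run.traces[pi, 0], cont, atol=0.01)

    def test_no_noise_is_seed_independent(self, params):
        p = _gain_free(params)
        runs = [ctwc.simulate_single_node(p, duration_ms=1200.0, seed=s,
                                          initial_state=p.constant_inputs + 0.5)
                for s in (1, 99)]
        assert np.array_equal(runs[0].traces, runs[1].traces)


class TestReproducibility:
    def test_identical_seeds_bitwise_identical(self, params, small_connectome):
        stim = ctwc.StimulusSpec.static(0.5, small_connectome.n_nodes)
        a = ctwc.simulate(params, small_connectome, stim, duration_ms=3000.0, seed=11)
        b = ctwc.simulate(params, small_connectome, stim, duration_ms=3000.0, seed=11)
        assert np.array_equal(a.traces, b.traces)
        c = ctwc.simulate(params, small_connectome, stim, duration_ms=3000.0, seed=12)
        assert not np.array_equal(a.traces, c.traces)

    def test_single_node_equals_trivial_network(self, params):
        iso = ctwc.simulate_single_node(params, i_o=0.7, duration_ms=3000.0, seed=4)
        net = ctwc.simulate(params, ctwc.Connectome.single_node(),
                            ctwc.StimulusSpec(i_o=np.array([0.7]), m=np.array([0.0])),
                            duration_ms=3000.0, seed=4)
        assert np.array_equal(iso.traces, net.traces)


class TestKernelAgainstReferenceOps:
    def test_network_step_matches_pure_numpy_stepper(self, params):
        """The compiled kernel and a stepper composed from the reference
        sigmoid/coupling/afferent operations must agree to rounding."""
        rng = np.random.default_rng(8)
        n = 3
        W = rng.uniform(0.2, 1.0, (n, n))
        np.fill_diagonal(W, 0)
        L = rng.uniform(20, 60, (n, n))
        L = 0.5 * (L + L.T)
        np.fill_diagonal(L, 0)
        conn = ctwc.Connectome.from_matrices(W, L, cv=params.cv)
        p = params.replace(D=0.0)
        stim = ctwc.StimulusSpec(i_o=np.array([0.0, 1.0, 0.2]),
                                 m=np.array([0.3, 0.0, 0.1]), omega_hz=11.0)
        duration, burn = 150.0, 40.0
        run = ctwc.simulate(p, conn, stim, duration_ms=duration, seed=0,
                            burn_in_ms=burn)

        dt = p.dt
        steps = int(round(duration / dt))
        burn_steps = int(round(burn / dt))
        dsteps = np.maximum(_round_half_away(conn.T / dt), 1).astype(int)
        nct = int(round(p.tau_ct / dt))
        ntt = int(round(p.tau_tt / dt))
        Wn = conn.normalized_weights(p.w_normalization)
        hist = np.tile(p.constant_inputs[:, None, None], (1, n, steps + 1))
        pad = max(dsteps.max(), nct, ntt)
        hist = np.concatenate(
            [np.tile(p.constant_inputs[:, None, None], (1, n, pad)), hist], axis=2)
        for t in range(steps):
            cur = pad + t
            state = hist[:, :, cur]
            drive = local_coupling(state, hist[:, :, cur - nct], hist[:, :, cur - ntt], p)
            delayed_ue = np.empty((n, n))
            for j in range(n):
                for k in range(n):
                    delayed_ue[j, k] = hist[0, k, cur - dsteps[j, k]]
            q = p.g * afferent_input(delayed_ue, Wn, p)
            t_ms = (t - burn_steps) * dt
            drive[0] += q + stim.m * np.sin(2 * np.pi * stim.omega_hz * t_ms / 1000.0)
            drive[3] += stim.i_o
            hist[:, :, cur + 1] = state + dt * p.alpha_eff[:, None] * (
                -state + drive + p.constant_inputs[:, None])
        ref = hist[:, :, pad + burn_steps + 1:]
        assert np.allclose(run.traces, ref, rtol=1e-11, atol=1e-12)


class TestNoiseStatistics:
    @pytest.mark.parametrize("D", [1e-4, 4e-4])
    def test_stationary_variance_matches_ou_closed_form(self, params, D):
        """Gains off, the update is an OU process du = a(-u+i)dt + a*sqrt(2D)dW
        whose stationary variance is a*D."""
        p = _gain_free(params, D=D)
        run = ctwc.simulate_single_node(p, duration_ms=61000.0, seed=7)
        measured = run.traces[:, 0, :].var(axis=1)
        assert np.allclose(measured, p.alpha_eff * D, rtol=0.10)

    def test_variance_scales_linearly_with_d(self, params):
        p1 = _gain_free(params, D=1e-4)
        p4 = _gain_free(params, D=4e-4)
        v1 = ctwc.simulate_single_node(p1, duration_ms=31000.0, seed=3).e[0].var()
        v4 = ctwc.simulate_single_node(p4, duration_ms=31000.0, seed=3).e[0].var()
        assert v4 / v1 == pytest.approx(4.0, rel=0.15)


class TestNetworkConsistency:
    def test_uncoupled_network_nodes_match_isolated_node_spectrum(
            self, params, small_connectome):
        p = params.replace(g=0.0)
        net = ctwc.simulate(p, small_connectome, duration_ms=21000.0, seed=9)
        iso = ctwc.simulate_single_node(params, duration_ms=21000.0, seed=9)
        spec_iso = ctwc.welch_psd(iso.e[0], iso.fs, mode="peak")
        f_iso = ctwc.dominant_peak(spec_iso)
        # normalized cumulative spectral distribution over 1-45 Hz
        mask = (spec_iso.freqs >= 1) & (spec_iso.freqs <= 45)
        cdf_iso = np.cumsum(spec_iso.power[mask])
        cdf_iso /= cdf_iso[-1]
        for j in range(net.n_nodes):
            spec_j = ctwc.welch_psd(net.e[j], net.fs, mode="peak")
            assert abs(ctwc.dominant_peak(spec_j) - f_iso) <= 0.5
            cdf_j = np.cumsum(spec_j.power[mask])
            cdf_j /= cdf_j[-1]
            # Kolmogorov-Smirnov distance between spectral shapes
            assert np.max(np.abs(cdf_j - cdf_iso)) < 0.1

    def test_states_stay_bounded_at_nominal_parameters(self, params, small_connectome):
        long_run = ctwc.simulate_single_node(params, duration_ms=300000.0, seed=2)
        assert np.all(np.abs(long_run.traces) < 10.0)
        for g in (0.0, 5.0):
            net = ctwc.simulate(params.replace(g=g), small_connectome,
                                duration_ms=21000.0, seed=2, record_every=10)
            assert np.all(np.abs(net.traces) < 10.0)
            assert np.all(np.isfinite(net.traces))

    def test_numerical_blowup_raises_with_step_index(self, params):
        # an unstable step size (alpha_eff * dt >> 2) diverges immediately
        p = params.replace(dt=1e5, D=0.0)
        with pytest.raises(ctwc.SimulationBlowUpError, match="step"):
            ctwc.simulate_single_node(p, duration_ms=1e7, seed=0, burn_in_ms=2e5,
                                      initial_state=np.array([1.0, 1.0, 1.0, 1.0]))

    def test_duration_must_exceed_burn_in(self, params):
        with pytest.raises(ValueError, match="exceed"):
            ctwc.simulate_single_node(params, duration_ms=500.0, burn_in_ms=1000.0)
        with pytest.raises(ValueError, match="burn_in"):
            ctwc.simulate_single_node(params, duration_ms=2000.0, burn_in_ms=10.0)


class TestDownsample:
    def _sine_result(self, f_hz=10.0, fs=10000.0, dur_s=4.0):
        t = np.arange(1, int(dur_s * fs) + 1) / fs
        traces = np.tile(np.sin(2 * np.pi * f_hz * t), (4, 1, 1))
        return ctwc.SimulationResult(time=t * 1000.0, traces=traces, fs=fs,
                                     meta={"record_every": 1, "params": {"dt": 0.1}})

    def test_tone_amplitude_preserved_through_decimation(self):
        res = self._sine_result()
        out = ctwc.downsample(res, 1000.0)
        assert out.traces.shape[-1] == res.traces.shape[-1] // 10
        assert out.fs == 1000.0
        interior = out.e[0][100:-100]
        assert np.max(np.abs(interior)) == pytest.approx(1.0, rel=0.01)

    def test_identity_when_target_equals_native(self):
        res = self._sine_result()
        out = ctwc.downsample(res, res.fs)
        assert np.array_equal(out.traces, res.traces)

    def test_nyquist_guard_rejects_low_rates(self):
        res = self._sine_result()
        with pytest.raises(ValueError, match="Nyquist"):
            ctwc.downsample(res, 50.0)
        with pytest.raises(ValueError, match="exceeds"):
            ctwc.downsample(res, 20000.0)

    def test_non_divisor_rate_rejected(self):
        res = self._sine_result()
        with pytest.raises(ValueError, match="divide"):
            ctwc.downsample(res, 300.0)


class TestArchiveRoundTrip:
    def test_hdf5_save_load(self, params, tmp_path):
        run = ctwc.simulate_single_node(params, duration_ms=1500.0, seed=3)
        path = tmp_path / "run.h5"
        run.save(path)
        loaded = ctwc.SimulationResult.load(path)
        assert np.array_equal(loaded.traces, run.traces)
        assert np.array_equal(loaded.time, run.time)
        assert loaded.fs == run.fs
        assert loaded.meta["seed"] == 3
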