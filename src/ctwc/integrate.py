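"""Stochastic Euler-Maruyama integration of the delayed CTWC network.

The system integrated per node j and population p ∈ (e, i, r, s) is

    u_p ← u_p + dt·α_p·(−u_p + G_p + i_p + [g·Q_j + P_j]_e + [I_o^j]_s)
              + α_p·√(2·D·dt)·η,   η ~ N(0, 1) i.i.d.

where G_p is the within-node coupling (delayed across the
corticothalamic loop), Q_j the tract-delayed cortico-cortical afferent
sum, P_j = M_j·sin(2πωt) the sinusoidal cortical stimulus and I_o the
static thalamic relay drive.  Delay history is served from a ring
buffer; per-pair delays are rounded to integer steps (half away from
zero) with a floor of one step, so zero-delay pairs read the previous
step's value and the scheme stays explicit.

History before t = 0 is initialized to the constant-input vector
(i_e, i_i, i_r, i_s) so that a gain-free system starts at rest; a
burn-in interval is discarded before recording.  Runs are bitwise
reproducible for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit
from scipy import signal

from .connectome import Connectome
from .params import POPULATIONS, CTWCParameters, StimulusSpec

__all__ = [
    "SimulationResult",
    "SimulationBlowUpError",
    "simulate",
    "simulate_single_node",
    "downsample",
]


class SimulationBlowUpError(RuntimeError):
    """The state became non-finite (or left |u| < 1e3) during integration."""


@dataclass
class SimulationResult:
    """Regional time series for each network node.

    ``traces`` has shape (4, n_nodes, n_samples) in population order
    (e, i, r, s); ``time`` is in ms from the end of burn-in and is
    uniformly spaced at 1/fs.
    """

    time: np.ndarray
    traces: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.traces.shape[1]

    @property
    def e(self) -> np.ndarray:
        return self.traces[0]

    @property
    def i(self) -> np.ndarray:
        return self.traces[1]

    @property
    def r(self) -> np.ndarray:
        return self.traces[2]

    @property
    def s(self) -> np.ndarray:
        return self.traces[3]

    def save(self, path) -> None:
        """Write to an HDF5 archive: /time, /traces/{e,i,r,s}, /meta."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=self.time)
            grp = f.create_group("traces")
            for idx, pop in enumerate(POPULATIONS):
                grp.create_dataset(pop, data=self.traces[idx])
            f.attrs["fs"] = self.fs
            f.attrs["meta"] = json.dumps(self.meta, default=str)

    @classmethod
    def load(cls, path) -> "SimulationResult":
        import h5py

        with h5py.File(path, "r") as f:
            time = f["time"][()]
            traces = np.stack([f["traces"][pop][()] for pop in POPULATIONS])
            fs = float(f.attrs["fs"])
            meta = json.loads(f.attrs["meta"])
        return cls(time=time, traces=traces, fs=fs, meta=meta)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@njit(cache=False)
def _em_kernel(steps_total, burn_steps, record_every, alpha, ip, beta, sigma,
               w, nct, ntt, Wg, dsteps, io, m_amp, omega_hz, dt, noise_scale,
               seed, init, out):  # pragma: no cover - exercised via simulate()
    n = Wg.shape[0]
    max_d = nct if nct > ntt else ntt
    for j in range(n):
        for k in range(n):
            if dsteps[j, k] > max_d:
                max_d = dsteps[j, k]
    buf_len = max_d + 2  # +2: the write slot is never a live delayed read
    hist = np.empty((buf_len, 4, n))
    for b in range(buf_len):
        for p in range(4):
            for j in range(n):
                hist[b, p, j] = init[p, j]
    np.random.seed(seed)
    two_pi = 2.0 * np.pi
    rec = 0
    n_rec = out.shape[2]
    for t in range(steps_total):
        cur = t % buf_len
        nxt = (t + 1) % buf_len
        i_ct = (t - nct) % buf_len
        i_tt = (t - ntt) % buf_len
        ts_ms = (t - burn_steps) * dt
        for j in range(n):
            q = 0.0
            for k in range(n):
                wjk = Wg[j, k]
                if wjk != 0.0:
                    ue_d = hist[(t - dsteps[j, k]) % buf_len, 0, k]
                    q += wjk / (1.0 + np.exp(-beta * (ue_d - sigma)))
            fe = 1.0 / (1.0 + np.exp(-beta * (hist[cur, 0, j] - sigma)))
            fi = 1.0 / (1.0 + np.exp(-beta * (hist[cur, 1, j] - sigma)))
            fe_ct = 1.0 / (1.0 + np.exp(-beta * (hist[i_ct, 0, j] - sigma)))
            fs_ct = 1.0 / (1.0 + np.exp(-beta * (hist[i_ct, 3, j] - sigma)))
            fr_tt = 1.0 / (1.0 + np.exp(-beta * (hist[i_tt, 2, j] - sigma)))
            fs_tt = 1.0 / (1.0 + np.exp(-beta * (hist[i_tt, 3, j] - sigma)))
            stim = m_amp[j] * np.sin(two_pi * omega_hz * ts_ms / 1000.0)
            # drives per population: within-node coupling + exogenous terms
            g0 = w[0] * fe + w[2] * fi + w[7] * fs_ct + q + stim
            g1 = w[1] * fe + w[3] * fi + w[6] * fs_ct
            g2 = w[4] * fe_ct + w[9] * fs_tt
            g3 = w[5] * fe_ct + w[8] * fr_tt + io[j]
            for p in range(4):
                if p == 0:
                    gp = g0
                elif p == 1:
                    gp = g1
                elif p == 2:
                    gp = g2
                else:
                    gp = g3
                u = hist[cur, p, j]
                un = u + dt * alpha[p] * (-u + gp + ip[p]) \
                    + noise_scale[p] * np.random.standard_normal()
                if not np.isfinite(un) or abs(un) > 1e3:
                    return t
                hist[nxt, p, j] = un
        if t + 1 > burn_steps:
            off = t + 1 - burn_steps
            if off % record_every == 0 and rec < n_rec:
                for p in range(4):
                    for j in range(n):
                        out[p, j, rec] = hist[nxt, p, j]
                rec += 1
    return -1


def simulate(params: CTWCParameters, connectome: Connectome,
             stim: Optional[StimulusSpec] = None, duration_ms: float = 20000.0,
             seed: int = 0, burn_in_ms: float = 1000.0, record_every: int = 1,
             initial_state: Optional[np.ndarray] = None) -> SimulationResult:
    """Integrate the CTWC network and return post-burn-in traces.

    ``duration_ms`` is the total simulated time including burn-in;
    recorded traces cover ``duration_ms − burn_in_ms``.  ``record_every``
    strides the recording (native rate 1000/dt Hz); analyses that reach
    near the recorded Nyquist should use :func:`downsample` on a
    natively recorded run instead.

    Raises
    ------
    SimulationBlowUpError
        if the state becomes non-finite, naming the first offending step.
    """
    n = connectome.n_nodes
    if stim is None:
        stim = StimulusSpec.none(n)
    if stim.n_nodes != n:
        raise ValueError(f"stimulus is for {stim.n_nodes} nodes, connectome has {n}")
    dt = params.dt
    max_delay_ms = max(float(connectome.T.max()), params.tau_ct, params.tau_tt)
    if burn_in_ms < max_delay_ms:
        raise ValueError(
            f"burn_in_ms ({burn_in_ms}) must cover the maximum delay ({max_delay_ms} ms)"
        )
    if duration_ms <= burn_in_ms:
        raise ValueError(
            f"duration_ms ({duration_ms}) must exceed burn_in_ms ({burn_in_ms})"
        )
    if record_every < 1:
        raise ValueError("record_every must be a positive integer")

    steps_total = int(round(duration_ms / dt))
    burn_steps = int(round(burn_in_ms / dt))
    n_rec = (steps_total - burn_steps) // record_every
    if n_rec < 1:
        raise ValueError("no samples to record after burn-in")

    dsteps = np.maximum(_round_half_away(connectome.T / dt), 1.0).astype(np.int64)
    nct = max(1, int(_round_half_away(np.array(params.tau_ct / dt))))
    ntt = max(1, int(_round_half_away(np.array(params.tau_tt / dt))))
    Wg = params.g * connectome.normalized_weights(params.w_normalization)

    alpha = params.alpha_eff
    if params.noise_scaling == "alpha":
        noise_scale = alpha * np.sqrt(2.0 * params.D * dt)
    else:
        noise_scale = np.full(4, np.sqrt(2.0 * params.D * dt))

    if initial_state is None:
        init = np.tile(params.constant_inputs[:, None], (1, n))
    else:
        initial_state = np.asarray(initial_state, dtype=float)
        if initial_state.shape == (4,):
            init = np.tile(initial_state[:, None], (1, n))
        elif initial_state.shape == (4, n):
            init = initial_state.copy()
        else:
            raise ValueError(f"initial_state must have shape (4,) or (4, {n})")

    out = np.empty((4, n, n_rec))
    bad_step = _em_kernel(
        steps_total, burn_steps, record_every, alpha, params.constant_inputs,
        params.beta, params.sigma, params.gain_vector, nct, ntt,
        np.ascontiguousarray(Wg), dsteps, stim.i_o, stim.m, stim.omega_hz, dt,
        noise_scale, int(seed) & 0xFFFFFFFF, init, out,
    )
    if bad_step >= 0:
        raise SimulationBlowUpError(
            f"state became non-finite or exceeded |u|=1e3 at step {bad_step} "
            f"(t = {bad_step * dt:.1f} ms)"
        )

    fs = 1000.0 / (dt * record_every)
    time = (np.arange(n_rec) + 1) * (dt * record_every)
    meta = {
        "params": params.to_dict(),
        "seed": int(seed),
        "connectome_hash": connectome.content_hash(),
        "n_nodes": n,
        "duration_ms": duration_ms,
        "burn_in_ms": burn_in_ms,
        "record_every": record_every,
        "fs": fs,
        "stim": {
            "i_o_max": float(stim.i_o.max()), "m_max": float(stim.m.max()),
            "omega_hz": stim.omega_hz,
        },
    }
    return SimulationResult(time=time, traces=out, fs=fs, meta=meta)


def simulate_single_node(params: CTWCParameters, i_o: float = 0.0,
                         m: float = 0.0, omega_hz: float = 0.0,
                         duration_ms: float = 20000.0, seed: int = 0,
                         burn_in_ms: float = 1000.0, record_every: int = 1,
                         initial_state: Optional[np.ndarray] = None
                         ) -> SimulationResult:
    """One isolated corticothalamic motif (network path with a 1×1 zero
    connectome, so single-node and network runs agree bitwise)."""
    stim = StimulusSpec(i_o=np.array([i_o]), m=np.array([m]), omega_hz=omega_hz)
    return simulate(params, Connectome.single_node(), stim,
                    duration_ms=duration_ms, seed=seed, burn_in_ms=burn_in_ms,
                    record_every=record_every, initial_state=initial_state)


def downsample(result: SimulationResult, target_fs: float,
               max_analysis_hz: float = 45.0) -> SimulationResult:
    """Anti-alias (zero-phase low-pass) and decimate to ``target_fs``.

    ``target_fs`` must divide the recorded rate to within rounding and
    must leave headroom above twice the highest analysis frequency
    (120 Hz minimum for 45–60 Hz gamma work, hence the guard).
    """
    fs = result.fs
    if target_fs > fs:
        raise ValueError(f"target_fs {target_fs} exceeds recorded rate {fs}")
    if target_fs <= 2.0 * max_analysis_hz:
        raise ValueError(
            f"target_fs {target_fs} Hz violates the Nyquist guard for analyses "
            f"up to {max_analysis_hz} Hz (need > {2 * max_analysis_hz} Hz)"
        )
    q = fs / target_fs
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"target_fs must divide the recorded rate; fs/target = {q}")
    q = int(round(q))
    if q == 1:
        return SimulationResult(time=result.time.copy(), traces=result.traces.copy(),
                                fs=fs, meta=dict(result.meta))
    traces = result.traces
    stages = []
    while q > 10:  # decimate in stages to keep the IIR filter well conditioned
        for f in (10, 8, 5, 4, 3, 2):
            if q % f == 0:
                stages.append(f)
                q //= f
                break
        else:
            break
    stages.append(q)
    for stage in stages:
        if stage > 1:
            # FIR keeps the passband flat (IIR Chebyshev ripple costs ~1%)
            traces = signal.decimate(traces, stage, axis=-1, ftype="fir",
                                     zero_phase=True)
    n_out = traces.shape[-1]
    new_fs = fs / int(np.prod(stages))
    time = (np.arange(n_out) + 1) / new_fs * 1000.0
    meta = dict(result.meta)
    chain = list(meta.get("downsample_chain", []))
    chain.append({"from_fs": fs, "to_fs": new_fs, "stages": stages})
    meta["downsample_chain"] = chain
    meta["fs"] = new_fs
    return SimulationResult(time=time, traces=traces, fs=new_fs, meta=meta)
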