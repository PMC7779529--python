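"""Deterministic right-hand-side structure of the CTWC node.

These are the reference (pure NumPy) implementations of the sigmoid
activation, the within-node coupling across the four populations, and
the delayed cortico-cortical afferent sum.  The production integrator
re-implements the same arithmetic in a compiled kernel; agreement
between the two routes is asserted in the test suite.

State arrays follow the population order (e, i, r, s) on axis 0.
"""

from __future__ import annotations

import numpy as np
from scipy import special

from .params import CTWCParameters

__all__ = ["sigmoid", "local_coupling", "afferent_input"]


def sigmoid(u, beta: float = 20.0, sigma: float = 0.0):
    """Logistic response F(u) = 1 / (1 + exp(−β(u−σ))), bounded in (0, 1).

    β sets the gain (slope β/4 at threshold) and σ the activation
    threshold.  Strictly increasing in u.
    """
    if beta <= 0:
        raise ValueError("sigmoid gain beta must be positive")
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("sigmoid input must be finite")
    out = special.expit(beta * (u - sigma))
    return float(out) if out.ndim == 0 else out


def local_coupling(state, state_ct, state_tt, params: CTWCParameters):
    """Within-node drive to each population from its four partners.

    Parameters
    ----------
    state : array (4,) or (4, n)
        Current activity (e, i, r, s).
    state_ct : array, same shape
        Activity delayed by the corticothalamic/thalamocortical delay τ_ct.
    state_tt : array, same shape
        Activity delayed by the intrathalamic delay τ_tt.

    Returns
    -------
    array, same shape as ``state``
        Gain-weighted sigmoidal drive: cortical populations receive
        instantaneous cortical input plus τ_ct-delayed relay input;
        thalamic populations receive τ_ct-delayed cortical input plus
        τ_tt-delayed input from the other thalamic population.
    """
    state = np.asarray(state, dtype=float)
    state_ct = np.asarray(state_ct, dtype=float)
    state_tt = np.asarray(state_tt, dtype=float)
    if state.shape != state_ct.shape or state.shape != state_tt.shape:
        raise ValueError("state and delayed states must share a shape")
    p = params
    F = lambda u: sigmoid(u, p.beta, p.sigma)  # noqa: E731
    e, i = state[0], state[1]
    e_ct, s_ct = state_ct[0], state_ct[3]
    r_tt, s_tt = state_tt[2], state_tt[3]
    drive = np.empty_like(state)
    drive[0] = p.w_ee * F(e) + p.w_ie * F(i) + p.w_se * F(s_ct)
    drive[1] = p.w_ei * F(e) + p.w_ii * F(i) + p.w_si * F(s_ct)
    drive[2] = p.w_er * F(e_ct) + p.w_sr * F(s_tt)
    drive[3] = p.w_es * F(e_ct) + p.w_rs * F(r_tt)
    return drive


def afferent_input(delayed_ue_by_pair, W, params: CTWCParameters):
    """Delayed cortico-cortical afferent sum Q.

    Parameters
    ----------
    delayed_ue_by_pair : array (n, n)
        Entry [j, k] is the excitatory activity of source node k sampled
        at t − T[j, k].
    W : array (n, n)
        Connection weights, target rows / source columns.

    Returns
    -------
    array (n,)
        Q_j = Σ_k W[j, k] · F(u_e^k(t − T[j, k])).  The scaled quantity
        g·Q_j enters the drive of the excitatory population only.
    """
    U = np.asarray(delayed_ue_by_pair, dtype=float)
    W = np.asarray(W, dtype=float)
    if U.shape != W.shape or U.ndim != 2 or U.shape[0] != U.shape[1]:
        raise ValueError(f"shape mismatch: delayed activities {U.shape} vs weights {W.shape}")
    return np.sum(W * sigmoid(U, params.beta, params.sigma), axis=1)
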