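"""Model parameters and stimulation specifications.

The CTWC (cortico-thalamic Wilson-Cowan) node couples four neural
populations — cortical excitatory (e), cortical inhibitory (i), thalamic
reticular (r) and thalamic relay (s) — through gain-weighted sigmoidal
interactions with conduction delays.  :class:`CTWCParameters` holds the
nominal parameter set; :class:`StimulusSpec` describes per-node static
thalamic drive and sinusoidal cortical stimulation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["CTWCParameters", "StimulusSpec", "POPULATIONS"]

#: Population order used for all state arrays: cortical excitatory,
#: cortical inhibitory, thalamic reticular, thalamic relay.
POPULATIONS = ("e", "i", "r", "s")

_EXCITATORY_GAINS = ("w_ee", "w_ei", "w_er", "w_es", "w_si", "w_se", "w_sr")
_INHIBITORY_GAINS = ("w_ie", "w_ii", "w_rs")


@dataclass(frozen=True)
class CTWCParameters:
    """Nominal CTWC parameter set.

    Rate constants ``alpha_*`` are stored as tabulated; the effective
    rate in ms⁻¹ is ``alpha_* × rate_scale``.  The default
    ``rate_scale = 0.1`` corresponds to population time constants of
    33 ms (e), 20 ms (i) and 50 ms (r, s) — the standard neural-mass
    range — and is the unique scaling under which the model expresses
    the ~10 Hz idling rhythm, the ~30 Hz active rhythm and the
    idling→active transition near I_o ≈ 1.3 simultaneously (see
    docs/methods.md).

    Gain naming is source→target: ``w_xy`` is the projection gain from
    population x onto population y.  Inhibitory sources (i, r) carry
    negative gains.
    """

    # population rate constants (tabulated units; effective ms⁻¹ after rate_scale)
    alpha_e: float = 0.3
    alpha_i: float = 0.5
    alpha_s: float = 0.2
    alpha_r: float = 0.2
    rate_scale: float = 0.1

    # constant population inputs (mV)
    i_e: float = -0.35
    i_i: float = -0.3
    i_s: float = 0.5
    i_r: float = -0.8

    # connection gains (dimensionless, source→target)
    w_ee: float = 0.5
    w_ei: float = 1.0
    w_ie: float = -2.0
    w_ii: float = -0.5
    w_er: float = 0.6
    w_es: float = 0.6
    w_si: float = 0.2
    w_se: float = 1.65
    w_rs: float = -2.0
    w_sr: float = 2.0

    # conduction delays (ms)
    tau_ct: float = 20.0
    tau_tt: float = 5.0

    # noise intensity, global coupling, sigmoid shape
    D: float = 1e-4
    g: float = 5.0
    beta: float = 20.0
    sigma: float = 0.0

    # cortico-cortical conduction velocity (m/s) and integration step (ms)
    cv: float = 4.0
    dt: float = 0.1

    # numerical conventions (see docs/methods.md)
    noise_scaling: str = "alpha"     # "alpha": noise pre-multiplied by alpha_p; "unit": not
    w_normalization: str = "mean"    # "mean" | "max" | "row" | "none"

    def __post_init__(self) -> None:
        for name in ("alpha_e", "alpha_i", "alpha_s", "alpha_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.rate_scale <= 0:
            raise ValueError("rate_scale must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tau_ct < 0 or self.tau_tt < 0:
            raise ValueError("conduction delays must be non-negative")
        if self.D < 0:
            raise ValueError("noise intensity D must be non-negative")
        if self.beta <= 0:
            raise ValueError("sigmoid gain beta must be positive")
        if self.cv <= 0:
            raise ValueError("conduction velocity cv must be positive")
        for name in _INHIBITORY_GAINS:
            if getattr(self, name) > 0:
                raise ValueError(f"inhibitory gain {name} must be <= 0")
        for name in _EXCITATORY_GAINS:
            if getattr(self, name) < 0:
                raise ValueError(f"excitatory gain {name} must be >= 0")
        if self.noise_scaling not in ("alpha", "unit"):
            raise ValueError("noise_scaling must be 'alpha' or 'unit'")
        if self.w_normalization not in ("mean", "max", "row", "none"):
            raise ValueError("w_normalization must be 'mean', 'max', 'row' or 'none'")

    # -- derived quantities -------------------------------------------------

    @property
    def alpha_eff(self) -> np.ndarray:
        """Effective rate constants (ms⁻¹) in population order (e, i, r, s)."""
        return self.rate_scale * np.array(
            [self.alpha_e, self.alpha_i, self.alpha_r, self.alpha_s]
        )

    @property
    def constant_inputs(self) -> np.ndarray:
        """Constant inputs i_p (mV) in population order (e, i, r, s)."""
        return np.array([self.i_e, self.i_i, self.i_r, self.i_s])

    @property
    def gain_vector(self) -> np.ndarray:
        """All ten gains in the fixed order used by the integrator kernel."""
        return np.array([self.w_ee, self.w_ei, self.w_ie, self.w_ii,
                         self.w_er, self.w_es, self.w_si, self.w_se,
                         self.w_rs, self.w_sr])

    def replace(self, **kwargs) -> "CTWCParameters":
        return dataclasses.replace(self, **kwargs)

    # -- config I/O ---------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, overrides: Mapping) -> "CTWCParameters":
        """Build a parameter set from a flat key→value mapping.

        Unknown keys are rejected so that typos in config files fail
        loudly rather than silently running the nominal model.
        """
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(overrides) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**dict(overrides))


@dataclass(frozen=True)
class StimulusSpec:
    """Per-node drive: static thalamic input and sinusoidal cortical input.

    ``i_o`` (mV) targets only the thalamic relay population; the
    sinusoid ``m·sin(2π·omega_hz·t)`` targets only the cortical
    excitatory population.
    """

    i_o: np.ndarray = field(default_factory=lambda: np.zeros(1))
    m: np.ndarray = field(default_factory=lambda: np.zeros(1))
    omega_hz: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "i_o", np.atleast_1d(np.asarray(self.i_o, dtype=float)))
        object.__setattr__(self, "m", np.atleast_1d(np.asarray(self.m, dtype=float)))
        if self.i_o.shape != self.m.shape:
            raise ValueError(
                f"i_o and m must have the same length, got {self.i_o.shape} vs {self.m.shape}"
            )
        if np.any(self.m < 0):
            raise ValueError("sinusoid amplitudes m must be non-negative")
        if self.omega_hz < 0:
            raise ValueError("stimulation frequency must be non-negative")

    @property
    def n_nodes(self) -> int:
        return self.i_o.size

    @classmethod
    def none(cls, n_nodes: int = 1) -> "StimulusSpec":
        return cls(i_o=np.zeros(n_nodes), m=np.zeros(n_nodes))

    @classmethod
    def static(cls, i_o: float, n_nodes: int = 1) -> "StimulusSpec":
        """Uniform static thalamic drive at every node."""
        return cls(i_o=np.full(n_nodes, float(i_o)), m=np.zeros(n_nodes))

    @classmethod
    def focal(cls, node: int, i_o: float, n_nodes: int) -> "StimulusSpec":
        """Static thalamic drive at a single node, zero elsewhere."""
        if not 0 <= node < n_nodes:
            raise IndexError(f"node {node} out of range for {n_nodes} nodes")
        io = np.zeros(n_nodes)
        io[node] = float(i_o)
        return cls(i_o=io, m=np.zeros(n_nodes))

    @classmethod
    def sinusoid(cls, m: float, omega_hz: float, n_nodes: int = 1,
                 i_o: float = 0.0) -> "StimulusSpec":
        """Uniform sinusoidal cortical stimulation, optionally on top of
        uniform static thalamic drive."""
        return cls(i_o=np.full(n_nodes, float(i_o)),
                   m=np.full(n_nodes, float(m)), omega_hz=float(omega_hz))
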