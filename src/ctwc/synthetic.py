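"""Seeded generators for synthetic connectomes and target spectra.

The connectome generator emulates the statistical features of a
group-average tractography matrix that the model actually consumes:
hemispheric block structure (stronger intra- than inter-hemispheric
weights), distance-decayed log-normal weights, symmetric non-negative
matrices with zero diagonal, and tract lengths inside the (10, 250) mm
range that survives standard streamline length filtering.  No attempt is
made to match edge-level values of any empirical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import Connectome
from .spectral import Spectrum

__all__ = ["SyntheticConnectomeSpec", "generate_connectome", "generate_target_spectrum"]


@dataclass(frozen=True)
class SyntheticConnectomeSpec:
    """Recipe for a hemispherically structured random connectome.

    ``intra_hemisphere_bias`` is the ratio of mean intra- to
    inter-hemispheric weight before thresholding (> 1); ``density`` the
    fraction of off-diagonal pairs kept nonzero; weights follow a
    log-normal law attenuated with distance scale ``distance_decay_mm``.
    """

    n_nodes: int = 68
    hemispheres: int = 2
    intra_hemisphere_bias: float = 3.0
    density: float = 0.4
    weight_mu: float = 0.0
    weight_sigma: float = 1.0
    distance_decay_mm: float = 80.0
    length_range_mm: tuple = (10.0, 250.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if self.hemispheres != 2:
            raise ValueError("only the two-hemisphere layout is supported")
        if not 0 < self.density <= 1:
            raise ValueError(f"density must lie in (0, 1], got {self.density}")
        if self.intra_hemisphere_bias < 1:
            raise ValueError("intra_hemisphere_bias must be >= 1")
        lo, hi = self.length_range_mm
        if not 0 < lo < hi:
            raise ValueError("length_range_mm must satisfy 0 < lo < hi")


def generate_connectome(spec: SyntheticConnectomeSpec, cv: float = 4.0) -> Connectome:
    """Generate a symmetric, distance-dependent synthetic connectome.

    Nodes are placed in two lateralized 3-D clusters; tract lengths are
    Euclidean distances affinely mapped into the interior of
    ``length_range_mm``; weights are distance-decayed log-normal draws
    with the inter-hemispheric block attenuated by the bias factor,
    symmetrized, thresholded to the requested density and scaled to a
    maximum of one.  Deterministic for a given spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    n_left = n // 2
    hemi = np.zeros(n, dtype=int)
    hemi[n_left:] = 1
    # two blobs separated along x, ~anatomical spread along y/z
    centers = np.array([[-35.0, 0.0, 0.0], [35.0, 0.0, 0.0]])
    coords = centers[hemi] + rng.normal(scale=[18.0, 40.0, 30.0], size=(n, 3))

    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    lo, hi = spec.length_range_mm
    # map observed distances into the interior of the admissible range
    off = ~np.eye(n, dtype=bool)
    dmin, dmax = dist[off].min(), dist[off].max()
    span = dmax - dmin if dmax > dmin else 1.0
    L = (lo + 5.0) + (dist - dmin) / span * ((hi - 5.0) - (lo + 5.0))
    L = 0.5 * (L + L.T)
    np.fill_diagonal(L, 0.0)

    raw = rng.lognormal(mean=spec.weight_mu, sigma=spec.weight_sigma, size=(n, n))
    raw *= np.exp(-L / spec.distance_decay_mm)
    inter = hemi[:, None] != hemi[None, :]
    raw[inter] /= spec.intra_hemisphere_bias
    W = np.triu(raw, k=1)
    W = W + W.T

    if spec.density < 1:
        iu = np.triu_indices(n, k=1)
        vals = W[iu]
        k = int(round(spec.density * vals.size))
        if k < 1:
            raise ValueError("density too low: no edges survive")
        thresh = np.sort(vals)[vals.size - k]
        W[W < thresh] = 0.0
    np.fill_diagonal(W, 0.0)
    W /= W.max()

    labels = [f"{'L' if h == 0 else 'R'}{idx:02d}" for idx, h in enumerate(hemi)]
    return Connectome.from_matrices(W, L, cv=cv, labels=labels)


def generate_target_spectrum(peak_hz: float = 10.0, peak_width: float = 2.0,
                             one_over_f_exponent: float = 1.0,
                             noise_sd: float = 0.1, amplitude: float = 1.0,
                             bump_height: float = 4.0,
                             freq_grid=None, seed: int = 0) -> Spectrum:
    """Smooth alpha-peaked power spectrum standing in for a resting
    M/EEG average: a 1/f^exponent background plus a Gaussian bump at
    ``peak_hz``, under multiplicative log-normal noise.

    The file is marked synthetic by construction — it is generated, not
    measured.  ``bump_height`` is the bump amplitude relative to the
    background at the peak frequency.
    """
    if freq_grid is None:
        freq_grid = np.arange(1.0, 45.0 + 0.25, 0.5)
    freq_grid = np.asarray(freq_grid, dtype=float)
    if np.any(freq_grid <= 0):
        raise ValueError("frequency grid must be strictly positive")
    if not freq_grid[0] <= peak_hz <= freq_grid[-1]:
        raise ValueError("peak_hz must lie inside the frequency grid")
    rng = np.random.default_rng(seed)
    background = freq_grid ** (-one_over_f_exponent)
    bump = (bump_height * peak_hz ** (-one_over_f_exponent)
            * np.exp(-0.5 * ((freq_grid - peak_hz) / peak_width) ** 2))
    power = amplitude * (background + bump)
    if noise_sd > 0:
        power = power * rng.lognormal(mean=0.0, sigma=noise_sd, size=freq_grid.size)
    return Spectrum(freqs=freq_grid, power=power,
                    meta={"synthetic": True, "peak_hz": peak_hz,
                          "peak_width": peak_width,
                          "one_over_f_exponent": one_over_f_exponent,
                          "noise_sd": noise_sd, "seed": seed})
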