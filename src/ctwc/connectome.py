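"""Structural connectome container and delimited-text I/O.

``W[j, k]`` is the strength of the projection from node k onto node j
(target rows, source columns); ``L`` holds tract lengths in mm and the
conduction-delay matrix ``T = L / cv`` is in ms (mm divided by m/s gives
ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Connectome", "delay_matrix", "load_connectome", "save_connectome"]


def delay_matrix(L: np.ndarray, cv: float) -> np.ndarray:
    """Conduction delays (ms) from tract lengths (mm) at velocity cv (m/s).

    mm / (m/s) = ms, so the division is unit-exact.  Zero lengths map to
    zero delays; the zero diagonal is preserved.
    """
    if cv <= 0:
        raise ValueError(f"conduction velocity must be positive, got {cv}")
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("tract lengths must be non-negative")
    return L / cv


@dataclass(frozen=True)
class Connectome:
    """Weights, tract lengths and derived conduction delays over N regions."""

    W: np.ndarray
    L: np.ndarray
    T: np.ndarray
    labels: tuple = field(default=())

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    @classmethod
    def from_matrices(cls, W, L, cv: float = 4.0, labels=None) -> "Connectome":
        """Validate matrices and derive T = L/cv.

        Raises on non-square or negative input; a nonzero diagonal is
        warned about and zeroed rather than rejected, since group-average
        tractography matrices occasionally carry self-loop counts.
        """
        W = np.array(W, dtype=float)
        L = np.array(L, dtype=float)
        for name, M in (("W", W), ("L", L)):
            if M.ndim != 2 or M.shape[0] != M.shape[1]:
                raise ValueError(f"{name} must be square, got shape {M.shape}")
            if not np.all(np.isfinite(M)):
                bad = np.argwhere(~np.isfinite(M))[0]
                raise ValueError(f"{name} has non-finite entry at {tuple(bad)}")
            if np.any(M < 0):
                bad = np.argwhere(M < 0)[0]
                raise ValueError(f"{name} has negative entry at row {bad[0]}, column {bad[1]}")
            if np.any(np.diag(M) != 0):
                warnings.warn(f"{name} has a nonzero diagonal; zeroing it", stacklevel=2)
                np.fill_diagonal(M, 0.0)
        if W.shape != L.shape:
            raise ValueError(f"W and L shapes differ: {W.shape} vs {L.shape}")
        if np.any((W > 0) & (L <= 0)):
            bad = np.argwhere((W > 0) & (L <= 0))[0]
            raise ValueError(
                f"connected pair (row {bad[0]}, column {bad[1]}) has zero tract length"
            )
        if labels is None:
            labels = tuple(f"node{i}" for i in range(W.shape[0]))
        else:
            labels = tuple(str(x) for x in labels)
            if len(labels) != W.shape[0]:
                raise ValueError("label count does not match matrix size")
        return cls(W=W, L=L, T=delay_matrix(L, cv), labels=labels)

    @classmethod
    def single_node(cls, label: str = "node0") -> "Connectome":
        """The 1×1 zero connectome of an isolated node."""
        z = np.zeros((1, 1))
        return cls.from_matrices(z, z, labels=(label,))

    def normalized_weights(self, scheme: str = "mean") -> np.ndarray:
        """W rescaled before the global coupling g is applied.

        "mean" (default) divides by the largest entry and by the node
        count, making g·Q a g-scaled weighted *mean-field* of afferent
        activity: total long-range drive stays O(g·F) regardless of
        network size, which keeps the cortical populations inside their
        dynamic range (a weighted *sum* at g = 5 drives them into
        sigmoid saturation and silences every network phenomenon).
        "max" divides by the largest entry only; "row" divides each
        target row by its sum; "none" returns W unchanged.
        """
        W = self.W
        if scheme == "none" or not np.any(W > 0):
            return W.copy()
        if scheme == "mean":
            return W / (W.max() * self.n_nodes)
        if scheme == "max":
            return W / W.max()
        if scheme == "row":
            sums = W.sum(axis=1, keepdims=True)
            sums[sums == 0] = 1.0
            return W / sums
        raise ValueError(f"unknown normalization scheme {scheme!r}")

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.W).tobytes())
        h.update(np.ascontiguousarray(self.L).tobytes())
        return h.hexdigest()[:16]


def _read_matrix(path) -> tuple[np.ndarray, tuple | None]:
    """Read a square delimited matrix, tolerating an optional header row
    of region labels."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep, header=None, float_precision="round_trip")
        labels = None
        if df.dtypes.apply(lambda d: d == object).any():
            df = pd.read_csv(path, sep=sep, header=0, float_precision="round_trip")
            labels = tuple(str(c) for c in df.columns)
        values = df.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path} does not parse as a numeric matrix: {exc}") from exc
    return values, labels


def load_connectome(path_w, path_l, cv: float = 4.0) -> Connectome:
    """Load weight and length matrices from delimited text (CSV/TSV)."""
    W, labels_w = _read_matrix(path_w)
    L, labels_l = _read_matrix(path_l)
    labels = labels_w or labels_l
    return Connectome.from_matrices(W, L, cv=cv, labels=labels)


def save_connectome(conn: Connectome, path_w, path_l, header: bool = True) -> None:
    """Write W and L as delimited text, optionally with a label header.

    Values are written with the shortest round-trip representation so a
    write→read cycle reproduces them bit-exactly.
    """
    for M, path in ((conn.W, path_w), (conn.L, path_l)):
        with open(path, "w") as f:
            if header:
                f.write(",".join(conn.labels) + "\n")
            for row in M:
                f.write(",".join(repr(float(v)) for v in row) + "\n")
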