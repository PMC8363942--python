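"""Diffusion-encoding protocols and b-tensors.

A b-tensor summarises a diffusion-encoding gradient waveform as a symmetric
3x3 matrix whose trace is the b-value.  Axially symmetric b-tensors are
described by (b, b_delta, n): b_delta = 1 is linear tensor encoding (LTE,
conventional single-direction weighting), b_delta = 0 is spherical tensor
encoding (STE, isotropic weighting) and b_delta = -1/2 is planar encoding.

Units
-----
b-values are stored internally in ms/um^2 (1 ms/um^2 = 1000 s/mm^2) so that
``b * diffusivity`` is dimensionless when diffusivities are in um^2/ms.
Scheme files and protocol JSON use the conventional s/mm^2; conversion
happens at the I/O boundary via :data:`B_FROM_SI`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "B_FROM_SI",
    "GYROMAGNETIC_RATIO",
    "BTensor",
    "Shell",
    "Protocol",
    "GradientWaveform",
    "make_btensor",
    "btensor_from_waveform",
    "shape_of",
    "fibonacci_directions",
    "default_protocol",
    "load_protocol",
    "save_protocol",
    "read_scheme",
    "write_scheme",
]

#: multiply a b-value in s/mm^2 by this to get ms/um^2
B_FROM_SI = 1e-3

#: proton gyromagnetic ratio, rad / (s T)
GYROMAGNETIC_RATIO = 2.6752218744e8

_TRACE_RTOL = 1e-9


@dataclass(frozen=True)
class BTensor:
    """Symmetric positive semi-definite 3x3 diffusion-weighting tensor."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"b-tensor must be 3x3, got {m.shape}")
        if not np.allclose(m, m.T, atol=1e-12 * max(1.0, abs(m).max())):
            raise ValueError("b-tensor must be symmetric")
        w = np.linalg.eigvalsh(0.5 * (m + m.T))
        if w.min() < -1e-9 * max(1.0, w.max()):
            raise ValueError(f"b-tensor must be positive semi-definite, eigenvalues {w}")
        object.__setattr__(self, "matrix", 0.5 * (m + m.T))

    @property
    def b(self) -> float:
        """Trace of the tensor (the b-value)."""
        return float(np.trace(self.matrix))


@dataclass(frozen=True)
class Shell:
    """One powder-averaged measurement shell.

    Parameters
    ----------
    b : float
        Diffusion weighting in ms/um^2.
    b_delta : float
        B-tensor shape, in [-1/2, 1].
    n_dirs : int
        Number of uniformly distributed waveform rotations in the shell.
    """

    b: float
    b_delta: float
    n_dirs: int

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError(f"b must be non-negative, got {self.b}")
        if not -0.5 <= self.b_delta <= 1.0:
            raise ValueError(f"b_delta must be in [-1/2, 1], got {self.b_delta}")
        if self.n_dirs < 1:
            raise ValueError(f"n_dirs must be >= 1, got {self.n_dirs}")


@dataclass(frozen=True)
class Protocol:
    """Ordered collection of shells plus echo time and b=0 count.

    The shell order is part of the protocol identity: an estimator trained on
    a protocol refuses signal vectors from any other (see :meth:`fingerprint`).
    """

    shells: tuple[Shell, ...]
    te: float = 0.094  #: echo time, s
    n_b0: int = 12

    def __post_init__(self) -> None:
        object.__setattr__(self, "shells", tuple(self.shells))
        if not self.shells:
            raise ValueError("protocol needs at least one shell")
        if self.te <= 0:
            raise ValueError("te must be positive")

    @property
    def n_shells(self) -> int:
        return len(self.shells)

    @property
    def b(self) -> np.ndarray:
        return np.array([s.b for s in self.shells])

    @property
    def b_delta(self) -> np.ndarray:
        return np.array([s.b_delta for s in self.shells])

    @property
    def n_dirs(self) -> np.ndarray:
        return np.array([s.n_dirs for s in self.shells])

    def fingerprint(self) -> str:
        """Hash of (ordered shell b, b_delta, n_dirs, TE, n_b0)."""
        payload = {
            "shells": [[round(s.b, 9), round(s.b_delta, 9), s.n_dirs] for s in self.shells],
            "te": round(self.te, 9),
            "n_b0": self.n_b0,
        }
        blob = json.dumps(payload, separators=(",", ":")).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class GradientWaveform:
    """Sampled spin-echo gradient waveform.

    samples : (3, N) gradient amplitudes in mT/m; dt : sample spacing in s;
    rf_flip_index : index of the 180-degree refocusing pulse, after which the
    effective gradient sign is inverted.
    """

    samples: np.ndarray
    dt: float
    rf_flip_index: int = 0

    def __post_init__(self) -> None:
        g = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if g.shape[0] != 3:
            raise ValueError(f"waveform must be (3, N), got {g.shape}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 <= self.rf_flip_index <= g.shape[1]:
            raise ValueError("rf_flip_index outside waveform")
        object.__setattr__(self, "samples", g)

    def effective_gradient(self) -> np.ndarray:
        g = self.samples.copy()
        g[:, self.rf_flip_index:] *= -1.0
        return g

    def q_of_t(self) -> np.ndarray:
        """Dephasing trajectory q(t) = gamma * int_0^t G dt', rad/m; shape (3, N+1)."""
        g_si = self.effective_gradient() * 1e-3  # mT/m -> T/m
        q = np.concatenate(
            [np.zeros((3, 1)), np.cumsum(g_si, axis=1) * self.dt], axis=1
        )
        return GYROMAGNETIC_RATIO * q


def make_btensor(b: float, b_delta: float, n) -> BTensor:
    """Build an axially symmetric b-tensor b_delta*b*nn' + b/3*(1-b_delta)*I.

    ``b`` is returned in the units it is given in; the trace equals ``b``
    exactly.  ``n`` must be a unit 3-vector (it is irrelevant when
    b_delta = 0).
    """
    if b < 0:
        raise ValueError(f"b must be non-negative, got {b}")
    if not -0.5 <= b_delta <= 1.0:
        raise ValueError(f"b_delta must be in [-1/2, 1], got {b_delta}")
    n = np.asarray(n, dtype=float).reshape(3)
    norm = np.linalg.norm(n)
    if not np.isclose(norm, 1.0, atol=1e-8):
        raise ValueError(f"direction must be a unit vector, |n| = {norm}")
    n = n / norm
    m = b_delta * b * np.outer(n, n) + (b / 3.0) * (1.0 - b_delta) * np.eye(3)
    return BTensor(m)


def btensor_from_waveform(w: GradientWaveform, *, rtol: float = 1e-6) -> BTensor:
    """Integrate q q' over the waveform duration (trapezoidal quadrature).

    The result is in s/mm^2.  Raises if the waveform does not rephase,
    i.e. if q(TE) is not negligible relative to the peak |q|.
    """
    q = w.q_of_t()  # rad/m, (3, N+1)
    q_te = q[:, -1]
    q_peak = np.linalg.norm(q, axis=0).max()
    if q_peak > 0 and np.linalg.norm(q_te) > 1e-6 * q_peak + 1e-30:
        raise ValueError(
            f"waveform does not rephase: |q(TE)| = {np.linalg.norm(q_te):.3e} rad/m"
        )
    t = np.arange(q.shape[1]) * w.dt
    outer = q[:, None, :] * q[None, :, :]  # (3, 3, N+1)
    b_si = np.trapezoid(outer, t, axis=2)  # s/m^2
    return BTensor(b_si * 1e-6)  # s/m^2 -> s/mm^2


def shape_of(bt: BTensor, *, rtol: float = 1e-6) -> tuple[float, float]:
    """Recover (b, b_delta) of an axially symmetric b-tensor.

    Inverse of :func:`make_btensor` up to the (unreported) symmetry axis.
    Raises if the two transverse eigenvalues differ by more than ``rtol``
    relative to the b-value.
    """
    w = np.sort(np.linalg.eigvalsh(bt.matrix))
    b = float(w.sum())
    if b == 0:
        return 0.0, 0.0
    scale = max(abs(b), abs(w).max())
    # the axial eigenvalue is the one furthest from the other two
    if abs(w[1] - w[0]) <= abs(w[2] - w[1]):
        perp, axial = 0.5 * (w[0] + w[1]), w[2]
        spread = abs(w[1] - w[0])
    else:
        perp, axial = 0.5 * (w[1] + w[2]), w[0]
        spread = abs(w[2] - w[1])
    if spread > rtol * scale:
        raise ValueError(f"b-tensor is not axially symmetric: eigenvalues {w}")
    b_delta = (axial - perp) / b
    return b, float(b_delta)


def fibonacci_directions(n: int, *, seed: int = 0) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors on the sphere, shape (n, 3).

    Fibonacci lattice with a seed-dependent golden-angle offset so that
    distinct seeds give rotated (still uniform) point sets.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * (i / phi + seed * phi)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def split_directions(total: int, n_shells: int) -> list[int]:
    """Split a per-encoding direction budget across shells.

    Equal split; any remainder is assigned to the last (highest-b) shells.
    """
    base, rem = divmod(total, n_shells)
    out = [base] * n_shells
    for k in range(rem):
        out[n_shells - 1 - k] += 1
    if min(out) < 1:
        raise ValueError(f"cannot split {total} directions over {n_shells} shells")
    return out


# in-vivo acquisition: 4 STE + 4 LTE shells, 128 directions per encoding
_STE_B_SI = (500.0, 1000.0, 1500.0, 2000.0)
_LTE_B_SI = (1000.0, 2000.0, 3500.0, 5000.0)


def default_protocol(
    n_dirs_per_encoding: int = 128, te: float = 0.094, n_b0: int = 12
) -> Protocol:
    """The 8-shell LTE+STE protocol used throughout this package.

    STE at b = 500/1000/1500/2000 s/mm^2 (b_delta = 0) and LTE at
    b = 1000/2000/3500/5000 s/mm^2 (b_delta = 1), with
    ``n_dirs_per_encoding`` waveform rotations split over the four shells
    of each encoding. TE = 94 ms, 12 b=0 volumes.
    """
    shells = []
    for b_list, bdel in ((_STE_B_SI, 0.0), (_LTE_B_SI, 1.0)):
        counts = split_directions(n_dirs_per_encoding, len(b_list))
        shells += [
            Shell(b * B_FROM_SI, bdel, nd) for b, nd in zip(b_list, counts)
        ]
    return Protocol(tuple(shells), te=te, n_b0=n_b0)


# ---------------------------------------------------------------------------
# serialisation


def save_protocol(protocol: Protocol, path) -> None:
    """Write protocol JSON (b-values in s/mm^2, TE in ms)."""
    doc = {
        "shells": [
            {"b": s.b / B_FROM_SI, "bdelta": s.b_delta, "ndirs": s.n_dirs}
            for s in protocol.shells
        ],
        "te_ms": protocol.te * 1e3,
        "nb0": protocol.n_b0,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_protocol(path) -> Protocol:
    doc = json.loads(Path(path).read_text())
    shells = tuple(
        Shell(s["b"] * B_FROM_SI, s["bdelta"], int(s["ndirs"])) for s in doc["shells"]
    )
    return Protocol(shells, te=doc["te_ms"] * 1e-3, n_b0=int(doc["nb0"]))


def write_scheme(protocol: Protocol, path, *, seed: int = 0) -> np.ndarray:
    """Write a per-volume scheme table: ``# b bdelta nx ny nz`` (b in s/mm^2).

    b=0 rows come first, then each shell's directions.  Returns the table.
    """
    rows = [np.zeros((protocol.n_b0, 5))]
    for i, s in enumerate(protocol.shells):
        dirs = fibonacci_directions(s.n_dirs, seed=seed + i)
        block = np.column_stack(
            [np.full(s.n_dirs, s.b / B_FROM_SI), np.full(s.n_dirs, s.b_delta), dirs]
        )
        rows.append(block)
    table = np.vstack(rows)
    header = "b bdelta nx ny nz"
    np.savetxt(path, table, fmt="%.6f", header=header)
    return table


def read_scheme(path) -> np.ndarray:
    """Read a scheme table written by :func:`write_scheme`; shape (n_vol, 5)."""
    table = np.atleast_2d(np.loadtxt(path, comments="#"))
    if table.shape[1] != 5:
        raise ValueError(f"scheme table must have 5 columns, got {table.shape[1]}")
    return table
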