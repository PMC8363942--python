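"""Volume I/O and powder averaging of directional diffusion data.

A 4-D diffusion-weighted volume plus a per-volume scheme table (b-value,
b-tensor shape, direction) is reduced to a :class:`PowderVolume`: per-voxel
T2-normalised shell means, a noise map estimated from the b=0 repeats, and a
mask.  Shell order follows the protocol, so the result plugs straight into a
matching trained estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocol import B_FROM_SI, Protocol

__all__ = ["PowderVolume", "powder_average", "load_nifti", "save_nifti"]


@dataclass
class PowderVolume:
    """Shell-mean signals for a volume.

    data : (x, y, z, n_shells) T2-normalised shell means;
    sigma : (x, y, z) per-measurement noise standard deviation;
    mask : (x, y, z) boolean, True where voxels are valid;
    affine : 4x4 voxel-to-world matrix carried through from the input.
    """

    data: np.ndarray
    sigma: np.ndarray
    mask: np.ndarray
    protocol: Protocol
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, shell)")
        if self.data.shape[-1] != self.protocol.n_shells:
            raise ValueError(
                f"shell axis {self.data.shape[-1]} does not match protocol "
                f"({self.protocol.n_shells} shells)"
            )
        if self.sigma.shape != self.data.shape[:3] or self.mask.shape != self.data.shape[:3]:
            raise ValueError("sigma and mask must match the spatial grid")

    @property
    def fingerprint(self) -> str:
        return self.protocol.fingerprint()


def _match_shell(b_si: float, b_delta: float, protocol: Protocol) -> int:
    for i, s in enumerate(protocol.shells):
        if abs(s.b - b_si * B_FROM_SI) < 1e-6 and abs(s.b_delta - b_delta) < 1e-6:
            return i
    raise ValueError(f"scheme row (b={b_si} s/mm^2, bdelta={b_delta}) "
                     "matches no protocol shell")


def powder_average(dwi: np.ndarray, scheme: np.ndarray, protocol: Protocol,
                   affine: np.ndarray | None = None,
                   b0_threshold: float = 50.0) -> PowderVolume:
    """Reduce directional 4-D data to per-shell powder means.

    ``scheme`` rows are (b [s/mm^2], b_delta, nx, ny, nz), one per volume.
    Per voxel: S0 = mean over b=0 volumes (b below ``b0_threshold``), shell
    mean of S/S0 per (b, b_delta) group, and sigma = the powder-mean noise
    level: the standard deviation of the b=0 repeats normalised by S0 and
    divided by the square root of the average per-shell direction count
    (the shell means average that many rotations).  Voxels with
    non-positive S0 are masked out.
    """
    dwi = np.asarray(dwi, dtype=float)
    scheme = np.atleast_2d(np.asarray(scheme, dtype=float))
    if dwi.ndim != 4:
        raise ValueError("dwi must be 4-D (x, y, z, volume)")
    if scheme.shape[0] != dwi.shape[-1]:
        raise ValueError(
            f"scheme rows ({scheme.shape[0]}) must match volume count ({dwi.shape[-1]})"
        )
    is_b0 = scheme[:, 0] < b0_threshold
    if not np.any(is_b0):
        raise ValueError("no b=0 volumes in the scheme")
    groups: dict[int, list[int]] = {i: [] for i in range(protocol.n_shells)}
    for row in np.nonzero(~is_b0)[0]:
        groups[_match_shell(scheme[row, 0], scheme[row, 1], protocol)].append(row)
    missing = [i for i, rows in groups.items() if not rows]
    if missing:
        raise ValueError(f"scheme has no volumes for protocol shells {missing}")

    s0 = dwi[..., is_b0].mean(axis=-1)
    valid = s0 > 0
    s0_safe = np.where(valid, s0, 1.0)
    shell_means = np.stack(
        [dwi[..., rows].mean(axis=-1) / s0_safe for rows in groups.values()], axis=-1
    )
    shell_means[~valid] = 0.0
    n_b0 = int(is_b0.sum())
    n_mean_dirs = float(np.mean(protocol.n_dirs))
    if n_b0 > 1:
        sigma = dwi[..., is_b0].std(axis=-1, ddof=1) / s0_safe / np.sqrt(n_mean_dirs)
    else:
        sigma = np.zeros_like(s0)
    sigma[~valid] = 0.0
    return PowderVolume(shell_means, sigma, valid, protocol,
                        affine if affine is not None else np.eye(4))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, affine)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_nifti(data: np.ndarray, affine: np.ndarray, path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
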