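"""Priors for training and evaluating the estimator.

Volume fractions (v_cyl, v_sph, v_ext) are uniform on the 2-simplex.
Diffusivities cover the constrained triangle 0 <= lambda_sph <= lambda_cyl
<= lambda_free by drawing the scaled increments
(lambda_sph, lambda_cyl - lambda_sph, lambda_free - lambda_cyl) / lambda_free
uniformly on a 2-simplex.  Noise standard deviations are log-uniform on
[0.01, 1], a scale-invariant prior spanning SNR 1-100 for unit b=0 signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal import LAMBDA_FREE, TissueParams

__all__ = [
    "PriorConfig",
    "sample_tissue_params",
    "sample_sigma",
    "simplex_grid",
    "diffusivity_grid",
]


@dataclass(frozen=True)
class PriorConfig:
    """Sampling configuration for synthetic training data."""

    n_samples: int = 2 ** 20
    sigma_min: float = 0.01
    sigma_max: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not 0 < self.sigma_min <= self.sigma_max:
            raise ValueError("need 0 < sigma_min <= sigma_max")


def sample_tissue_params(n: int, rng: np.random.Generator | int | None = None
                         ) -> TissueParams:
    """Draw ``n`` parameter sets uniformly over the constrained space."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    fractions = rng.dirichlet(np.ones(3), size=n)
    incr = rng.dirichlet(np.ones(3), size=n) * LAMBDA_FREE
    lambda_sph = incr[:, 0]
    lambda_cyl = incr[:, 0] + incr[:, 1]
    return TissueParams(
        fractions[:, 0], fractions[:, 1], fractions[:, 2], lambda_cyl, lambda_sph
    )


def sample_sigma(n: int, rng: np.random.Generator | int | None = None,
                 sigma_min: float = 0.01, sigma_max: float = 1.0) -> np.ndarray:
    """Draw ``n`` noise levels with log(sigma) uniform on [log min, log max]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return np.exp(rng.uniform(np.log(sigma_min), np.log(sigma_max), size=n))


def simplex_grid(step: float = 0.05) -> np.ndarray:
    """All non-negative fraction triples on the simplex lattice, shape (m, 3).

    ``1/step`` must be an integer; step 0.05 yields 231 triples.
    """
    k = 1.0 / step
    if abs(k - round(k)) > 1e-9:
        raise ValueError("step must divide 1")
    k = int(round(k))
    pts = [
        (i * step, j * step, (k - i - j) * step)
        for i in range(k + 1)
        for j in range(k + 1 - i)
    ]
    return np.asarray(pts)


def diffusivity_grid(lo: float = 0.5, hi: float = LAMBDA_FREE, step: float = 0.5
                     ) -> np.ndarray:
    """(lambda_cyl, lambda_sph) pairs on a regular grid with sph <= cyl."""
    vals = np.arange(lo, hi + 1e-9, step)
    return np.asarray([(lc, ls) for lc in vals for ls in vals if ls <= lc])
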