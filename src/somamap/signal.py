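"""Three-compartment powder-averaged signal model and its violated variants.

Brain tissue is modelled as three Gaussian compartments within each
microscopic domain: quasi-cylindrical neural projections (zero-radius sticks
with parallel diffusivity ``lambda_cyl``), quasi-spherical neural soma
(isotropic apparent diffusivity ``lambda_sph``) and extra-cellular space
whose axially symmetric tensor follows a tortuosity approximation driven by
the volume fractions.  Powder averaging over waveform rotations removes the
orientation distribution, leaving four independent parameters:
v_cyl, v_sph, lambda_cyl, lambda_sph (v_ext = 1 - v_cyl - v_sph).

The powder-averaged signal of an axially symmetric compartment under an
axially symmetric b-tensor (b, b_delta) is

    h = sqrt(pi)/2 * erf(sqrt(x))/sqrt(x)
        * exp(-b * [(1-b_delta)/3 * l_par + (2+b_delta)/3 * l_perp]),
    x = b * b_delta * (l_par - l_perp),

with erf(sqrt(x))/sqrt(x) -> 2/sqrt(pi) as x -> 0.  For b_delta < 0 the
factor continues through the imaginary error function.

All b-values here are in ms/um^2, diffusivities in um^2/ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .protocol import BTensor, Protocol, Shell

__all__ = [
    "LAMBDA_FREE",
    "TissueParams",
    "CompartmentTensor",
    "ViolationConfig",
    "tortuosity",
    "compartment_powder_term",
    "powder_signal",
    "powder_signals",
    "microdomain_signal",
    "violated_powder_signal",
    "violated_powder_signals",
    "add_noise",
    "rician_bias_correct",
]

#: free-water diffusivity at body temperature, um^2/ms
LAMBDA_FREE = 3.0

_FRACTION_ATOL = 1e-9


@dataclass(frozen=True)
class TissueParams:
    """Biophysical state of a voxel (scalar fields or equal-length arrays).

    Invariants: fractions in [0, 1] summing to 1;
    0 <= lambda_sph <= lambda_cyl <= LAMBDA_FREE.
    """

    v_cyl: np.ndarray
    v_sph: np.ndarray
    v_ext: np.ndarray
    lambda_cyl: np.ndarray
    lambda_sph: np.ndarray

    def __post_init__(self) -> None:
        fields = {}
        for name in ("v_cyl", "v_sph", "v_ext", "lambda_cyl", "lambda_sph"):
            fields[name] = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, fields[name])
        f = fields
        if np.any(f["v_cyl"] < -_FRACTION_ATOL) or np.any(f["v_sph"] < -_FRACTION_ATOL) \
                or np.any(f["v_ext"] < -_FRACTION_ATOL):
            raise ValueError("volume fractions must be non-negative")
        total = f["v_cyl"] + f["v_sph"] + f["v_ext"]
        if np.any(np.abs(total - 1.0) > 1e-9):
            raise ValueError("volume fractions must sum to 1")
        if np.any(f["lambda_sph"] < -_FRACTION_ATOL) \
                or np.any(f["lambda_sph"] > f["lambda_cyl"] + 1e-9) \
                or np.any(f["lambda_cyl"] > LAMBDA_FREE + 1e-9):
            raise ValueError(
                "diffusivities must satisfy 0 <= lambda_sph <= lambda_cyl <= "
                f"{LAMBDA_FREE}"
            )

    @classmethod
    def from_fractions(cls, v_cyl, v_sph, lambda_cyl, lambda_sph) -> "TissueParams":
        v_cyl = np.asarray(v_cyl, dtype=float)
        v_sph = np.asarray(v_sph, dtype=float)
        return cls(v_cyl, v_sph, 1.0 - v_cyl - v_sph,
                   np.asarray(lambda_cyl, dtype=float),
                   np.asarray(lambda_sph, dtype=float))

    @property
    def n(self) -> int:
        return int(np.broadcast(self.v_cyl, self.lambda_cyl).size)

    def as_array(self) -> np.ndarray:
        """Stack (v_cyl, v_sph, v_ext, lambda_cyl, lambda_sph) along the last axis."""
        return np.stack(np.broadcast_arrays(
            self.v_cyl, self.v_sph, self.v_ext, self.lambda_cyl, self.lambda_sph
        ), axis=-1)


@dataclass(frozen=True)
class CompartmentTensor:
    """Axially symmetric diffusion tensor, eigenvalues (l_par, l_perp, l_perp)."""

    lambda_par: np.ndarray
    lambda_perp: np.ndarray

    def __post_init__(self) -> None:
        lp = np.asarray(self.lambda_par, dtype=float)
        lq = np.asarray(self.lambda_perp, dtype=float)
        if np.any(lq < -1e-12) or np.any(lq > lp + 1e-9) or np.any(lp > LAMBDA_FREE + 1e-9):
            raise ValueError("need 0 <= lambda_perp <= lambda_par <= lambda_free")
        object.__setattr__(self, "lambda_par", lp)
        object.__setattr__(self, "lambda_perp", lq)


VIOLATION_KINDS = (
    "none", "csf", "compartmental_t2", "perp_stick", "myelin",
    "tortuosity_perp", "tortuosity_both", "gamma_sph", "kurtosis",
)


@dataclass(frozen=True)
class ViolationConfig:
    """One generative departure from the ideal model.

    kind selects the departure; only the matching magnitude field is read:

    - ``csf``: free-water compartment of fraction ``v_csf`` with diffusivity
      ``csf_diffusivity``, T2 ``t2_csf`` vs tissue ``t2_tissue``
    - ``compartmental_t2``: intra-cellular T2 ``t2_intra`` (fixed) vs
      extra-cellular T2 ``t2_extra``
    - ``perp_stick``: non-zero cylinder perpendicular diffusivity
      ``lambda_perp_cyl``
    - ``myelin``: MR-invisible fraction ``v_myelin`` entering the
      tortuosity exponents
    - ``tortuosity_perp`` / ``tortuosity_both``: extra-cellular
      diffusivities scaled by ``alpha`` / ``beta``, clipped at LAMBDA_FREE
    - ``gamma_sph``: gamma-distributed spherical diffusivities with the
      sample's mean and variance ``gamma_variance``, Monte-Carlo averaged
      over ``n_gamma`` draws
    - ``kurtosis``: spherical log-signal gains + K_T/6 * b^2 * lambda_sph^2
    """

    kind: str = "none"
    v_csf: float = 0.0
    t2_csf: float = 2.0          # s
    t2_tissue: float = 0.1       # s
    csf_diffusivity: float = 3.0  # um^2/ms
    t2_intra: float = 0.1        # s
    t2_extra: float = 0.1        # s
    lambda_perp_cyl: float = 0.0  # um^2/ms
    v_myelin: float = 0.0
    alpha: float = 1.0
    beta: float = 1.0
    gamma_variance: float = 0.0   # (um^2/ms)^2
    n_gamma: int = 10_000
    k_t: float = 0.0
    b_max: float = 5.0            # ms/um^2, kurtosis plausibility bound
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in VIOLATION_KINDS:
            raise ValueError(f"unknown violation kind {self.kind!r}")
        if not 0.0 <= self.v_csf <= 1.0 or not 0.0 <= self.v_myelin < 1.0:
            raise ValueError("partial-volume fractions must be in [0, 1]")
        if self.kind == "compartmental_t2" and not 0.0 < self.t2_extra:
            raise ValueError("t2_extra must be positive")
        if self.lambda_perp_cyl < 0 or self.gamma_variance < 0:
            raise ValueError("magnitudes must be non-negative")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("tortuosity perturbation factors must be positive")

    def lambda_sph_max(self) -> float:
        """Upper bound on lambda_sph keeping the kurtosis signal monotone."""
        if self.kind == "kurtosis" and self.k_t > 0:
            return 3.0 / (self.b_max * self.k_t)
        return LAMBDA_FREE


# ---------------------------------------------------------------------------
# core model


def tortuosity(v_cyl, v_sph, v_ext, lambda_cyl, v_myelin=0.0) -> CompartmentTensor:
    """Extra-cellular diffusivities from the tortuosity power law.

    l_par = lambda * v_ext ** (v_sph/2 / (v_sph + v_cyl))
    l_perp = lambda * v_ext ** ((v_sph/2 + v_cyl) / (v_sph + v_cyl))

    When a myelin fraction is present the hindering-volume denominators (and
    the perpendicular numerator) include ``v_myelin``.  In the limit of no
    cellular structures (v_sph = v_cyl = v_myelin = 0) the extra-cellular
    space is free water: both diffusivities equal ``lambda_cyl``.
    """
    v_cyl = np.asarray(v_cyl, dtype=float)
    v_sph = np.asarray(v_sph, dtype=float)
    v_ext = np.asarray(v_ext, dtype=float)
    lam = np.asarray(lambda_cyl, dtype=float)
    v_my = np.asarray(v_myelin, dtype=float)
    denom = v_sph + v_cyl + v_my
    safe = np.where(denom > 0, denom, 1.0)
    exp_par = 0.5 * v_sph / safe
    exp_perp = (0.5 * v_sph + v_cyl + v_my) / safe
    # v_ext ** e with v_ext = 0 and e = 0 -> 1 (pure intra-cellular voxel)
    base = np.where(v_ext > 0, v_ext, 1.0)
    l_par = lam * np.where((v_ext > 0) | (exp_par == 0), base ** exp_par, 0.0)
    l_perp = lam * np.where((v_ext > 0) | (exp_perp == 0), base ** exp_perp, 0.0)
    free = denom <= 0
    l_par = np.where(free, lam, l_par)
    l_perp = np.where(free, lam, l_perp)
    return CompartmentTensor(l_par, l_perp)


def _erf_ratio(x: np.ndarray) -> np.ndarray:
    """sqrt(pi)/2 * erf(sqrt(x)) / sqrt(x), continued to x <= 0.

    Equals 1 at x = 0 and continues through the imaginary error function
    (Dawson branch) for x < 0.  Series expansion near 0 avoids 0/0.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-6
    xs = x[small]
    out[small] = 1.0 - xs / 3.0 + xs * xs / 10.0
    pos = (~small) & (x > 0)
    rp = np.sqrt(x[pos])
    out[pos] = 0.5 * np.sqrt(np.pi) * special.erf(rp) / rp
    neg = (~small) & (x < 0)
    rn = np.sqrt(-x[neg])
    out[neg] = 0.5 * np.sqrt(np.pi) * special.erfi(rn) / rn
    return out


def compartment_powder_term(b, b_delta, lambda_par, lambda_perp) -> np.ndarray:
    """Powder-averaged signal of one axially symmetric Gaussian compartment."""
    b = np.asarray(b, dtype=float)
    lp = np.asarray(lambda_par, dtype=float)
    lq = np.asarray(lambda_perp, dtype=float)
    x = b * b_delta * (lp - lq)
    att = np.exp(-b * ((1.0 - b_delta) / 3.0 * lp + (2.0 + b_delta) / 3.0 * lq))
    return _erf_ratio(x) * att


def powder_signal(p: TissueParams, shell: Shell,
                  violation: ViolationConfig | None = None) -> np.ndarray:
    """T2-normalised powder-averaged signal for one shell.

    Sum of the cylinder (stick), sphere and extra-cellular powder terms,
    weighted by volume fractions.  With a ``violation`` config the matching
    generative departure is applied (see :func:`violated_powder_signal`).
    """
    if violation is not None and violation.kind != "none":
        return violated_powder_signal(p, shell, violation)
    ext = tortuosity(p.v_cyl, p.v_sph, p.v_ext, p.lambda_cyl)
    return (
        p.v_cyl * compartment_powder_term(shell.b, shell.b_delta, p.lambda_cyl, 0.0)
        + p.v_sph * compartment_powder_term(shell.b, shell.b_delta, p.lambda_sph, p.lambda_sph)
        + p.v_ext * compartment_powder_term(shell.b, shell.b_delta, ext.lambda_par, ext.lambda_perp)
    )


def powder_signals(p: TissueParams, protocol: Protocol,
                   violation: ViolationConfig | None = None) -> np.ndarray:
    """Stack :func:`powder_signal` over the protocol's shells, shape (..., n_shells)."""
    return np.stack(
        [powder_signal(p, s, violation) for s in protocol.shells], axis=-1
    )


def microdomain_signal(bt: BTensor, p: TissueParams, phi) -> np.ndarray:
    """Directional microdomain signal sum_i v_i exp(-b : D_i(phi)).

    ``phi`` is the microdomain symmetry axis (unit 3-vector, or (m, 3) array
    of axes).  The cylinder and extra-cellular tensors share this axis; the
    sphere is isotropic.  This is the orientation-resolved generator whose
    uniform-orientation average equals :func:`powder_signal`.
    """
    u = np.atleast_2d(np.asarray(phi, dtype=float))
    u = u / np.linalg.norm(u, axis=-1, keepdims=True)
    bmat = bt.matrix
    tr_b = np.trace(bmat)
    ubu = np.einsum("mi,ij,mj->m", u, bmat, u)  # u' b u per axis
    ext = tortuosity(p.v_cyl, p.v_sph, p.v_ext, p.lambda_cyl)
    # b : D = l_perp tr(b) + (l_par - l_perp) u' b u  for axially symmetric D
    s_cyl = np.exp(-p.lambda_cyl * ubu)
    s_sph = np.exp(-p.lambda_sph * tr_b) * np.ones_like(ubu)
    s_ext = np.exp(-(ext.lambda_perp * tr_b + (ext.lambda_par - ext.lambda_perp) * ubu))
    out = p.v_cyl * s_cyl + p.v_sph * s_sph + p.v_ext * s_ext
    return out[0] if np.ndim(phi) == 1 else out


# ---------------------------------------------------------------------------
# violated generators


def _t2_weights(fractions: list[np.ndarray], t2s: list[float], te: float):
    """Signal fractions f_i = v_i exp(-TE/T2_i) / sum_j v_j exp(-TE/T2_j).

    The b=0 reference carries the same compartmental T2 weighting, so the
    normalised signal fractions sum to 1.
    """
    ws = [f * np.exp(-te / t2) for f, t2 in zip(fractions, t2s)]
    total = sum(ws)
    return [w / total for w in ws]


def violated_powder_signal(p: TissueParams, shell: Shell,
                           v: ViolationConfig, te: float = 0.094) -> np.ndarray:
    """Powder-averaged signal under one generative model departure.

    ``p`` holds the *visible tissue* fractions summing to 1; for the ``csf``
    and ``myelin`` kinds they are internally rescaled by (1 - v_extra) so the
    four compartments sum to 1.  All signals are T2-normalised against a b=0
    reference carrying the same compartmental T2 weights.
    """
    b, bd = shell.b, shell.b_delta
    kind = v.kind

    if kind == "none":
        return powder_signal(p, shell)

    if kind == "csf":
        scale = 1.0 - v.v_csf
        vc, vs, ve = p.v_cyl * scale, p.v_sph * scale, p.v_ext * scale
        ext = tortuosity(vc, vs, ve, p.lambda_cyl)
        f_c, f_s, f_e, f_csf = _t2_weights(
            [vc, vs, ve, np.full_like(np.asarray(vc, dtype=float), v.v_csf)],
            [v.t2_tissue, v.t2_tissue, v.t2_tissue, v.t2_csf], te,
        )
        return (
            f_c * compartment_powder_term(b, bd, p.lambda_cyl, 0.0)
            + f_s * compartment_powder_term(b, bd, p.lambda_sph, p.lambda_sph)
            + f_e * compartment_powder_term(b, bd, ext.lambda_par, ext.lambda_perp)
            + f_csf * np.exp(-b * v.csf_diffusivity)
        )

    if kind == "compartmental_t2":
        ext = tortuosity(p.v_cyl, p.v_sph, p.v_ext, p.lambda_cyl)
        f_c, f_s, f_e = _t2_weights(
            [p.v_cyl, p.v_sph, p.v_ext], [v.t2_intra, v.t2_intra, v.t2_extra], te
        )
        return (
            f_c * compartment_powder_term(b, bd, p.lambda_cyl, 0.0)
            + f_s * compartment_powder_term(b, bd, p.lambda_sph, p.lambda_sph)
            + f_e * compartment_powder_term(b, bd, ext.lambda_par, ext.lambda_perp)
        )

    if kind == "perp_stick":
        lq = np.minimum(v.lambda_perp_cyl, p.lambda_cyl)
        ext = tortuosity(p.v_cyl, p.v_sph, p.v_ext, p.lambda_cyl)
        return (
            p.v_cyl * compartment_powder_term(b, bd, p.lambda_cyl, lq)
            + p.v_sph * compartment_powder_term(b, bd, p.lambda_sph, p.lambda_sph)
            + p.v_ext * compartment_powder_term(b, bd, ext.lambda_par, ext.lambda_perp)
        )

    if kind == "myelin":
        scale = 1.0 - v.v_myelin
        vc, vs, ve = p.v_cyl * scale, p.v_sph * scale, p.v_ext * scale
        ext = tortuosity(vc, vs, ve, p.lambda_cyl, v_myelin=v.v_myelin)
        visible = vc + vs + ve  # myelin carries no signal; b=0 normalises by this
        return (
            vc * compartment_powder_term(b, bd, p.lambda_cyl, 0.0)
            + vs * compartment_powder_term(b, bd, p.lambda_sph, p.lambda_sph)
            + ve * compartment_powder_term(b, bd, ext.lambda_par, ext.lambda_perp)
        ) / visible

    if kind in ("tortuosity_perp", "tortuosity_both"):
        ext = tortuosity(p.v_cyl, p.v_sph, p.v_ext, p.lambda_cyl)
        if kind == "tortuosity_perp":
            l_perp = np.minimum(v.alpha * ext.lambda_perp, LAMBDA_FREE)
            l_par = np.maximum(l_perp, ext.lambda_par)
        else:
            l_par = np.minimum(v.beta * ext.lambda_par, LAMBDA_FREE)
            l_perp = np.minimum(v.beta * ext.lambda_perp, LAMBDA_FREE)
        return (
            p.v_cyl * compartment_powder_term(b, bd, p.lambda_cyl, 0.0)
            + p.v_sph * compartment_powder_term(b, bd, p.lambda_sph, p.lambda_sph)
            + p.v_ext * compartment_powder_term(b, bd, l_par, l_perp)
        )

    if kind == "gamma_sph":
        ext = tortuosity(p.v_cyl, p.v_sph, p.v_ext, p.lambda_cyl)
        sph = _gamma_sphere_signal(
            np.asarray(p.lambda_sph, dtype=float), b, v.gamma_variance,
            v.n_gamma, v.seed,
        )
        return (
            p.v_cyl * compartment_powder_term(b, bd, p.lambda_cyl, 0.0)
            + p.v_sph * sph
            + p.v_ext * compartment_powder_term(b, bd, ext.lambda_par, ext.lambda_perp)
        )

    if kind == "kurtosis":
        ls = np.asarray(p.lambda_sph, dtype=float)
        if v.k_t > 0 and np.any(ls > v.lambda_sph_max() + 1e-9):
            raise ValueError(
                "kurtosis signal would be non-monotone within the b-range: "
                f"lambda_sph must be <= {v.lambda_sph_max():.4g}"
            )
        ext = tortuosity(p.v_cyl, p.v_sph, p.v_ext, p.lambda_cyl)
        sph = np.exp(-b * ls + v.k_t / 6.0 * b * b * ls * ls)
        return (
            p.v_cyl * compartment_powder_term(b, bd, p.lambda_cyl, 0.0)
            + p.v_sph * sph
            + p.v_ext * compartment_powder_term(b, bd, ext.lambda_par, ext.lambda_perp)
        )

    raise ValueError(f"unknown violation kind {kind!r}")


def _gamma_sphere_signal(mean: np.ndarray, b: float, variance: float,
                         n_gamma: int, seed: int) -> np.ndarray:
    """Mean of exp(-b l) over gamma draws with the given mean and variance.

    One fixed set of standard draws is shared across samples (scaled to each
    sample's shape/scale) for reproducibility.
    """
    scalar = np.ndim(mean) == 0
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    if variance <= 0:
        out = np.exp(-b * mean)
        return float(out[0]) if scalar else out
    rng = np.random.default_rng(seed)
    out = np.empty_like(mean)
    positive = mean > 0
    out[~positive] = 1.0
    # gamma with mean m and variance V: shape k = m^2/V, scale theta = V/m;
    # chunk over samples to bound memory at ~2e6 draws in flight
    chunk = max(1, int(2e6) // n_gamma)
    idx = np.nonzero(positive)[0]
    for start in range(0, idx.size, chunk):
        sl = idx[start:start + chunk]
        k = (mean[sl] ** 2 / variance)[:, None]
        th = (variance / mean[sl])[:, None]
        draws = rng.standard_gamma(k, size=(sl.size, n_gamma)) * th
        out[sl] = np.exp(-b * draws).mean(axis=1)
    return float(out[0]) if scalar else out


def violated_powder_signals(p: TissueParams, protocol: Protocol,
                            v: ViolationConfig) -> np.ndarray:
    """Stack :func:`violated_powder_signal` over shells, TE from the protocol."""
    return np.stack(
        [violated_powder_signal(p, s, v, te=protocol.te) for s in protocol.shells],
        axis=-1,
    )


# ---------------------------------------------------------------------------
# noise


def add_noise(signal, sigma, model: str = "gaussian",
              rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Corrupt signals with Gaussian or Rician noise of standard deviation sigma.

    Gaussian: s + N(0, sigma).  Rician: sqrt((s + N(0, sigma))^2 + N(0, sigma)^2),
    the magnitude of a complex signal with independent channel noise.
    """
    s = np.asarray(signal, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if model == "gaussian":
        return s + sigma * rng.standard_normal(s.shape)
    if model == "rician":
        re = s + sigma * rng.standard_normal(s.shape)
        im = sigma * rng.standard_normal(s.shape)
        return np.hypot(re, im)
    raise ValueError(f"unknown noise model {model!r}")


def rician_mean(s, sigma) -> np.ndarray:
    """Expected magnitude E[m | s, sigma] of a Rician measurement.

    sigma*sqrt(pi/2) * [(1+t) I0(t/2) + t I1(t/2)] * exp(-t/2), t = s^2/(2 sigma^2),
    evaluated with exponentially scaled Bessel functions for stability.
    """
    s = np.asarray(s, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    t = np.where(sigma > 0, s * s / (2.0 * np.maximum(sigma, 1e-300) ** 2), 0.0)
    half = t / 2.0
    # ive(n, x) = iv(n, x) * exp(-x); exp(-t/2)*I(t/2) = ive(., t/2)
    val = np.sqrt(np.pi / 2.0) * ((1.0 + t) * special.ive(0, half) + t * special.ive(1, half))
    return np.where(sigma > 0, sigma * val, s)


def rician_bias_correct(m, sigma) -> np.ndarray:
    """Invert the Rician expectation: find s >= 0 with E[m | s, sigma] = m.

    Measurements at or below the zero-signal noise floor sigma*sqrt(pi/2)
    map to 0.  sigma = 0 is the identity.
    """
    from scipy.optimize import brentq

    m_arr = np.atleast_1d(np.asarray(m, dtype=float))
    sig_arr = np.broadcast_to(np.asarray(sigma, dtype=float), m_arr.shape)
    if np.any(m_arr < 0):
        raise ValueError("measured magnitudes must be non-negative")
    out = np.empty_like(m_arr)
    for i, (mi, si) in enumerate(zip(m_arr.ravel(), sig_arr.ravel())):
        if si == 0:
            out.ravel()[i] = mi
            continue
        floor = si * np.sqrt(np.pi / 2.0)
        if mi <= floor + 1e-12 * si:
            out.ravel()[i] = 0.0
            continue
        hi = mi + 5.0 * si
        out.ravel()[i] = brentq(lambda s: rician_mean(s, si) - mi, 0.0, hi, xtol=1e-12)
    return out if np.ndim(m) else float(out[0])
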