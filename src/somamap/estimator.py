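"""Simulation-trained network estimator and classical least-squares baseline.

The estimator maps per-shell powder-averaged signals plus the noise standard
deviation to four unbounded outputs

    z1 = logit(v_cyl + v_sph)          z2 = logit(v_cyl / (v_cyl + v_sph))
    z3 = logit(lambda_cyl / lambda_free)   z4 = logit(lambda_sph / lambda_cyl)

whose inverse transform is, by construction, always a physically plausible
parameter set.  The network is three fully connected layers with rectified
linear units, trained with mini-batch stochastic gradient descent (momentum)
on a mean-squared-error criterion over synthetic signals; Gaussian noise with
each sample's sigma is regenerated for every batch and epoch so the network
never sees the same noisy instance twice.

Noise convention: sigma is the standard deviation of the noise in the
powder-averaged shell signals themselves (the network inputs), at the
protocol's per-shell direction counts.  Protocols with unequal per-shell
counts scale each shell's noise by sqrt(mean count / shell count).  Acquiring
fewer or more directions than the protocol is emulated by scaling sigma with
the square root of the count ratio (see :mod:`somamap.experiments`).
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass

import numpy as np

from .protocol import Protocol
from .sampling import sample_sigma, sample_tissue_params
from .signal import (
    LAMBDA_FREE,
    CompartmentTensor,
    TissueParams,
    powder_signals,
    tortuosity,
)

__all__ = [
    "LOGIT_EPS",
    "ProtocolMismatchError",
    "TrainConfig",
    "desk_train_config",
    "Estimator",
    "params_to_logits",
    "logits_to_params",
    "train",
    "fit_nlls",
]

#: boundary clipping for the logit transform
LOGIT_EPS = 1e-6


class ProtocolMismatchError(ValueError):
    """Signals come from a protocol the estimator was not trained on."""


def shell_noise_scale(protocol: Protocol) -> np.ndarray:
    """Per-shell noise multiplier relative to the protocol-level sigma.

    sigma describes the noise of a shell mean at the protocol's average
    per-shell direction count; shells with more directions average more
    rotations and are quieter by the square root of the count ratio.
    """
    n = np.asarray(protocol.n_dirs, dtype=float)
    return np.sqrt(n.mean() / n)


# ---------------------------------------------------------------------------
# logit parameterisation


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def params_to_logits(p: TissueParams, *, eps: float = LOGIT_EPS) -> np.ndarray:
    """Map tissue parameters to the four unbounded network targets.

    Ratios at 0 or 1 (e.g. v_cyl + v_sph = 0, or lambda_cyl = 0 making the
    sph/cyl ratio undefined) are clipped to [eps, 1 - eps] with a warning.
    """
    v_in = np.asarray(p.v_cyl + p.v_sph, dtype=float)
    lc = np.asarray(p.lambda_cyl, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_cyl = np.where(v_in > 0, p.v_cyl / np.where(v_in > 0, v_in, 1.0), 0.5)
        r_sph = np.where(lc > 0, p.lambda_sph / np.where(lc > 0, lc, 1.0), 0.5)
    ratios = np.stack(
        np.broadcast_arrays(v_in, r_cyl, lc / LAMBDA_FREE, r_sph), axis=-1
    )
    clipped = np.clip(ratios, eps, 1.0 - eps)
    if np.any(ratios != clipped):
        warnings.warn(
            "boundary parameter values clipped for the logit transform",
            RuntimeWarning, stacklevel=2,
        )
    return _logit(clipped)


def logits_to_params(z: np.ndarray) -> TissueParams:
    """Inverse of :func:`params_to_logits`; any real z is a valid parameter set."""
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != 4:
        raise ValueError("logit vectors must have length 4")
    s = _sigmoid(z)
    v_in = s[..., 0]
    v_cyl = v_in * s[..., 1]
    v_sph = v_in - v_cyl
    lambda_cyl = LAMBDA_FREE * s[..., 2]
    lambda_sph = lambda_cyl * s[..., 3]
    return TissueParams(v_cyl, v_sph, 1.0 - v_in, lambda_cyl, lambda_sph)


# ---------------------------------------------------------------------------
# network


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters.

    Defaults mirror the full-scale regimen (2^20 samples, 100,000 epochs,
    learning rate 0.001, momentum 0.9); :func:`desk_train_config` gives a
    preset that trains in minutes on one CPU.  Hidden widths are open
    configuration — three layers of 256 by default.
    """

    n_samples: int = 2 ** 20
    epochs: int = 100_000
    hidden: tuple[int, int] = (256, 256)
    batch_size: int = 2 ** 12
    learning_rate: float = 1e-3
    momentum: float = 0.9
    val_fraction: float = 0.25
    noise_model: str = "gaussian"
    sigma_min: float = 0.01
    sigma_max: float = 1.0
    val_every: int = 50
    seed: int = 0


def desk_train_config(seed: int = 0, **overrides) -> TrainConfig:
    """Desk-scale preset: 2^17 samples, 800 epochs, batch 256, hidden 64.

    Trains in minutes on one CPU.  The small batch trades per-step
    efficiency for many more gradient updates, which converges measurably
    further than large-batch variants at equal wall time.
    """
    base = dict(n_samples=2 ** 17, epochs=800, hidden=(64, 64),
                batch_size=256, seed=seed)
    base.update(overrides)
    return TrainConfig(**base)


@dataclass
class Estimates:
    """Estimator output: tissue parameters plus derived extra-cellular tensor."""

    params: TissueParams
    ext: CompartmentTensor


class Estimator:
    """Trained three-layer network bound to one acquisition protocol."""

    def __init__(self, weights: list[np.ndarray], biases: list[np.ndarray],
                 protocol: Protocol, config: TrainConfig,
                 history: dict | None = None) -> None:
        self.weights = [np.asarray(w, dtype=np.float32) for w in weights]
        self.biases = [np.asarray(b, dtype=np.float32) for b in biases]
        self.protocol = protocol
        self.config = config
        self.history = history or {}
        self.fingerprint = protocol.fingerprint()

    # -- inference ----------------------------------------------------------

    def _forward(self, x: np.ndarray) -> np.ndarray:
        h = x.astype(np.float32, copy=False)
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ w + b, 0.0)
        return h @ self.weights[-1] + self.biases[-1]

    def predict_logits(self, signals: np.ndarray, sigma) -> np.ndarray:
        signals = np.atleast_2d(np.asarray(signals, dtype=float))
        n_shells = self.protocol.n_shells
        if signals.shape[-1] != n_shells:
            raise ProtocolMismatchError(
                f"expected {n_shells} shell signals, got {signals.shape[-1]}"
            )
        sig = np.broadcast_to(np.asarray(sigma, dtype=float), signals.shape[:-1])
        x = np.concatenate([signals, sig[..., None]], axis=-1)
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite inputs rejected")
        return self._forward(x).astype(float)

    def estimate(self, signals: np.ndarray, sigma,
                 protocol: Protocol | None = None) -> Estimates:
        """Voxelwise parameter estimates from per-shell powder means.

        If ``protocol`` is given its fingerprint must match the training
        protocol.  ``signals`` has shape (..., n_shells); ``sigma`` is the
        per-measurement noise standard deviation (scalar or per-voxel).
        """
        if protocol is not None and protocol.fingerprint() != self.fingerprint:
            raise ProtocolMismatchError(
                "protocol fingerprint does not match the training protocol"
            )
        scalar = np.ndim(signals) == 1
        z = self.predict_logits(signals, sigma)
        p = logits_to_params(z[0] if scalar else z)
        ext = tortuosity(p.v_cyl, p.v_sph, p.v_ext, p.lambda_cyl)
        return Estimates(p, ext)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Write weights + config + protocol fingerprint to an HDF5 container."""
        import h5py

        from .protocol import B_FROM_SI

        with h5py.File(path, "w") as f:
            f.attrs["format_version"] = 1
            f.attrs["fingerprint"] = self.fingerprint
            f.attrs["config"] = json.dumps(
                {**self.config.__dict__, "hidden": list(self.config.hidden)}
            )
            f.attrs["protocol"] = json.dumps({
                "shells": [
                    {"b": s.b / B_FROM_SI, "bdelta": s.b_delta, "ndirs": s.n_dirs}
                    for s in self.protocol.shells
                ],
                "te_ms": self.protocol.te * 1e3,
                "nb0": self.protocol.n_b0,
            })
            for i, (w, b) in enumerate(zip(self.weights, self.biases)):
                f.create_dataset(f"w{i}", data=w)
                f.create_dataset(f"b{i}", data=b)
            if "val_loss" in self.history:
                f.create_dataset("val_loss", data=np.asarray(self.history["val_loss"]))
                f.create_dataset("val_epoch", data=np.asarray(self.history["val_epoch"]))

    @classmethod
    def load(cls, path) -> "Estimator":
        import h5py

        from .protocol import B_FROM_SI, Shell

        with h5py.File(path, "r") as f:
            if f.attrs.get("format_version") != 1:
                raise ValueError("unsupported model file version")
            cfg = json.loads(f.attrs["config"])
            cfg["hidden"] = tuple(cfg["hidden"])
            config = TrainConfig(**cfg)
            proto = json.loads(f.attrs["protocol"])
            protocol = Protocol(
                tuple(Shell(s["b"] * B_FROM_SI, s["bdelta"], int(s["ndirs"]))
                      for s in proto["shells"]),
                te=proto["te_ms"] * 1e-3, n_b0=int(proto["nb0"]),
            )
            n_layers = len([k for k in f.keys() if k.startswith("w")])
            weights = [f[f"w{i}"][...] for i in range(n_layers)]
            biases = [f[f"b{i}"][...] for i in range(n_layers)]
            history = {}
            if "val_loss" in f:
                history = {"val_loss": f["val_loss"][...],
                           "val_epoch": f["val_epoch"][...]}
        model = cls(weights, biases, protocol, config, history)
        if model.fingerprint != f_attr_fingerprint(path):
            raise ValueError("stored fingerprint does not match stored protocol")
        return model


def f_attr_fingerprint(path) -> str:
    import h5py

    with h5py.File(path, "r") as f:
        return str(f.attrs["fingerprint"])


def train(protocol: Protocol, config: TrainConfig | None = None,
          progress: bool = False) -> Estimator:
    """Train the network on synthetic signals from the ideal forward model.

    Draws ``config.n_samples`` tissue parameter sets (uniform simplex priors)
    and noise levels (log-uniform sigma), synthesises noise-free powder
    signals once, and injects fresh per-shell Gaussian noise
    sigma / sqrt(n_dirs) at every batch of every epoch.  75% of the samples
    train the network and 25% monitor validation loss.
    """
    if len({s.b_delta for s in protocol.shells}) < 2 or protocol.n_shells < 2:
        raise ValueError("protocol must span at least two shells and two b-tensor shapes")
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)

    params = sample_tissue_params(config.n_samples, rng)
    sigma = sample_sigma(config.n_samples, rng, config.sigma_min, config.sigma_max)
    clean = powder_signals(params, protocol).astype(np.float32)
    with warnings.catch_warnings():
        # uniform draws graze the logit boundaries with vanishing probability
        warnings.simplefilter("ignore", RuntimeWarning)
        targets = params_to_logits(params).astype(np.float32)
    sigma32 = sigma.astype(np.float32)
    shell_scale = shell_noise_scale(protocol).astype(np.float32)

    n_val = int(round(config.val_fraction * config.n_samples))
    n_train = config.n_samples - n_val
    perm = rng.permutation(config.n_samples)
    tr, va = perm[:n_train], perm[n_train:]

    n_in = protocol.n_shells + 1
    sizes = [n_in, *config.hidden, 4]
    weights, biases, vel_w, vel_b = [], [], [], []
    for a, b in zip(sizes[:-1], sizes[1:]):
        weights.append((rng.standard_normal((a, b)) * np.sqrt(2.0 / a)).astype(np.float32))
        biases.append(np.zeros(b, dtype=np.float32))
        vel_w.append(np.zeros((a, b), dtype=np.float32))
        vel_b.append(np.zeros(b, dtype=np.float32))

    # fixed validation noise for comparable loss across epochs
    val_noise = rng.standard_normal((n_val, protocol.n_shells)).astype(np.float32)
    x_val = np.concatenate(
        [clean[va] + sigma32[va, None] * shell_scale[None, :] * val_noise,
         sigma32[va, None]], axis=1,
    )
    y_val = targets[va]

    lr, mu = np.float32(config.learning_rate), np.float32(config.momentum)
    batch = config.batch_size
    history: dict[str, list] = {"val_epoch": [], "val_loss": []}
    t0 = time.time()

    def forward_backward(x, y):
        h0 = np.maximum(x @ weights[0] + biases[0], 0.0)
        h1 = np.maximum(h0 @ weights[1] + biases[1], 0.0)
        out = h1 @ weights[2] + biases[2]
        diff = out - y
        loss = float(np.mean(diff * diff))
        g_out = (2.0 / diff.size) * diff
        g_w2 = h1.T @ g_out
        g_b2 = g_out.sum(axis=0)
        g_h1 = (g_out @ weights[2].T) * (h1 > 0)
        g_w1 = h0.T @ g_h1
        g_b1 = g_h1.sum(axis=0)
        g_h0 = (g_h1 @ weights[1].T) * (h0 > 0)
        g_w0 = x.T @ g_h0
        g_b0 = g_h0.sum(axis=0)
        return loss, (g_w0, g_w1, g_w2), (g_b0, g_b1, g_b2)

    def val_loss():
        h0 = np.maximum(x_val @ weights[0] + biases[0], 0.0)
        h1 = np.maximum(h0 @ weights[1] + biases[1], 0.0)
        out = h1 @ weights[2] + biases[2]
        return float(np.mean((out - y_val) ** 2))

    for epoch in range(config.epochs):
        order = rng.permutation(n_train)
        for start in range(0, n_train, batch):
            idx = tr[order[start:start + batch]]
            noise = rng.standard_normal((idx.size, protocol.n_shells)).astype(np.float32)
            if config.noise_model == "rician":
                noise2 = rng.standard_normal((idx.size, protocol.n_shells)).astype(np.float32)
                s = clean[idx] + sigma32[idx, None] * shell_scale[None, :] * noise
                noisy = np.hypot(s, sigma32[idx, None] * shell_scale[None, :] * noise2)
            else:
                noisy = clean[idx] + sigma32[idx, None] * shell_scale[None, :] * noise
            x = np.concatenate([noisy, sigma32[idx, None]], axis=1)
            loss, g_w, g_b = forward_backward(x, targets[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss={loss}); "
                    "reduce the learning rate or batch size"
                )
            for i in range(3):
                vel_w[i] = mu * vel_w[i] - lr * g_w[i]
                vel_b[i] = mu * vel_b[i] - lr * g_b[i]
                weights[i] += vel_w[i]
                biases[i] += vel_b[i]
        if epoch % config.val_every == 0 or epoch == config.epochs - 1:
            history["val_epoch"].append(epoch)
            history["val_loss"].append(val_loss())
            if progress:
                print(f"epoch {epoch:6d}  val_loss {history['val_loss'][-1]:.5f}  "
                      f"[{time.time() - t0:.1f}s]")

    history["train_seconds"] = time.time() - t0
    return Estimator(weights, biases, protocol, config, history)


# ---------------------------------------------------------------------------
# classical baseline


def _signals_from_logits(z: np.ndarray, b: np.ndarray, b_delta: np.ndarray
                         ) -> np.ndarray:
    """Forward model straight from logit coordinates, without validation.

    Identical to ``powder_signals(logits_to_params(z), protocol)`` but cheap
    enough for the inner loop of the least-squares fit.
    """
    from .signal import compartment_powder_term, tortuosity

    s = _sigmoid(z)
    v_in = s[0]
    v_cyl, v_sph = v_in * s[1], v_in * (1.0 - s[1])
    v_ext = 1.0 - v_in
    l_cyl = LAMBDA_FREE * s[2]
    l_sph = l_cyl * s[3]
    ext = tortuosity(v_cyl, v_sph, v_ext, l_cyl)
    return (
        v_cyl * compartment_powder_term(b, b_delta, l_cyl, 0.0)
        + v_sph * np.exp(-b * l_sph)
        + v_ext * compartment_powder_term(b, b_delta, ext.lambda_par, ext.lambda_perp)
    )


def fit_nlls(signals: np.ndarray, sigma, protocol: Protocol,
             n_restarts: int = 5, rng: np.random.Generator | int | None = None
             ) -> TissueParams:
    """Multi-start non-linear least squares in the unbounded logit space.

    Minimises per-shell residuals between the forward model and the measured
    powder means, weighted by the inverse effective shell noise
    (sigma times the per-shell :func:`shell_noise_scale`) when sigma > 0.
    Serves as the classical baseline and independent cross-check for the
    network estimator.
    """
    from scipy.optimize import least_squares

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    scalar = signals.shape[0] == 1 and np.ndim(sigma) == 0
    n_vox = signals.shape[0]
    if signals.shape[1] != protocol.n_shells:
        raise ProtocolMismatchError(
            f"expected {protocol.n_shells} shell signals, got {signals.shape[1]}"
        )
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), (n_vox,))
    w = np.ones(protocol.n_shells)
    scale = shell_noise_scale(protocol)
    b, b_delta = protocol.b, protocol.b_delta

    ls_opts = dict(method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=1000)
    # the sphere/extra-cellular trade-off creates a narrow valley along the
    # soma-diffusivity coordinate z4; a coarse profile over z4 (fitting the
    # other three coordinates at each fixed value) locates the global valley
    # reliably where plain multistart does not
    z4_profile = np.linspace(-4.0, 4.0, 17)

    out = np.empty((n_vox, 4))
    for i in range(n_vox):
        weights = w if sig[i] == 0 else 1.0 / (sig[i] * scale)

        def residual(z):
            return (_signals_from_logits(z, b, b_delta) - signals[i]) * weights

        best, best_cost = None, np.inf
        starts = [np.zeros(4)] + [rng.normal(scale=1.5, size=4)
                                  for _ in range(max(0, n_restarts - 1))]
        for z0 in starts:
            try:
                res = least_squares(residual, z0, **ls_opts)
            except Exception:
                continue
            if res.cost < best_cost:
                best, best_cost = res.x, res.cost
        if best is None:
            raise RuntimeError(f"all NLLS restarts failed for voxel {i}")
        if best_cost > 1e-20:  # a vanishing cost means the global optimum is in hand
            candidates = []
            for z4v in z4_profile:
                try:
                    # a zero start keeps the conditional fit out of the basin
                    # the full fit may already be stuck in
                    res3 = least_squares(
                        lambda w3: residual(np.append(w3, z4v)), np.zeros(3),
                        **ls_opts)
                except Exception:
                    continue
                candidates.append((res3.cost, np.append(res3.x, z4v)))
            candidates.sort(key=lambda c: c[0])
            for _, z0 in candidates[:4]:
                try:
                    res = least_squares(residual, z0, **ls_opts)
                except Exception:
                    continue
                if res.cost < best_cost:
                    best, best_cost = res.x, res.cost
        out[i] = best
    return logits_to_params(out[0] if scalar else out)
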