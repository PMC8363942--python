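"""Simulation studies quantifying estimator bias and precision.

Four harnesses: a fraction-simplex bias/precision map at fixed diffusivity
pairs, sweeps over SNR and gradient-direction count, violation experiments
where test data depart from the assumed model, and the CSF-vs-v_cyl
dependence study.  All results are tidy pandas tables with one row per
(condition, parameter) holding box-plot statistics of (estimate - truth).

Gold standards follow the renormalisation conventions of the violation
studies: with a CSF compartment the extra-cellular reference is
v_ext + v_csf; with an MR-invisible myelin fraction the reference is
v_i / (1 - v_myelin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimator import Estimator, shell_noise_scale
from .sampling import diffusivity_grid, sample_tissue_params, simplex_grid
from .signal import TissueParams, ViolationConfig, powder_signals, violated_powder_signals

__all__ = [
    "ErrorStats",
    "error_stats",
    "violation_config",
    "gold_standard",
    "run_simplex_evaluation",
    "run_sweep",
    "run_violation_experiment",
    "csf_vcyl_dependence",
    "PARAMETERS",
]

PARAMETERS = ("v_cyl", "v_sph", "v_ext", "lambda_cyl", "lambda_sph")


@dataclass(frozen=True)
class ErrorStats:
    """Box-plot summary of an error sample: mean bias, spread, quartiles.

    Whiskers extend 1.5 interquartile ranges beyond the box.
    """

    mean_bias: float
    sd: float
    p25: float
    p50: float
    p75: float
    whisker_lo: float
    whisker_hi: float
    n: int

    @property
    def iqr(self) -> float:
        return self.p75 - self.p25


def error_stats(errors: np.ndarray) -> ErrorStats:
    errors = np.asarray(errors, dtype=float).ravel()
    if errors.size == 0:
        raise ValueError("empty error sample")
    p25, p50, p75 = np.percentile(errors, [25, 50, 75])
    iqr = p75 - p25
    return ErrorStats(
        mean_bias=float(errors.mean()), sd=float(errors.std(ddof=1)) if errors.size > 1 else 0.0,
        p25=float(p25), p50=float(p50), p75=float(p75),
        whisker_lo=float(p25 - 1.5 * iqr), whisker_hi=float(p75 + 1.5 * iqr),
        n=int(errors.size),
    )


_MAGNITUDE_FIELD = {
    "none": None,
    "csf": "v_csf",
    "compartmental_t2": "t2_extra",
    "perp_stick": "lambda_perp_cyl",
    "myelin": "v_myelin",
    "tortuosity_perp": "alpha",
    "tortuosity_both": "beta",
    "gamma_sph": "gamma_variance",
    "kurtosis": "k_t",
}


def violation_config(kind: str, magnitude: float = 0.0, **kw) -> ViolationConfig:
    """Build a :class:`ViolationConfig` with ``magnitude`` in the kind's field."""
    if kind not in _MAGNITUDE_FIELD:
        raise ValueError(f"unknown violation kind {kind!r}")
    field_name = _MAGNITUDE_FIELD[kind]
    if field_name is not None:
        kw[field_name] = magnitude
    return ViolationConfig(kind=kind, **kw)


def gold_standard(params: TissueParams, config: ViolationConfig) -> dict[str, np.ndarray]:
    """Reference parameter values the estimates are compared against.

    ``params`` are the *visible tissue* simplex draws handed to the violated
    generator (which rescales internally for the csf/myelin kinds).
    """
    out = {
        "v_cyl": np.asarray(params.v_cyl, dtype=float),
        "v_sph": np.asarray(params.v_sph, dtype=float),
        "v_ext": np.asarray(params.v_ext, dtype=float),
        "lambda_cyl": np.asarray(params.lambda_cyl, dtype=float),
        "lambda_sph": np.asarray(params.lambda_sph, dtype=float),
    }
    if config.kind == "csf":
        scale = 1.0 - config.v_csf
        out["v_cyl"] = out["v_cyl"] * scale
        out["v_sph"] = out["v_sph"] * scale
        out["v_ext"] = out["v_ext"] * scale + config.v_csf
    # myelin: generator fractions are v_i*(1-v_myelin); the gold standard
    # v_i*(1-v_myelin)/(1-v_myelin) is the unscaled draw, already in `out`
    return out


def _noisy_inputs(clean: np.ndarray, sigma: float, protocol,
                  rng: np.random.Generator) -> np.ndarray:
    scale = shell_noise_scale(protocol)
    return clean + sigma * scale[None, :] * rng.standard_normal(clean.shape)


def _stats_rows(estimates, gold, base_row: dict) -> list[dict]:
    est = {
        "v_cyl": estimates.params.v_cyl, "v_sph": estimates.params.v_sph,
        "v_ext": estimates.params.v_ext,
        "lambda_cyl": estimates.params.lambda_cyl,
        "lambda_sph": estimates.params.lambda_sph,
    }
    rows = []
    for name in PARAMETERS:
        st = error_stats(est[name] - gold[name])
        rows.append({**base_row, "parameter": name, **st.__dict__, "iqr": st.iqr})
    return rows


def run_simplex_evaluation(model: Estimator, fraction_step: float = 0.05,
                           diffusivities: np.ndarray | None = None,
                           n_noise: int = 10_000, snr: float = 25.0,
                           seed: int = 0) -> pd.DataFrame:
    """Bias/precision per fraction-simplex point and diffusivity pair.

    For every (lambda_cyl, lambda_sph) pair and every fraction triple on the
    simplex lattice, ``n_noise`` Gaussian noise instances at the given SNR
    are estimated and summarised.  Defaults reproduce the full-scale study
    (231 fraction points, diffusivities 0.5-3.0 step 0.5, 10,000 instances);
    pass smaller values for desk runs.
    """
    rng = np.random.default_rng(seed)
    fracs = simplex_grid(fraction_step)
    if diffusivities is None:
        diffusivities = diffusivity_grid()
    sigma = 1.0 / snr
    rows = []
    for lc, ls in np.atleast_2d(diffusivities):
        p = TissueParams(fracs[:, 0], fracs[:, 1], fracs[:, 2],
                         np.full(len(fracs), lc), np.full(len(fracs), ls))
        clean = powder_signals(p, model.protocol)
        rep = np.repeat(clean, n_noise, axis=0)
        noisy = _noisy_inputs(rep, sigma, model.protocol, rng)
        est = model.estimate(noisy, sigma)
        gold_all = gold_standard(p, ViolationConfig("none"))
        for k in range(len(fracs)):
            sl = slice(k * n_noise, (k + 1) * n_noise)
            est_view = type(est)(
                params=TissueParams(
                    est.params.v_cyl[sl], est.params.v_sph[sl], est.params.v_ext[sl],
                    est.params.lambda_cyl[sl], est.params.lambda_sph[sl]),
                ext=est.ext,
            )
            gold = {name: np.full(n_noise, gold_all[name][k]) for name in PARAMETERS}
            rows += _stats_rows(est_view, gold, {
                "lambda_cyl_true": lc, "lambda_sph_true": ls,
                "v_cyl_true": fracs[k, 0], "v_sph_true": fracs[k, 1],
                "v_ext_true": fracs[k, 2], "snr": snr,
            })
    return pd.DataFrame(rows)


def run_sweep(model: Estimator, axis: str, values,
              n_samples: int = 107_520, seed: int = 0,
              snr: float = 25.0) -> pd.DataFrame:
    """Error statistics versus SNR or per-encoding direction count.

    ``axis='snr'``: the powder-mean noise level varies, protocol fixed.
    ``axis='n_dirs'``: the per-direction SNR implied by ``snr`` at the
    protocol's direction count is held fixed while the shell means average
    fewer or more rotations, so the powder-mean noise scales with the square
    root of the count ratio; the matching sigma is fed to the network, so
    one trained network serves every direction count.
    """
    if axis not in ("snr", "n_dirs"):
        raise ValueError("axis must be 'snr' or 'n_dirs'")
    rng = np.random.default_rng(seed)
    params = sample_tissue_params(n_samples, rng)
    clean = powder_signals(params, model.protocol)
    gold = gold_standard(params, ViolationConfig("none"))
    scale = shell_noise_scale(model.protocol)
    n_protocol = float(np.sum(model.protocol.n_dirs)) / 2.0  # dirs per encoding
    rows = []
    for value in values:
        if axis == "snr":
            sigma_eff = 0.0 if np.isinf(value) else 1.0 / float(value)
        else:
            # value = directions per encoding; fewer rotations -> noisier means
            sigma_eff = (1.0 / snr) * np.sqrt(n_protocol / float(value))
        noisy = clean + sigma_eff * scale[None, :] * rng.standard_normal(clean.shape)
        # network sigma input stays within the trained noise prior
        est = model.estimate(noisy, max(sigma_eff, model.config.sigma_min))
        rows += _stats_rows(est, gold, {"axis": axis, "value": value, "n": n_samples})
    return pd.DataFrame(rows)


def run_violation_experiment(model: Estimator, kind: str, magnitudes,
                             n_samples: int = 107_520, snr: float = 25.0,
                             seed: int = 0, **config_kw) -> pd.DataFrame:
    """Bias statistics versus violation magnitude for one departure kind.

    Test data come from the violated generator; the estimator is the
    ideal-model-trained network.  Parameters are drawn uniformly from the
    constrained space; for the kurtosis kind with positive total kurtosis,
    draws violating lambda_sph <= 3/(b_max K_T) get lambda_sph redrawn
    uniformly below the bound so the signal stays monotone in b.
    """
    rng = np.random.default_rng(seed)
    params = sample_tissue_params(n_samples, rng)
    sigma = 1.0 / snr
    rows = []
    for mag in magnitudes:
        cfg = violation_config(kind, mag, **config_kw)
        p = params
        bound = cfg.lambda_sph_max()
        if np.any(params.lambda_sph > bound):
            cap = np.minimum(params.lambda_cyl, bound)
            ls = np.where(params.lambda_sph > bound,
                          rng.uniform(0.0, 1.0, n_samples) * cap,
                          params.lambda_sph)
            p = TissueParams(params.v_cyl, params.v_sph, params.v_ext,
                             params.lambda_cyl, ls)
        clean = violated_powder_signals(p, model.protocol, cfg)
        noisy = _noisy_inputs(clean, sigma, model.protocol, rng)
        est = model.estimate(noisy, sigma)
        gold = gold_standard(p, cfg)
        rows += _stats_rows(est, gold, {
            "kind": kind, "magnitude": mag, "snr": snr, "n": n_samples,
        })
    return pd.DataFrame(rows)


def csf_vcyl_dependence(model: Estimator, v_csf: float = 0.1,
                        vcyl_values=None, n_per_bin: int = 10_000,
                        snr: float = 25.0, seed: int = 0) -> pd.DataFrame:
    """CSF-contamination bias as a function of the cylinder fraction.

    For each fixed v_cyl bin, the remaining parameters are sampled uniformly
    and signals are generated with a CSF compartment of fraction ``v_csf``;
    the bias of v_cyl and v_sph estimates grows with v_cyl.
    """
    if vcyl_values is None:
        vcyl_values = np.arange(0.0, 0.91, 0.1)
    rng = np.random.default_rng(seed)
    cfg = violation_config("csf", v_csf)
    sigma = 1.0 / snr
    rows = []
    for vc in vcyl_values:
        v_sph = rng.uniform(0.0, 1.0 - vc, n_per_bin)
        free = sample_tissue_params(n_per_bin, rng)  # reuse diffusivity draws
        p = TissueParams(np.full(n_per_bin, vc), v_sph, 1.0 - vc - v_sph,
                         free.lambda_cyl, free.lambda_sph)
        clean = violated_powder_signals(p, model.protocol, cfg)
        noisy = _noisy_inputs(clean, sigma, model.protocol, rng)
        est = model.estimate(noisy, sigma)
        gold = gold_standard(p, cfg)
        rows += _stats_rows(est, gold, {
            "v_cyl_bin": vc, "v_csf": v_csf, "snr": snr, "n": n_per_bin,
        })
    return pd.DataFrame(rows)
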