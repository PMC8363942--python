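"""Train the network estimator and recover parameters from noisy signals.

Trains a compact configuration (for illustration; the desk preset in
``somamap.desk_train_config()`` is the recommended minimum), then estimates
tissue parameters from noisy powder signals of one grey-matter-like voxel.
Estimation is repeated over many noise instances to separate the
estimator's central tendency from the unavoidable per-instance noise
scatter, and the classical multi-start least-squares baseline is run on a
subset of the same instances for comparison.
"""

import numpy as np

import somamap as sm
from somamap.estimator import desk_train_config, fit_nlls, train

protocol = sm.default_protocol()
config = desk_train_config(seed=0)
print("training (desk-scale preset) ...")
model = train(protocol, config)
print(f"validation loss: {model.history['val_loss'][0]:.3f} -> "
      f"{model.history['val_loss'][-1]:.3f} in {model.history['train_seconds']:.0f} s")

truth = sm.TissueParams.from_fractions(0.35, 0.35, 2.2, 0.5)
# powder-mean noise of a 128-direction acquisition at per-direction SNR 25
sigma = 0.01
rng = np.random.default_rng(1)
clean = sm.powder_signals(truth, protocol)
n_rep = 1000
noisy = clean[None, :] + sigma * rng.standard_normal((n_rep, clean.size))

est = model.estimate(noisy, sigma).params
nlls = fit_nlls(noisy[:50], sigma, protocol, n_restarts=3, rng=2)

print(f"\n{n_rep} noise instances of one voxel (sigma = {sigma}):")
print("parameter     truth   network median [IQR]    least-squares median")
for name in ("v_cyl", "v_sph", "v_ext", "lambda_cyl", "lambda_sph"):
    n_q = np.percentile(getattr(est, name), [25, 50, 75])
    l_med = np.median(getattr(nlls, name))
    print(f"{name:<12}  {float(getattr(truth, name)):6.3f}   "
          f"{n_q[1]:6.3f} [{n_q[0]:.3f}, {n_q[2]:.3f}]     {l_med:6.3f}")

print("\nThe least-squares medians centre on the generating parameters; "
      "the network, a posterior-mean estimator, shows the shrinkage toward "
      "the prior that is typical at this noise level, with much tighter "
      "per-instance scatter - and evaluates all 1000 instances in "
      "milliseconds.")
ext = sm.tortuosity(truth.v_cyl, truth.v_sph, truth.v_ext, truth.lambda_cyl)
print(f"true derived extra-cellular diffusivities: parallel "
      f"{float(ext.lambda_par):.3f}, perpendicular "
      f"{float(ext.lambda_perp):.3f} um^2/ms")
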