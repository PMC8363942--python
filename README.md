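# somamap

Apparent neural soma density mapping from powder-averaged B-tensor
diffusion MRI.

## The problem

Conventional diffusion MRI models of brain tissue describe neural
projections (axons, dendrites, glial processes) as thin cylinders but
ignore cell bodies, which limits their usefulness in grey matter where
soma are abundant. Combining two diffusion-encoding shapes — linear tensor
encoding (LTE, conventional directional weighting, b_delta = 1) and
spherical tensor encoding (STE, isotropic weighting, b_delta = 0) — makes
quasi-spherical and quasi-cylindrical cellular structures separable at
clinically available gradient strengths and scan times.

`somamap` implements the complete simulation-and-estimation machinery for
this approach, aimed at diffusion-MRI methods researchers:

- the three-compartment powder-averaged signal model

      S(b, b_delta)/S0 = sum_i v_i
          * sqrt(pi)/2 erf(sqrt(x_i))/sqrt(x_i)
          * exp(-b [ (1-b_delta)/3 l_par_i + (2+b_delta)/3 l_perp_i ]),
      x_i = b b_delta (l_par_i - l_perp_i),

  with stick (l_par = lambda_cyl, l_perp = 0), sphere
  (l_par = l_perp = lambda_sph) and tortuosity-coupled extra-cellular
  compartments, four free parameters: v_cyl, v_sph, lambda_cyl, lambda_sph;
- b-tensor and protocol tooling (shape/waveform construction and
  validation, scheme files, protocol fingerprints);
- a simulation-trained three-layer network estimator with a bounded logit
  output parameterisation, plus a classical multi-start least-squares
  baseline;
- generative "violation" variants (CSF partial volume, compartmental T2
  differences, non-zero stick radius, myelin volume, tortuosity
  perturbations, gamma-distributed sphere diffusivities, explicit
  kurtosis) and harnesses that quantify the estimator's bias under each;
- powder averaging of directional NIfTI volumes and a synthetic 3-D
  phantom for end-to-end map recovery.

## Worked example

```python
import numpy as np
import somamap as sm
from somamap.estimator import desk_train_config, train

protocol = sm.default_protocol()      # 4 STE + 4 LTE shells, TE 94 ms
model = train(protocol, desk_train_config(seed=0))   # ~8 min on one CPU

truth = sm.TissueParams.from_fractions(0.35, 0.35, 2.2, 0.5)
clean = sm.powder_signals(truth, protocol)
noisy = clean + 0.04 * np.random.default_rng(1).standard_normal(clean.shape)
est = model.estimate(noisy, 0.04)
print(est.params.v_cyl, est.params.v_sph, est.params.lambda_cyl)
```

Running `python examples/02_train_and_estimate.py` estimates 1000 noise
instances of one grey-matter-like voxel at the in-vivo-equivalent
powder-mean noise (sigma = 0.01) and prints

```
parameter     truth   network median [IQR]    least-squares median
v_cyl          0.350    0.422 [0.396, 0.448]      0.352
v_sph          0.350    0.347 [0.322, 0.371]      0.377
v_ext          0.300    0.231 [0.219, 0.244]      0.267
lambda_cyl     2.200    1.946 [1.871, 2.020]      2.208
lambda_sph     0.500    0.872 [0.854, 0.891]      0.502
```

— the least-squares medians centre on the generating parameters, while the
network (a posterior-mean estimator) trades a visible shrinkage toward the
prior for a much tighter per-instance scatter and millisecond-scale
evaluation. The other examples cover the signal model and its
contrast-inversion effect (`01`), estimator bias under model violations
(`03`), and phantom map fitting (`04`).

A thin CLI wraps the same library calls:

```sh
somamap train --scale desk --seed 0 --out model.h5
somamap simulate --shape 32 32 4 --seed 0 --out-prefix phantom
somamap experiment myelin --model model.h5 --out myelin.csv
```

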