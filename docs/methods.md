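# Methods

## Biophysical model

`somamap` models each imaging voxel as a powder of microscopic domains, each
containing three Gaussian diffusion compartments:

- **Neural projections** (axons, dendrites, glial processes): zero-radius
  sticks, `D_cyl = diag(lambda_cyl, 0, 0)`. The parallel stick diffusivity
  equals the intrinsic neural diffusivity lambda.
- **Neural soma** (neuronal and glial cell bodies): isotropic spheres with
  apparent diffusivity `lambda_sph <= lambda_cyl`. This is an *apparent*
  quantity entangling bulk diffusivity, restriction and exchange; no single
  biological meaning is ascribed to it.
- **Extra-cellular space**: an axially symmetric tensor coupled to the
  cellular fractions through a tortuosity power law,

      lambda_par_ext  = lambda * v_ext^( (v_sph/2) / (v_sph + v_cyl) )
      lambda_perp_ext = lambda * v_ext^( (v_sph/2 + v_cyl) / (v_sph + v_cyl) )

  In the limit of no cellular structures the extra-cellular space is free
  water (both diffusivities equal lambda), which is how CSF is absorbed by
  the model.

Volume fractions satisfy `v_cyl + v_sph + v_ext = 1`, leaving four
independent parameters: `v_cyl, v_sph, lambda_cyl, lambda_sph`. Units are
um^2/ms for diffusivities and ms/um^2 for b-values (so `b * lambda` is
dimensionless); the free-water ceiling is `lambda_free = 3.0` um^2/ms.

Orientation dispersion is removed by powder averaging: the mean signal over
uniformly rotated encodings depends only on (b, b_delta) and the compartment
eigenvalues. For an axially symmetric compartment,

    h(b, b_delta) = sqrt(pi)/2 * erf(sqrt(x))/sqrt(x)
                    * exp(-b [ (1-b_delta)/3 lambda_par
                             + (2+b_delta)/3 lambda_perp ]),
    x = b * b_delta * (lambda_par - lambda_perp),

with the factor -> 1 as x -> 0. A series expansion is used for |x| < 1e-6 to
avoid 0/0, and x < 0 (planar-type encoding) continues through the imaginary
error function; the default protocols use only LTE (b_delta = 1) and STE
(b_delta = 0).

## Protocol

The default acquisition mirrors a clinically viable 3T scan: four STE shells
at b = 500/1000/1500/2000 s/mm^2 and four LTE shells at
b = 1000/2000/3500/5000 s/mm^2, 128 waveform rotations per encoding split
equally over its four shells (the split is configurable; any remainder goes
to the highest shell), TE = 94 ms, 12 b=0 volumes. Each protocol carries a
fingerprint (hash of ordered shell b, b_delta, direction counts, TE, b=0
count); estimators refuse signals from protocols they were not trained on.
Gradient waveforms can be validated and integrated to b-tensors
(trapezoidal quadrature with the spin-echo sign flip), but waveform
*design* (slew/amplitude-constrained optimisation, Maxwell compensation)
is out of scope.

## Noise conventions

`sigma` always denotes the standard deviation of the noise in the
T2-normalised powder-averaged shell signals — the quantities the estimator
actually sees — at the protocol's per-shell direction counts. SNR = 1/sigma
on that scale; the training prior is log-uniform on [0.01, 1], covering SNR
1-100. Two consequences:

- Shells whose direction count differs from the protocol average are scaled
  by sqrt(mean count / shell count) (equal-split protocols are unaffected).
- Acquisitions with fewer/more directions than the protocol are emulated by
  scaling sigma with sqrt(count ratio): 16 of 128 directions per encoding
  multiplies the powder-mean noise by sqrt(8). This is what makes precision
  improve with direction count at fixed per-direction SNR.

When sigma is estimated from b=0 repeats (`powder_average`), the per-repeat
standard deviation is divided by sqrt(average per-shell direction count) to
land on the powder-mean scale. Rician bias correction
(`rician_bias_correct`) numerically inverts the Rician expectation of a
magnitude measurement and is available for magnitude data; synthetic studies
default to Gaussian noise.

## Estimator

The network maps the 8 shell means plus sigma (9 inputs) to four unbounded
outputs:

    z1 = logit(v_cyl + v_sph)            z2 = logit(v_cyl / (v_cyl + v_sph))
    z3 = logit(lambda_cyl / lambda_free) z4 = logit(lambda_sph / lambda_cyl)

The inverse transform maps any real z to a physically valid parameter set,
so estimates are bounded by construction. Ratios at exactly 0 or 1 are
clipped at eps = 1e-6 (with a warning): uniform priors hit the boundary with
probability zero but evaluation grids do not.

Architecture: three fully connected layers with rectified linear units,
implemented directly on numpy (float32 BLAS matmuls, He initialisation).
Training: mean-squared error on the logits, stochastic gradient descent with
learning rate 0.001 and momentum 0.9, 75/25 train/validation split, and —
the key regularisation — fresh Gaussian noise drawn for every batch of
every epoch with each sample's sigma, so no noisy instance is ever seen
twice. Divergent loss raises with diagnostics; identical seeds give
bit-identical weights.

Two scales are provided:

| preset | samples | epochs | hidden | batch | CPU time |
|---|---|---|---|---|---|
| `TrainConfig()` (full) | 2^20 | 100,000 | 256,256 | 4096 | hours-days |
| `desk_train_config()` | 2^17 | 800 | 64,64 | 256 | ~8 min |

The desk preset is used by the test-suite and the acceptance script; its
validation loss and bias figures are within a few percent of wider/longer
configurations (hidden widths 96/128, 2x-7x the update count and batch
sizes 256-4096 were compared and plateau together), so the reproduced
bias figures are not capacity-limited. Hidden widths and batch size are
open configuration.

One accuracy limit is informational rather than a training artefact: at
the lower edge of the noise prior (sigma = 0.01 on the shell means), even
maximum-likelihood fitting of noise-free signals in the well-conditioned
region leaves a mean absolute error near 0.05-0.09 on the volume
fractions, and the network's posterior-mean behaviour matches that floor.
In degenerate corners (pure free water, where a sphere at 3 um^2/ms and
free extra-cellular water produce identical signals) the posterior mean
assigns a non-zero spherical fraction (~0.15) where a mode-seeking fitter
returns ~0; both behaviours are reported by the harnesses.

A classical baseline, `fit_nlls`, performs multi-start unweighted/
inverse-sigma-weighted least squares in the same logit space and serves as
an independent cross-check; on noise-free model signals it recovers all
four parameters to 1e-3.

## Violation generators

Each `ViolationConfig` kind replaces the ideal generator by one departure.
All variants are T2-normalised against a b=0 reference carrying the same
compartmental T2 weights, so the effective signal fractions are
`f_i = v_i exp(-TE/T2_i) / sum_j v_j exp(-TE/T2_j)` with TE = 94 ms:

- **csf** — fourth free-water compartment (3 um^2/ms) with T2 = 2 s against
  tissue T2 = 0.1 s; tissue simplex draws are scaled by (1 - v_csf). Gold
  standard for the extra-cellular fraction is v_ext + v_csf.
- **compartmental_t2** — intra-cellular T2 fixed at 0.1 s, extra-cellular
  T2 swept over [0.03, 0.1] s.
- **perp_stick** — non-zero cylinder perpendicular diffusivity (default
  sweep {0, 0.005, 0.01, 0.02, 0.05} um^2/ms; the value reported for 3T
  axon calibres is < 0.01).
- **myelin** — MR-invisible fraction v_myelin occupying physical space: it
  enters the tortuosity denominators and the perpendicular exponent, and
  the visible fractions are rescaled. Gold standard is
  v_i / (1 - v_myelin), i.e. fractions of MR-visible volume.
- **tortuosity_perp / tortuosity_both** — extra-cellular diffusivities
  scaled by alpha (perpendicular only, parallel floored at the new
  perpendicular) or beta (both), clipped at lambda_free; sweep [0.5, 1.5].
- **gamma_sph** — spherical diffusivities drawn per microdomain from a
  gamma distribution with the sample's mean and a swept variance
  ([0, 0.1] (um^2/ms)^2), Monte-Carlo averaged over N = 10,000 draws
  (fixed seed). The gamma Laplace transform (1 + b theta)^(-k) is used as
  a test oracle only.
- **kurtosis** — spherical log-signal gains + K_T/6 b^2 lambda_sph^2,
  K_T in [-0.7, 0.7], with lambda_sph <= 3/(b_max K_T) enforced for
  K_T > 0 (b_max = 5 ms/um^2) so the signal stays monotone; sampler draws
  violating the bound get lambda_sph redrawn uniformly below it.

## Priors and sampling

Volume fractions are uniform on the 2-simplex (Dirichlet(1,1,1)).
Diffusivities are uniform on the constrained triangle
0 <= lambda_sph <= lambda_cyl <= 3 via uniform simplex draws of the scaled
increments — the unique reading of a "uniform 2-simplex" prior consistent
with those constraints. Evaluation grids: fraction simplex at step 0.05
(231 points) with diffusivities 0.5-3.0 in steps of 0.5 (lambda_sph <=
lambda_cyl), and 107,520 uniform draws for the pooled studies; harness
sample counts are arguments, and the test-suite runs them at 3,000-20,000
samples, which changes confidence-interval widths but not means beyond
sampling error.

## What the synthetic data do and do not emulate

The generators emulate T2-normalised powder-averaged signals with
additive Gaussian (optionally Rician) noise under multiple-Gaussian-
compartment physics. They do not emulate time-dependent diffusion or
restriction within the encoding waveform, exchange between compartments,
spatial noise correlations, motion/eddy/Gibbs artefacts, or partial volume
between labelled phantom regions. Passing tests therefore demonstrate
correctness of the method under its own assumptions and quantify its bias
under the listed departures — not performance on scanner data.

## Numerical choices

- erf-ratio series below |x| = 1e-6; Dawson/erfi branch for b_delta < 0.
- Logit clipping eps = 1e-6; network float32; training deterministic per
  seed.
- NLLS: Levenberg-Marquardt in the unbounded logit space, started from
  z = 0 plus N(0, 1.5^2) random restarts, followed (whenever the best cost
  is not already numerically zero) by a profile search over the
  soma-diffusivity coordinate: the sphere/extra-cellular trade-off forms a
  narrow curved valley that plain multistart misses, but conditional
  three-parameter fits along a coarse z4 grid locate it reliably.  Flat
  degenerate signals converge to a no-attenuation solution without error.
- Rician inversion by bisection on [0, m + 5 sigma]; measurements at or
  below the Rayleigh floor sigma sqrt(pi/2) map to 0.
- Waveform b-tensors: left-Riemann q accumulation, trapezoidal qq'
  integration; rephasing enforced to |q(TE)| <= 1e-6 of peak |q|. Agreement
  with the rectangular-pulse closed form is < 0.1% at dt = 10 us.
- Phantom default 64x64x8 with WM/GM/CSF quadrants plus a CSF-contaminated
  WM strip (v_csf = 0.3); tests use smaller grids for runtime.

## Known limitations

- The estimator is bound to its training protocol fingerprint; changing
  b-values or encodings requires retraining (direction count and noise
  level do not).
- Mean biases reproduced at desk scale carry the residual approximation
  error of the desk-trained network (ideal-data mean bias of order 0.04 on
  v_cyl at SNR 25), which is part of the estimator under study, not of the
  generators.
- lambda_sph estimates are unreliable where v_sph is small (and
  lambda_cyl where v_cyl is small); the simplex and sweep harnesses
  quantify this.
- No spatial regularisation: voxels are estimated independently.
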