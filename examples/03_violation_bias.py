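"""Estimator bias when the generative model departs from the assumptions.

Trains a desk-scale estimator on the ideal equal-T2 model, then feeds it
synthetic data in which the extra-cellular space has a shorter T2 than the
intra-cellular compartments (0.03 s vs 0.1 s at TE = 94 ms).  The faster
extra-cellular relaxation suppresses that compartment's signal, which the
estimator misreads as extra cylinder fraction: v_cyl is overestimated and
v_ext underestimated by roughly equal amounts.
"""

import somamap as sm
from somamap.estimator import desk_train_config, train
from somamap.experiments import run_violation_experiment

protocol = sm.default_protocol()
print("training desk-scale estimator ...")
model = train(protocol, desk_train_config(seed=0))

df = run_violation_experiment(model, "compartmental_t2",
                              magnitudes=[0.1, 0.05, 0.03],
                              n_samples=10_000, snr=25.0, seed=3)
print("\nextra-cellular T2 [s]   mean bias v_cyl   mean bias v_ext")
for mag in (0.1, 0.05, 0.03):
    sub = df[df.magnitude == mag].set_index("parameter")
    print(f"{mag:>18.2f}      {sub.loc['v_cyl', 'mean_bias']:+13.3f}   "
          f"{sub.loc['v_ext', 'mean_bias']:+14.3f}")
print("\nAt equal T2 (0.1 s) only the estimator's own small residual bias "
      "remains; as the T2 gap widens, extra-cellular signal is attributed "
      "to cylinders (+bias in v_cyl, matching -bias in v_ext).")
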