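"""Powder-averaged signals of the three-compartment model.

Builds white-matter-like and grey-matter-like parameter sets, evaluates the
powder-averaged signal on the 8-shell LTE+STE protocol, and shows the
contrast inversion that motivates combining the two encodings: at
b = 2000 s/mm^2 the stick-rich white matter is brighter under linear
encoding, while the soma-rich grey matter is brighter under spherical
encoding.
"""

import numpy as np

import somamap as sm

protocol = sm.default_protocol()
wm = sm.TissueParams.from_fractions(v_cyl=0.7, v_sph=0.1, lambda_cyl=2.3, lambda_sph=0.6)
gm = sm.TissueParams.from_fractions(v_cyl=0.25, v_sph=0.4, lambda_cyl=2.0, lambda_sph=0.6)

print("shell   b[s/mm^2]  shape   S_WM     S_GM")
for shell, s_wm, s_gm in zip(protocol.shells,
                             sm.powder_signals(wm, protocol),
                             sm.powder_signals(gm, protocol)):
    enc = "STE" if shell.b_delta == 0 else "LTE"
    print(f"{enc}    {shell.b * 1000:7.0f}    {shell.b_delta:+.1f}  {s_wm:.4f}   {s_gm:.4f}")

lte = sm.powder_signal(wm, sm.Shell(2.0, 1.0, 1)), sm.powder_signal(gm, sm.Shell(2.0, 1.0, 1))
ste = sm.powder_signal(wm, sm.Shell(2.0, 0.0, 1)), sm.powder_signal(gm, sm.Shell(2.0, 0.0, 1))
print(f"\nAt b=2000 s/mm^2: LTE WM {lte[0]:.3f} > GM {lte[1]:.3f}, "
      f"but STE WM {ste[0]:.3f} < GM {ste[1]:.3f} - the contrast inversion "
      "that makes soma density estimable at clinical field strengths.")

# the powder average is exactly the orientation average of the directional signal
rng = np.random.default_rng(0)
axes = rng.standard_normal((50_000, 3))
axes /= np.linalg.norm(axes, axis=1, keepdims=True)
bt = sm.make_btensor(5.0, 1.0, [0, 0, 1])
mc = sm.microdomain_signal(bt, wm, axes).mean()
analytic = sm.powder_signal(wm, sm.Shell(5.0, 1.0, 1))
print(f"\nOrientation-average check at LTE b=5000: Monte-Carlo {mc:.5f} "
      f"vs analytic {analytic:.5f}")
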