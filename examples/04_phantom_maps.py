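"""End-to-end phantom: generate a labelled volume, fit maps, check contrast.

Builds the default four-region phantom (white-matter-like, grey-matter-like,
CSF-like, and a CSF-contaminated white-matter interface strip) at SNR 25,
fits it voxel-by-voxel with a desk-scale trained network, and prints region
medians of the fitted maps.
"""

import numpy as np

import somamap as sm
from somamap.estimator import desk_train_config, train
from somamap.phantom import default_phantom_spec, fit_volume, generate_phantom

protocol = sm.default_protocol()
print("training desk-scale estimator ...")
model = train(protocol, desk_train_config(seed=0))

spec = default_phantom_spec((32, 32, 4))  # in-vivo-equivalent powder-mean SNR
pv, truth = generate_phantom(spec, protocol, seed=4)
maps = fit_volume(model, pv)

names = {1: "WM-like", 2: "GM-like", 3: "CSF-like", 4: "CSF/WM interface"}
print(f"\n{'region':<18} {'v_cyl':>7} {'v_sph':>7} {'v_ext':>7} "
      f"{'l_cyl':>7} {'l_sph':>7} {'rms':>7}")
for label, name in names.items():
    vox = spec.labels == label
    row = [np.nanmedian(maps[k][vox]) for k in
           ("v_cyl", "v_sph", "v_ext", "lambda_cyl", "lambda_sph", "rms_residual")]
    print(f"{name:<18} " + " ".join(f"{v:7.3f}" for v in row))

print("\nExpected contrast: v_cyl is highest in the WM-like region and "
      "v_sph in the GM-like region; in CSF, v_cyl is near zero while "
      "v_sph keeps a small residue (free water is degenerate with a "
      "sphere at the free-water diffusivity, and the posterior-mean "
      "estimator splits the difference).  In the interface strip, CSF "
      "partial volume inflates v_sph relative to pure WM - the headline "
      "failure mode of CSF contamination.")
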