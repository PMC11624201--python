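"""Recover perfusion maps and the core:penumbra ratio from a CTP phantom.

A noise-free dynamic series is simulated from known CBF/MTT/delay fields,
deconvolved with the block-circulant truncated SVD, and thresholded into
ischemic core (relative CBF < 30%) and penumbra (Tmax > 6 s).
"""

import numpy as np

from ischclock import ctp
from ischclock.phantom import default_ctp_spec, generate_ctp_series

spec = default_ctp_spec(noise_sd=0.0)
frames, timestamps, truth = generate_ctp_series(spec)
maps = ctp.compute_perfusion_maps(frames, timestamps, spec.aif_voxel,
                                  spec.vof_voxel, spacing=spec.spacing,
                                  sv_threshold_frac=0.001)

brain = truth["brain"].copy()
brain[spec.aif_voxel] = brain[spec.vof_voxel] = False
rel = np.abs(maps.cbf[brain] - truth["cbf"][brain]) / truth["cbf"][brain]
print(f"median CBF recovery error: {100 * np.median(rel):.1f}%")

ref = ctp.hemispheric_reference(maps.cbf, brain, "left")
mm = ctp.core_penumbra(maps, ref, brain)
vox_ml = float(np.prod(spec.spacing)) / 1000.0
print(f"core     {mm.core_volume_ml:5.2f} mL  "
      f"(truth {truth['core'].sum() * vox_ml:5.2f})")
print(f"penumbra {mm.penumbra_volume_ml:5.2f} mL  "
      f"(truth {truth['penumbra'].sum() * vox_ml:5.2f})")
print(f"core:penumbra ratio {mm.cpr:.3f}; treatable mismatch "
      f"(CPR <= 0.8): {mm.treatable}")
print("-> the deconvolution recovers the programmed flow deficit and the"
      " mismatch classification used to select revascularisation patients.")
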