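"""Build one synthetic NCCT brain and measure its lesion's relative intensity.

The phantom programs a known water-uptake deficit; relative intensity (RI,
equivalent to net water uptake) should recover the programmed fraction from
the lesion vs its mirrored contralateral region.
"""

from ischclock.io_preprocess import mirror_mask
from ischclock.nwu import relative_intensity
from ischclock.phantom import PhantomSpec, aging_response, generate_ncct_phantom

spec = PhantomSpec(true_age=24.0, noise_sd=0.5, seed=42)
vol, mask, true_age = generate_ncct_phantom(spec)
ri = relative_intensity(vol, mask, mirror_mask(mask))

programmed = spec.uptake_rate * aging_response(true_age)
print(f"lesion age (programmed): {true_age:.1f} h")
print(f"programmed uptake fraction: {programmed:.3f}")
print(f"measured relative intensity: {ri.ri:.3f} "
      f"({ri.n_lesion_voxels} lesion voxels)")
print("-> RI recovers the programmed fractional HU deficit; on real NCCT it"
      " is the standard net-water-uptake proxy for lesion age.")
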