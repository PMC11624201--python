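"""Added value of an imaging age biomarker for predicting infarct growth.

The synthetic growth cohort programs % lesion growth as a function of
baseline volume, inter-scan interval, NIHSS and a latent biological lesion
age. Chronometric onset time is a noisy readout of that latent age; the
imaging biomarker is a low-noise readout. Adding each to the baseline
regression shows the biomarker carries more growth information.
"""

from ischclock.growth import added_value, compare_added_values, fit_growth_baseline
from ischclock.phantom import generate_growth_cohort

table = generate_growth_cohort(500, seed=1)
base = fit_growth_baseline(table)
print("baseline model t statistics:")
for name in ("v1", "interval", "nihss", "age", "sex", "lysis"):
    print(f"  {name:9s} t = {base.tvalues[name]:6.2f}")

bio = added_value(table, "biomarker", baseline=base)
cots = added_value(table, "cots", baseline=base)
z, p = compare_added_values(bio, cots)
print(f"biomarker: beta = {bio.coefficient:6.1f}, t = {bio.t:6.1f}")
print(f"cots:      beta = {cots.coefficient:6.1f}, t = {cots.t:6.1f}")
print(f"coefficient comparison: Z = {z:.2f}, p = {p:.4f}")
print("-> the low-noise biological-age biomarker predicts growth more"
      " strongly than chronometric onset time, whose coefficient is"
      " attenuated by the biology/clock dissociation.")
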