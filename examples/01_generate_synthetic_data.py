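"""Generate the 9-run CC-DoE synthetic fed-batch dataset and inspect it.

A reduced CHO-like kinetic model is simulated over a central composite
design of pre-/post-induction feed rates (4 square + 4 star + 1 center run,
240 h, 24 h sampling, 25 recorded species), then corrupted with Gaussian
noise of SD = 10% of each species' maximum concentration.
"""

import numpy as np

import biohybrid as bh

noisy, clean, truth = bh.make_cc_doe_dataset(seed=1)
sp = clean.species

print(f"{len(clean.experiments)} experiments, {sp.n} species, "
      f"{clean.experiments[0].times.size} samples each "
      f"({clean.n_residuals} scalar measurements)")

center = truth["ce1"]
for name in ("Xv", "Glc", "Lac", "mAb"):
    i = sp.index(name)
    print(f"{name:>4s} (center run): {np.round(center.conc[:, i], 2)}")

# the lactate metabolic shift: net specific rate changes sign mid-culture
i_lac = sp.index("Lac")
v_lac = center.rates[:, i_lac]
t_shift = center.times[np.argmax(v_lac < 0)]
print(f"\nlactate specific rate: {np.round(v_lac, 3)}")
print(f"production switches to consumption at ~{t_shift:.0f} h "
      "(glucose depletion releases the overflow pathway)")

# noise level: measured minus true, in units of the 10%-of-max SD
z = np.concatenate([
    (n.values - c.values) / (0.1 * sp.cmax)
    for n, c in zip(noisy.experiments, clean.experiments)
]).ravel()
print(f"\nadded noise: sample SD = {z.std(ddof=1):.3f} "
      "(1.0 = exactly the specified 10%-of-max error model)")

train_ids, test_ids = bh.cc_doe_split(noisy)
print(f"design split: train on {train_ids} (center+square), "
      f"extrapolation test on {test_ids} (star)")
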