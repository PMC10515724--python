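"""Train one hybrid structure with both regimes on a reduced problem.

Classical regime: Levenberg-Marquardt steps with indirect sensitivities and
early stopping on a noise-augmented validation copy, best of several random
restarts. Deep regime: ADAM with semidirect sensitivities and stochastic
regularization (minibatch + dropout), single initialization, keeping the
minimum-training-error iterate. Runs in ~2 minutes at this reduced scale.
"""

import numpy as np

import biohybrid as bh

noisy, clean, _ = bh.make_cc_doe_dataset(seed=1)
train_ids, test_ids = bh.cc_doe_split(noisy)
train, test = noisy.subset(train_ids), noisy.subset(test_ids)
vmax = noisy.provenance["volume_max"]
substep = 4.0  # coarse integration for speed; evaluation uses 0.5 h

model = bh.HybridModel.initialized(
    noisy.species, (10, 10), "tanh", seed=0, volume_input=vmax, substep=substep
)
print(f"structure 26-[10,10]-25 ({model.n_weights} weights), "
      f"train on {train_ids}, test on {test_ids}\n")

lmm = bh.train_lmm(
    model, train,
    bh.LmmConfig(max_iterations=25, restarts=2, patience=15, seed=0),
    substep=substep,
)
fitted = model.with_weights(lmm.kept_weights)
w_tr, _, _ = bh.wmse_objective(fitted, train, substep=0.5)
w_te, _, _ = bh.wmse_objective(fitted, test, substep=0.5)
print(f"LMM : {len(lmm.train_wmse)} accepted steps, kept iteration "
      f"{lmm.kept_iteration} (min validation error)")
print(f"      train WMSE {w_tr:.2f}, star-point test WMSE {w_te:.2f}")

adam = bh.train_adam(
    model, train,
    bh.AdamConfig(alpha=0.005, iterations=150, seed=0),
    substep=substep,
)
fitted = model.with_weights(adam.kept_weights)
w_tr, _, _ = bh.wmse_objective(fitted, train, substep=0.5)
w_te, _, _ = bh.wmse_objective(fitted, test, substep=0.5)
print(f"ADAM: 150 iterations, kept iteration {adam.kept_iteration} "
      f"(min full-batch training error)")
print(f"      train WMSE {w_tr:.2f}, star-point test WMSE {w_te:.2f}")

print("\nWMSE ~ 1 is the noise floor; LMM's curvature steps converge in far "
      "fewer iterations at this network size, while ADAM needs hundreds of "
      "iterations but scales to deep/wide networks where LMM destabilizes")
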