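"""Model-selection arithmetic: WMSE, AICc, resampling, structure comparison.

Shows the two selection routes — the corrected Akaike criterion computed on
training error alone, and resampled test error over shared train/test
partitions — plus the percentage-delta arithmetic used to compare a shallow
against a deep structure.
"""

import numpy as np

import biohybrid as bh

# WMSE and AICc on worked numbers
pred, meas, sig = np.array([2.0, 4.0]), np.array([1.0, 2.0]), np.array([1.0, 2.0])
print(f"wmse((2,4) vs (1,2), sigma (1,2)) = {bh.wmse(pred, meas, sig):.1f}")
print(f"aicc(WMSE=1, T=100, nw=10) = {bh.aicc(1.0, 100, 10):.3f} "
      "(pure complexity penalty: 2nw + small-sample correction)")

# resampled partitions are shared across structures for paired comparison
plan = bh.resample_partitions([f"b{i}" for i in range(9)], n_partitions=3,
                              n_test=4, seed=7)
for k, (tr, te) in enumerate(plan.pairs):
    print(f"partition {k}: test={te}")

# a fast LMM sweep over two structures on the synthetic CC-DoE data
from biohybrid.workflows import structure_sweep_study

report = structure_sweep_study(
    seed=1, structures=(((6,), "tanh"), ((7, 7), "relu")), trainer="lmm",
    n_partitions=2, lmm_iterations=12,
)
cols = ["structure", "train_wmse_mean", "test_wmse_mean", "n_weights", "chosen"]
print("\n" + report.to_dataframe()[cols].round(2).to_string(index=False))
print(f"selection rule: lowest mean test WMSE -> structure {report.chosen.label}")

# percentage-delta arithmetic between two summary rows
shallow = {"train_wmse_mean": 1.57, "test_wmse_mean": 2.46, "n_weights": 1067}
deep = {"train_wmse_mean": 1.35, "test_wmse_mean": 1.88, "n_weights": 2855}
out = bh.compare_structures(shallow, deep)
print(f"\nshallow vs deep summary rows: train error reduced "
      f"{out['train_reduction_pct']:.1f}%, test error reduced "
      f"{out['test_reduction_pct']:.1f}%, weights up "
      f"{out['weights_increase_pct']:.1f}%")
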