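"""Build a hybrid model and integrate it through a fed-batch schedule.

The hybrid model couples fed-batch material balances (dilution + feeding)
with a neural network supplying the specific reaction rates from normalized
concentrations (plus normalized volume). Here the network is untrained, so
the simulation shows what the mechanistic skeleton contributes on its own:
volume tracking and feed dilution are exact regardless of the network.
"""

import numpy as np

import biohybrid as bh

species = bh.SpeciesSet(("Xv", "Glc", "Lac"), np.array([12.0, 40.0, 50.0]))
model = bh.HybridModel.initialized(
    species, hidden=(8, 8), activation="relu", seed=0, volume_input=0.5,
)
print(f"architecture: {model.layout.n_in} inputs -> {model.layout.hidden} "
      f"-> {model.layout.n_out} outputs ({model.n_weights} weights)")

feed = bh.FeedStream(
    np.array([0.0, 130.0, 0.0]),                  # glucose-rich feed
    ((0.0, 96.0, 5e-4), (96.0, 240.0, 1e-3)),     # rate switch at induction
)
initial = bh.ProcessState(np.array([3.0, 35.0, 1.5]), V=0.25, t=0.0)
times = np.arange(0.0, 241.0, 24.0)
traj = model.simulate(initial, [feed], times)

print("\n  t(h)    V(L)     Xv     Glc     Lac")
for t, v, c in zip(traj.times, traj.volume, traj.conc):
    print(f"{t:6.0f}  {v:6.3f}  {c[0]:6.2f}  {c[1]:6.2f}  {c[2]:6.2f}")

added = 96 * 5e-4 + 144 * 1e-3
print(f"\nvolume balance: V(240) - V(0) = {traj.volume[-1] - 0.25:.4f} L, "
      f"integral of feed schedule = {added:.4f} L (exact for RK4)")
print("the near-zero random initialization gives small but nonzero specific "
      "rates: feeding dominates the metabolite balances, and Xv drifts with "
      "its tiny autocatalytic rate — training is what shapes these curves")
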