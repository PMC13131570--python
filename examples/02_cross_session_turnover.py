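"""Compare the learning network with the recall network for one animal.

The generator retains a known fraction q of training edges into the test
session, so the measured survival should sit at ~100q; Jaccard, turnover, and
the per-neuron turnover index summarise the same reorganisation from
different angles.
"""

from engramnet import compare_sessions, simulate_animal

q = 0.5  # ground-truth retention: half the training edges survive to recall
bundle = simulate_animal("control", seed=7, q=q, sessions=("training", "test"))
rep = compare_sessions(bundle.rasters["training"], bundle.rasters["test"], bundle.regmap)

print(f"shared neurons: {rep.n_shared_neurons}")
print(f"Jaccard similarity of edge sets: {rep.jaccard:.3f}")
print(f"edge turnover (1 - Jaccard):     {rep.turnover:.3f}")
print(f"cosine similarity of weights:    {rep.cosine:.3f}")
print(f"training-edge survival: {rep.survival_rate:.1f}%   (ground truth: {100*q:.0f}%)")
print(f"training-edge loss:     {rep.loss_rate:.1f}%")
print(f"testing-edge gain:      {rep.gain_rate:.1f}%   (new edges at recall)")
print(f"mean per-neuron turnover index: {rep.mean_edge_turnover_ti:.1f}% "
      f"(share of each neuron's partners replaced)")
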