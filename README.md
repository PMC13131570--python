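# engramnet

Coactivity-network analysis of longitudinal calcium-imaging event rasters:
how a learning-related neuronal ensemble's pairwise coactivity structure
forms, consolidates, reorganises, and predicts whether a memory survives.

The package is written for systems-neuroscience analysts working with
miniscope/CNMF-E-style event rasters recorded across multiple sessions of the
same animal (learning, post-learning reactivation, an interfering novel
experience, and memory testing). It takes as input plain-text event tables,
cross-session cell-registration maps, behavioural occupancy epochs, and
per-animal outcome labels — and it ships a fully ground-truthed synthetic
generator of the same multi-session design, so every statistic in the chain
can be validated by parameter recovery.

## The model

From a session's event raster `E ∈ N^{T×N}` (frames × neurons, 10 Hz), a
**weighted coactivity network** is built with a 1-s sliding window (10
frames, step 1): for every window position, each unordered pair of neurons
both active within the window increments its count, giving a symmetric count
matrix `C` with zero diagonal, read as the graph `G = (V, E, W)`.

Cross-session reorganisation is measured on the binary edge sets of the
aligned (shared-neuron) networks, with the training session as reference:

- Jaccard = |E₁∩E₂| / |E₁∪E₂|, turnover = 1 − Jaccard;
- training-edge loss = 100·|E₁\E₂|/|E₁|, survival = 100·|E₁∩E₂|/|E₁|,
  testing-edge gain = 100·|E₂\E₁|/|E₂|;
- cosine similarity of the weighted networks;
- per-neuron turnover index Ti(i) = 100·(1 − |E_i¹∩E_i²| / |E_i¹∪E_i²|)
  over each neuron's incident edges.

Node-level topology (degree, unnormalised betweenness, within-component
closeness, weighted eigenvector centrality, clustering) is z-scored within a
session and compared between NE-specific neurons (active during novelty
exploration, silent during training) and the rest by two-sided rank-sum.
Robustness of the training-edge network is summarised by k-core peeling:
occupancy N(k) for k = 0…k_max and the normalised area under the curve,
AUC_norm = ∫N(k)dk / (N₀·k_max).

Finally, the six remodelling features (Jaccard, turnover, mean Ti, survival,
loss, gain) feed an elastic-net logistic model `P(forget|x) = 1/(1+e^{−(β₀+βᵀx)})`
evaluated by leave-one-out cross-validation, with accuracy, confusion matrix,
ROC, and AUC over the held-out predictions.

## Worked example

```bash
python examples/02_cross_session_turnover.py
```

simulates one control animal with a known ground-truth retention of q = 0.5
(half the training edges survive to recall) and compares its training and
test networks:

```
shared neurons: 150
Jaccard similarity of edge sets: 0.412
edge turnover (1 - Jaccard):     0.588
cosine similarity of weights:    0.512
training-edge survival: 50.0%   (ground truth: 50%)
training-edge loss:     50.0%
testing-edge gain:      30.0%   (new edges at recall)
mean per-neuron turnover index: 59.5% (share of each neuron's partners replaced)
```

Survival recovers the planted retention exactly; gain recovers the planted
new-edge fraction (g = 0.30); Jaccard and turnover are the same
reorganisation seen through the union of both sessions' edges.

The other examples walk the remaining capabilities: `01` network construction
and global summaries, `03` the topological position of infiltrating NE
neurons (core-indistinguishable under interference within the consolidation
window, peripheral after it), `04` post-learning k-core maturation, `05` the
21-animal cohort classifier.

A thin CLI wraps the same pipeline for shell use:

```bash
engramnet simulate --scenario cohort --seed 1 --out runs/cohort
engramnet analyze-cohort --input runs/cohort --seed 1 --out runs/results
```

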