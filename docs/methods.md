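# Methods

## The analysis

The pipeline operates on per-session event rasters: matrices `E ∈ N^{T×N}`
of calcium event counts at a fixed frame period (default 0.1 s), where an
entry > 0 means the neuron emitted at least one detected event in that frame.
Every "active" predicate thresholds at ≥ 1 event; counts above 1 are retained
by the I/O layer but never weighted.

**Coactivity networks.** A symmetric window of `window_len` frames (default
10 = 1 s) slides across the session in steps of `step` frames (default 1).
For each window position `t` with `t + window_len ≤ T`, every unordered pair
of neurons that are both active somewhere in `[t, t + window_len)` has its
count `C_ij` incremented. Only full windows are counted, so
`0 ≤ C_ij ≤ n_windows`. `C` is read as a weighted undirected adjacency matrix
with zero diagonal. Two consequences matter for interpretation: a single
synchronous event pair contributes up to `window_len` counts (one per
overlapping window), and the binary edge predicate ("coactive at least once",
`min_weight = 1`) is therefore far less inflated than the weights themselves.
The only weight-consuming statistics — cosine similarity, restricted strength,
coactivation frequency, eigenvector centrality — are scale-consistent, so the
inflation cancels or rescales out.

**Edge sets and cross-session statistics.** Sessions are compared only on
neurons registered in both (registration is an input; neurons missing from a
session are dropped, not zero-filled, to avoid fabricating silence). With
binary edge sets `E1` (reference/training) and `E2` (comparison/testing):
Jaccard = |E1∩E2|/|E1∪E2|, turnover = 1 − Jaccard, loss = 100·|E1\E2|/|E1|,
gain = 100·|E2\E1|/|E2|, survival = 100·|E1∩E2|/|E1|. Cosine similarity is
the cosine of the two weight matrices' upper triangles on the common node
order (zero-padding edges absent from one network; any common support yields
the same value). The per-neuron turnover index is the incident-edge Jaccard
complement, `Ti(i) = 100·(1 − |E_i1∩E_i2|/|E_i1∪E_i2|)`, with neurons lacking
any incident edge in either session excluded from the mean — this is the only
reading of "percent of a neuron's connections replaced" that lands in
[0, 100].

**Topology.** Degree, betweenness (unnormalised pair counting), closeness
(within-component: (|R_i|−1)/Σd), and clustering run on the binary graph;
eigenvector centrality is the principal eigenvector of the weight matrix on
the largest component (non-negative, unit L2 norm, zero off-component),
because its defining sum runs over weights while the path metrics carry none.
Node metrics are z-scored within a session with the population standard
deviation; zero-variance metrics yield an all-zero, flagged column. Subgroups
(NE-specific vs the rest) are compared metric-wise with a two-sided
Mann-Whitney rank-sum test.

**k-core peeling.** For k = 0, 1, 2, … nodes of degree < k are removed
recursively; N(k) is the surviving count, `k_max` the deepest non-empty core,
and the robustness scalar is the trapezoidal area under N(k) normalised by
its ceiling `N0·k_max` (so 1 iff every node reaches the deepest core).
Edgeless graphs report `k_max = 0` with an undefined (None) normalised AUC
rather than 0, to keep "no structure" distinct from "measured zero". The
peel is applied by default to the subgraph induced by a reference edge set
(training edges expressed in the session) over all shared neurons, with
isolated nodes kept in `N0`.

**Classification.** Six features per animal, in fixed order: Jaccard,
turnover, mean per-neuron turnover, training-edge survival, training-edge
loss, testing-edge gain (training-vs-test comparison). The model is logistic
regression with an elastic-net penalty (default `l1_ratio = 0.5`,
`reg_strength = 1.0`, i.e. C = 1), positive class = forgetting, evaluated by
leave-one-out cross-validation. Features are re-z-scored inside each training
fold by default (leakage-free); a `cohort` mode z-scoring once across all
animals is available, matching the common published practice. Two
LOOCV-specific artifacts are handled explicitly, because pooling scores from
n differently-composed training folds into one ROC is biased: (i) fits use
inverse-class-frequency ("balanced") weights, so a fold's intercept does not
track the class it happens to be missing; (ii) the ROC is computed on
fold-centred scores — the held-out probability minus the training fold's
observed base rate. Under label permutations this pooled ROC is empirically
centred at AUC ≈ 0.5, where pooled raw probabilities are pessimistically
biased (holding out a positive lowers every probability its fold emits). Raw
probabilities are reported alongside and still drive the 0.5-threshold
accuracy and confusion matrix; ties at 0.5 predict "remember". A training
fold containing a single class emits that fold's class prior, flagged.

## The synthetic generator

The generator produces the five-session design the analysis assumes —
training, post-learning reactivation at 0.5 h and 4 h, novelty exploration
(NE), and memory testing — as 10-min, 10-Hz rasters over ~150 neurons with
full ground truth.

**Structure.** Engram nodes split into a core (default 40) and a periphery
(default 60); training edges are sampled with `p_cc = 0.20 > p_cp = 0.04 >
p_pp = 0.02`, giving a dense core (mean within-core degree ≈ 8) inside a
sparse shell, plus 40 task-silent background neurons and 10 NE neurons.

**Event placement: the slot lattice.** Sessions are rendered as "activation
packets": each expressed edge emits `1 + Poisson(λ_edge·duration − 1)`
pairwise co-activations (an edge listed as active is, by definition, observed
at least once; default λ_edge = 0.002 s⁻¹ → ≈ 1.2 co-activations per edge per
10-min session), and each neuron emits background singles at λ_bg
(default 0.001 s⁻¹). Every packet occupies its own slot on a lattice spaced
`window_len + offset_span − 1` frames (1.4 s), with events placed at uniform
offsets within the first `offset_span = 5` frames of the slot. Packet
endpoints therefore always share a coincidence window, and events from
different packets never do: the detected edge set equals the scheduled one,
with no chance edges. This is a deliberate stylisation. With free (uniform)
event times, the expected number of chance window coincidences between two
unconnected neurons is ≈ n_i·n_j·(2·window − 1)/T, which at any realistic
event count over ~11,000 pairs swamps the ground-truth edges; no edge-level
parameter would then be recoverable from the raster. Real rasters are not
lattice-structured, so passing recovery tests demonstrates correctness of the
measurement chain, not robustness to the chance-coincidence background of
real data — on real recordings the binary edge sets include a
coincidence-driven component that the paper-level statistics inherit. If
total packet demand exceeds the lattice capacity (429 slots at T = 6000), the
excess is dropped from the non-primary packets (extra co-events and
background singles) at random; each expressed edge's first packet is
protected, so expression is never silently lost.

**Session semantics.**

* *training*: all training edges expressed. NE neurons are silent (their
  NE-specificity is a ground-truth property, not a measurement accident).
* *test*: exactly `round(q·E)` training edges are retained (an exact-count
  random subset, so the controlled retention fraction is realised per animal;
  Bernoulli thinning would add ±3-4 percentage points of binomial noise that
  belongs to neither the biology being modelled nor the measurement).
  Which edges are lost is steered by a *loss diffuseness* parameter: at 1 the
  lost edges are a uniform subset, toward 0 the loss concentrates on a few
  nodes whose whole connectivity drifts out. New pairs are added among the
  task-engaged nodes to bring the new-edge fraction to `g`.
* *post_early / post_late*: reactivation is node-level — a neuron re-engages
  with probability ρ (default 0.5) early, `min(1, m·ρ)` late (maturation
  multiplier m, default 2), with coupled draws so the late network nests the
  early one; an edge is expressed iff both endpoints re-engage. Node-level
  partial reactivation is what makes the early network a sparse induced
  fragment whose core depth, density, edge presence, and normalised peeling
  AUC all sit below the late network's; with edge-level thinning the
  normalised AUC direction is not reproducible (a deeper `k_max` inflates the
  normalising ceiling faster than the curve mass grows).
* *NE*: the NE neurons' attachment edges plus a `ne_reactivation` fraction of
  training edges (engram replay during novelty); NE neurons also emit solo
  events so they are detectably NE-active.

**Infiltration depth.** NE neurons attach to existing engram nodes: in *core*
mode to the top-degree tercile, in *peripheral* mode to the bottom tercile.
The attachment count per NE neuron is by default resampled from the realised
engram degree distribution ("match"), making core-mode infiltrators
degree-exchangeable with engram members; a fixed integer count is also
supported. Core-mode attachments persist into the test session, thinned by
the same q as training edges, and each persisting attachment displaces one
retained training edge of its target — the infiltrator takes over part of the
hub's coactivity budget, which keeps target degrees unchanged (preserving
exchangeability) and makes core contamination destructive rather than
additive. Peripheral-mode attachments are expressed only during the NE
session: contact that stayed at the periphery washes out of the recall
network.

**Scenarios and cohorts.** `control` = no infiltration, retention
`q_remember = 0.5` (placing control training-edge survival near 50%), gain
`g_remember = 0.30`; `NE_0.5h` = core infiltration, `q_forget = q_remember −
d·σ_q`, `g_forget = g_remember + d·σ_g` (effect size d = 2 by default);
`NE_4h` = peripheral infiltration at control-level retention. Cohorts draw
per-animal parameters around the scenario means (σ_q = 0.05, σ_g = 0.04,
σ_diffuseness = 0.075) with a shared per-animal *expressivity* factor
inducing a within-group correlation `rho_qg = 0.5` between retention and
gain. That factor models a real structure of imaging cohorts — per-animal
differences in event detection and excitability scale retained and newly
formed edges together — and it is what lets the multivariate classifier beat
any single feature: the group effect moves q and g in opposite directions,
across the nuisance axis. The group effect on the survival feature alone
caps the achievable AUC at Φ(d/√2) ≈ 0.92 for d = 2 regardless of
classifier. Per-animal seeds derive from the master seed as
`SeedSequence([master, animal_index])`; retention/maturation/NE draws are
sub-streams of the animal seed, so any session can be re-derived
independently.

## Numerical choices

* Frames are 0-based; epochs are half-open `[start, end)`; the location gate
  is the union of `[start − lead_frames, end)`, clipped at 0 (default lead
  10 frames = 1 s).
* Windowed activity is computed from frame-count prefix sums and the count
  matrix as one boolean matrix product; results are exact integers
  (verified bit-exact against direct window enumeration).
* Density counts isolated nodes in |V|; average path length is taken over
  unordered pairs of the largest connected component and is flagged undefined
  (not 0) when that component has fewer than two nodes.
* z-scores use the population standard deviation (the session formula carries
  no sample correction); σ = 0 columns are zeroed and flagged.
* Trapezoidal integration over integer k with unit spacing for the peeling
  curve; AUC equality between the trapezoidal ROC and the Mann-Whitney
  pair-counting estimator is exact (to 1e−12) including ties.
* The elastic-net fit uses scikit-learn's saga solver, `tol = 1e-7`,
  deterministic `random_state` from the caller's seed.
* Probability draws clip per-animal parameters into valid ranges
  (q, g into [0.02, 0.98], diffuseness into [0, 1]).

## Problem sizes used in the validation suite

Unit tests run on small rasters (T ≤ 200, N ≤ 10) against brute-force
oracles. The end-to-end recovery suite uses the study-scale defaults —
T = 6000 frames (10 min at 10 Hz), 150 neurons — with 20 animals per
condition for retention/infiltration/maturation recovery and 50 cohorts of
21 animals for classifier recovery; these sizes keep every ground-truth
recovery well-powered while the full suite completes in a few minutes on one
CPU. `scripts/acceptance.py` analyses one full 21-animal cohort end to end.

## Known limitations

* The slot lattice removes chance coincidences entirely; real coactivity
  networks contain a rate-dependent coincidence background, and statistics on
  real data mix signal and chance edges.
* Calcium indicator kinetics, bursting, place fields, and behavioural
  covariates are not modelled; events are exchangeable within the session
  apart from the scheduled packets.
* The generator's group differences are imposed on edge retention, gain, and
  loss allocation; it does not model the upstream biology (protein-synthesis
  windows, receptor trafficking) that produces them.
* Occupancy tracks are alternating epochs with jittered dwell times, enough
  to exercise the gating operations but not a model of exploration behaviour.
* The per-neuron turnover index follows the incident-edge reading; the
  alternative "metric delta" reading (session-B value minus session-A value
  per neuron) is not a rate and is not implemented.
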