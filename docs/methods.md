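# Methods

## The model

A two-layer feedforward network maps nine input units onto N output
neurons through a weight matrix W (N x D).  Training is online and
unsupervised: at presentation t a sample `x = xi(p) + eps` is drawn, the
stochastic outputs `y` are sampled, and one of three weight-update rules is
applied.

**Fundamental patterns.**  Four binary prototypes over nine units.  In the
*overlapping* set, patterns 0/1 share unit 2 and patterns 2/3 share unit 6
(two interfering groups); in the *non-overlapping* set the four prototypes
occupy disjoint unit pairs.  Samples add i.i.d. Gaussian noise of standard
deviation `eta` per unit (default 0.1) — the simplest reading of a single
"noise magnitude" parameter; no clipping is applied, so sample entries may
be slightly negative.

**Output units (toy network).**  `y_i ~ Bernoulli(g(beta (u_i - h)))` with
drive `u_i = w_i . x` and logistic `g`.  A noise-driven unit with a nonzero
spontaneous rate is required because the weights start at zero and learning
must bootstrap from spontaneous coincidences.  Defaults: `beta = 8`, and a
protocol-dependent threshold `h` (below).

**Learning rules.**

* *LTP* — `W += gamma * outer(y, x)`; each neuron's row is divided by its
  maximum whenever that maximum exceeds 1.
* *LTP+LTD* — `W += gamma * outer(y, x - theta)`, same row normalization.
  `theta = 0.2` by default; any `0 < theta < 1/2` preserves the sign
  structure of the depressed equilibrium (active units at `1 - theta > 0`,
  inactive at `-theta < 0`).
* *LTP + synaptic competition* — the raw Hebbian update of neuron i is
  gated by maturation (zero once the neuron's accumulated excitatory mass
  `sum_j max(w_ij, 0)` reaches `Theta`), then centred across neurons per
  input unit: `Delta_ij = gated_ij - mean_i'(gated_i'j)`.  Every column of
  the applied update sums to zero — neurons compete for the limited
  synaptic resources of each presynaptic axon.  Normalization is per
  *column*: an input unit whose largest outgoing weight exceeds 1 has all
  its outgoing weights rescaled.  `gamma = 0.1` throughout the toy
  experiments.

Order of composition per presentation: maturation gate, competition
centring, scale by gamma, add, normalize.  The maturation condition is
strict (`mass < Theta` permits growth) and checked once per presentation.
Negative weights are permitted under LTP+LTD and competition (inhibited
input units); the LTP-only rule keeps weights nonnegative by construction.

**Maturation cap on the excitatory mass.**  The gate compares the
*positive part* of the weights against `Theta` (default 1.5), not the net
sum.  Under competition a tuned winner accumulates strongly negative
weights on the units of other patterns; counting that suppression against
the cap would keep winners formally "immature" forever, letting them drift
and erode the rest of the population.  The excitatory mass is also the
quantity the cap models biologically — the total strength of synaptic
contacts a maturing neuron can support.  The literal net-sum gate remains
available (`gate_positive_part=False`).

## Operating regimes of the stochastic unit

The threshold `h` relative to the typical post-training drive (about 1–2
for a trained row) selects one of two regimes, and the toy protocols use
the regime in which each rule's characteristic behaviour is expressed:

* **Symmetric regime** (`h = 0.1`, baseline rate ≈ 0.31) — units fire for
  every pattern; the LTP rule's updates then average over the whole
  stimulus ensemble and every neuron's profile converges to the mean
  input.  Used for the LTP-only protocol.
* **Selective regime** (`h = 0.6`, baseline rate ≈ 0.008) — a unit fires
  only when its drive approaches a full pattern, so the first patterns a
  neuron happens to fire for capture it, and depression or competition can
  stabilize the split.  Used for the LTP+LTD and competition protocols.

No single threshold does both: with a low threshold the depressed
multi-pattern states saturate and never break apart, while with a high
threshold LTP neurons lock onto the first group they fire for and the
2,000-presentation stream ends far from the symmetric equilibrium.  The
two regimes are two operating modes of the same unit, not two models, and
both are plain configuration (`SYMMETRIC_UNIT`, `SELECTIVE_UNIT`).

## Equilibrium estimation

The conditional renormalizations make the trained weights hover on a
stochastic limit cycle: after each firing the updated peak is pulled back
into `[1/(1+gamma), 1]`, so an instantaneous snapshot deviates from the
theoretical profile by up to ~0.1 even for an ideal always-firing unit.
The trainer therefore also accumulates a trailing average of W over the
final half of the stream (`tail_mean`), the standard constant-step-size
stochastic-approximation estimator of the stationary profile.  Profile
comparisons (LTP equilibrium, LTD templates) use `tail_mean`; the
competition rule's weights are frozen by maturation and its final W is
used directly.

## Analyses

* **Weight categories** — a row's category is the sorted pair of its two
  largest-weight input units.  Rows whose peak does not exceed 0.5 (half
  the normalization cap) carry no meaningful tuning and are *unresolved*;
  competition actively suppresses losing neurons to near-zero or negative
  rows, and excluding them mirrors reading tuned profiles off a figure.
  Weights within 5% of the second-largest are treated as tied, and the
  lowest two indices among the tied set are taken — with exact arithmetic
  this is the documented "lowest indices win" tie-break; with floats a
  tolerance is required, otherwise three near-equal weights fragment into
  arbitrary tie variants.  *Major* categories are those holding at least
  5% of resolved neurons (minimum 3).
* **Activity analyses** use sampled binary activities, not firing
  probabilities.  Single-trial Bernoulli noise is part of the code the
  readout sees; with smooth rates even nominally "collapsed"
  representations remain linearly decodable through tiny systematic rate
  differences.
* **Mahalanobis separation** — distance between two clusters' means under
  the pooled within-cluster covariance, shrunk by `reg * trace(S)/K * I`
  with `reg = 1e-3`.  The shrinkage keeps near-singular covariances (from
  saturated or silent units) invertible; its exact value shifts absolute
  distances but not the rule comparisons, which are computed with a common
  estimator.
* **Within-group collapse ratio** — mean within-class over mean
  between-class pairwise distance of activity vectors, restricted to the
  interfering pairs (0,1) and (2,3).  Identical responses (0/0) count as
  perfect collapse (ratio 1).
* **Mutual information** between discrete labels from the joint histogram,
  in nats (ceiling ln C).  For network representations the MI is computed
  between true labels and labels *decoded* by the least-squares readout: a
  histogram over hundreds of continuous neurons is infeasible, and the
  decoded-label construction attains the stated ln C ceiling.
* **Adjusted cosine** — raw cosine minus the mean cosine over
  independently element-permuted copies (default 100 shuffles, seeded).
  For independent permutations the baseline's expectation is
  `n * mean(a) * mean(b) / (|a||b|)`, which removes the overlap inflation
  of nonnegative vectors.
* **Energy function** — for competition without maturation,
  `E_i = -1/2 sum_j d_j^2 <x_j^2> - sum_{l<j} d_l d_j <x_l x_j>` with
  `d_j = w_ij - mean_{k != i} w_kj` (leave-one-out mean).  Identical rows
  give zero; a row growing away from the population mean lowers E_i
  without bound, which is the instability the maturation cap removes.
* **Paired tests** — exact Wilcoxon signed-rank on the six pattern-pair
  distances plus a two-sided variance-ratio F test; all-zero differences
  are reported as undefined with p = 1.

## Ablations: what collapses and what does not

Removing maturation or removing competition abolishes the separation of
*interfering* patterns: the within-group collapse ratio rises to ~0.9–1.0
in both ablations versus ~0.75–0.8 for the full rule.  Without maturation
the earliest winners take each pattern group's resources and the weight
profiles collapse to at most two flat group-level categories.  Without
competition each neuron freezes (the gate caps growth after roughly
`Theta / (gamma * sum(x))` ≈ 8 updates) onto the single pattern it first
fired for: the *weights* still fall into the four tuned categories, but
the frozen, un-sharpened profiles respond almost equally to both members
of a pattern group, so the *activities* no longer discriminate within a
group.  In this implementation the no-maturation ablation also retains
coarse group-level (non-interfering) separation; the loss is specific to
interfering patterns, which is the effect the collapse ratio quantifies.

## Image classifier

Three layers: `side^2` inputs, N ReLU hidden units (default 200), C output
units with one-hot targets.  The hidden weights are trained by the same
competition rule in a single unsupervised pass, with deterministic ReLU
activities standing in for y (the stochastic unit is a toy-network
device), initial weights uniform in `[0, 1e-3]` (an all-zero ReLU layer
never fires), `gamma = 0.05` and `Theta = 10` (an image's pixel mass is
~30–100, so the cap freezes a neuron once it has absorbed a template-sized
portion).  The readout is ridge-regularized least squares
(`lambda = 1e-6`) with an intercept; prediction is the readout argmax.

Baselines: (a) least squares directly on raw pixels; (b) standard-normal
random hidden weights with the same readout; (c) an MLP of identical
architecture trained by momentum SGD (0.9) on softmax cross-entropy
(scikit-learn; batch 32, learning rate 0.01, 5 epochs — five total
exposures per pattern versus one for the competition network).

**Synthetic digits.**  Each class template is a sum of 3 random Gaussian
bumps on a 28x28 canvas (peak 1); samples are cyclically jittered by up to
±2 px and perturbed by pixel noise sigma = 0.25 (clipped at 0).  Labels
are exactly balanced.  The generator emulates what the classifier needs
from handwritten digits — smooth class templates, within-class geometric
jitter, pixel noise, partial between-class overlap — and nothing else: no
stroke structure, no deformation correlations, no label noise.  Passing
tests therefore show that the algorithm ranks as published under
template-plus-jitter statistics at n≈500, not that it attains any
particular accuracy on real handwriting.  With 500 training samples the
orderings match the published MNIST experiment (competition > random
features > direct least squares).  Problem sizes in the test-suite
protocols (2,000 toy presentations, 500–1,000 images, 5–10 replicates)
were chosen as the smallest at which these orderings are stable across
seeds.

## Known limitations

* The stochastic output unit is a stand-in; the original model's exact
  form is not specified in the source available to us, and all
  regime-dependent statements above are claims about *this* unit.
* The no-maturation ablation's "single cluster" is reproduced only for
  interfering pairs; group-level structure survives.
* MNIST-scale correct rates (91.5% / 85.8% / 82.4%) require the real IDX
  files, which the tool reads but never downloads; the synthetic-digit
  results check orderings, not absolute rates.
* Replicate seeds derive from the master seed by a counter-based spawn, so
  adding replicates never changes earlier ones; results are reproducible
  bit for bit given the config file.
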