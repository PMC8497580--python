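# Methods

This note documents the models and simulation behind `cellannotator`: what is
computed, under which assumptions, which parameters matter, and what the
package's passing tests do and do not establish about real microscopy data.

## The annotation loop

A region image is first reduced to cell detections (centroid + bounding box).
Each detected cell is represented by a 40×40 pixel patch centered on its
centroid; when images differ in physical resolution, the source window side
is scaled by √(area_scale) and resampled bilinearly so a patch always covers
the same physical area. Patches are normalized per channel by the mean and
standard deviation of the *training* patches only (the pretraining corpus for
the backbone; never validation or evaluation data). Edge cells are omitted
when building the pretraining corpus and reflect-padded at annotation time,
so every detected cell stays annotatable in the live loop.

The classifier is a frozen feature backbone with a trainable head: two fully
connected layers of 32 rectified units and a 2-unit softmax output.
Finetuning follows a fixed protocol on all labeled cells: stratified 75/25
train/validation split; minority-class oversampling with replacement until
per-epoch class counts are equal (within one); stochastic gradient descent
with learning rate 10⁻⁵ and momentum 0.9; at most 100 epochs, early-stopped
when validation accuracy has not improved for 10 epochs, keeping the
best-epoch head (ties to the earliest epoch). During a session the head
refits after every 5 newly labeled cells, warm-starting from its current
parameters; suggestions appear once at least 10 labels per class exist.

The active learner receives the 32-dimensional activation of the second head
layer (the layer feeding the output; a config switch substitutes raw backbone
features) for every cell, labeled and unlabeled. Greedy k-center selection
builds a maximally diverse candidate subset: each step adds the unlabeled
point whose minimum Euclidean distance to the labeled-plus-selected set is
largest, with ties broken by smallest cell id; recorded max-min distances are
non-increasing, and the greedy construction carries the classical factor-2
bound on the k-center covering radius (verified against brute-force optima in
the tests). The annotator is then directed to the grid patch containing the
most candidate points (ties to the lowest patch id); visited patches are not
revisited.

## Numerical and design choices

* **Backbone.** With no large pretrained network in the loop, the backbone is
  a frozen filter bank — per-channel means and dispersions over a central
  nucleus disk, an annulus, and a coarse context grid, plus gradient and
  Laplacian-of-Gaussian responses — projected by a PCA fitted on a synthetic
  single-nucleus corpus (the "pretraining"). The PCA is intentionally not
  whitened: whitening equalizes component variances and destroys the dominant
  class-color axis as soon as scene patches add context variance the corpus
  lacks. Components are scaled so the mean per-component corpus variance is
  100 (standard deviation 10); deep backbones likewise feed their heads
  activations well above unit scale, and at learning rate 10⁻⁵ this scale is
  what lets the readout move appreciably inside the patience window.
* **Head initialization.** He-scaled hidden weights with bias 1.0 (units
  start active, the layers start near-linear) and a zero output layer. At
  this learning rate the hidden layers stay near initialization; the
  classifier is effectively a learned linear readout over fixed nonlinear
  random features, and the zero-initialized readout makes its direction
  purely data-driven.
* **Batch size 4.** The protocol fixes the learning rate, epoch cap, and
  patience but not the batch size. Small batches give the readout enough
  update steps per epoch to reach its best validation accuracy within the
  patience window; with batches of 32 the early stopper fires while the head
  is still half-trained.
* **Ties and determinism.** All randomness flows from explicit seeds
  (scene/appearance/noise substreams; split, oversampling, and shuffling from
  the train config; oracle beliefs from the oracle seed). Identical seeds
  reproduce byte-identical session logs.
* **Degenerate inputs.** Constant patches normalize to zero via an epsilon
  guard; scenes that cannot satisfy the minimum cell separation fail with an
  explicit density error; learning-curve prefixes with fewer than two labels
  in either class are assigned chance accuracy 0.5 (a convention required to
  integrate the curve from N = 0).

## The synthetic scenes and simulated annotators

Scenes emulate the statistical structure the loop exploits, not
photorealism: a stain-tinted noisy background; two nucleus classes rendered
as textured ellipses differing in size and color (hematoxylin-like negatives,
a weakly color-shifted minority positive class, 30% by default); positives
concentrated in Gaussian clusters whose mean color differs per cluster; and
Voronoi "tissue compartments" whose stain offset shifts every cell in a
region. The cluster and compartment structure is what gives spatial guidance
any signal: a model calibrated on one region is systematically off in
unvisited ones. The workload study uses patch-scale scenes (~800 cells; a
640 px viewport holds ~200); the effectiveness study uses slide-like scenes
(3000 cells at 2560², 15% positives) so the 200-label budget covers only a
few percent of the pool, as it would on a whole slide.

The annotator is an oracle holding a fixed belief per cell: the true label
flipped independently with probability ε (default 0.05; an expert-level
rate), sampled once per session because a person's opinion of a cell is
stable. Without a suggestion the oracle labels from belief; with one, it
accepts when the suggestion matches its belief and corrects otherwise.
Initialization labels 20 believed cells per class drawn from a single
starting viewport — a human finds their first examples in one field of view,
not scattered across the slide. In workload sessions the annotator then works
through the grid patch whose cell count is closest to 200 and whose classes
are most balanced (initialization cells are drawn outside it). In
effectiveness sessions the guided run follows the active learner for 200
total labels; the control run repeats the protocol with all models off,
visiting patches in a seeded random order of its own — each simulated
annotator roams its own path, as free-roaming humans would.

Effectiveness follows the order-preserving prefix protocol: for each N on a
grid (default 0, 10, …, 200) a fresh head is trained on the first N labels of
the run and evaluated on pooled labels from the *other* annotators' control
runs (ground truth is treated as unavailable, as in any real annotation
study); models are retrained `repeats` times (10 by default; the studies here
use 5) and averaged. Both of an annotator's curves share one evaluation set
and, in this implementation, the same per-repeat training seeds — with
identical initialization prefixes the shared region of the two curves then
cancels exactly in the paired comparison, a pure variance-reduction device.
The effectiveness score is the trapezoid area under accuracy-versus-N,
normalized by the N range; two runs are compared by the percent AUC ratio.

## What the studies show — and what they do not

On these synthetic conditions the loop reduces annotation workload by well
over 90%: after a 40-cell initialization, the classifier's suggestions are
almost always accepted (mean corrected fraction ≈ 0.003-0.05 depending on
scene difficulty and oracle error). The boundary contracts hold exactly (a
ground-truth suggester yields workload 0, an inverted one yields 1), the
detector recovers ≥ 99% of non-overlapping synthetic nuclei, and sessions are
bit-reproducible.

The paired effectiveness comparison is an honest null at this scale: over 20
paired guided/control runs the mean AUC difference is ≈ +0.005 (mean ratio
below +1%, one-sided p ≈ 0.18) — guidance does not degrade data
effectiveness, but its benefit is statistically indistinguishable from zero
here. The diagnosis is instructive: the guided runs demonstrably cover the
positive subpopulations far better than control runs, yet an effectively
linear readout converts that coverage into wider positive acceptance regions
that encroach on the (majority) negative class, and the evaluation labels are
themselves control-distributed. Converting coverage into accuracy requires a
decision function nonlinear enough to carve per-region boundaries — a deep
finetuned network, not a frozen-feature readout. Results obtained with human
experts and large pretrained classifiers on real slides are therefore outside
what this simulation can confirm or refute.

Passing tests here show the *protocol machinery* is correct and the loop
behaves sensibly under controlled conditions. Real tissue brings stain
variability, segmentation errors, ambiguous cells, and annotator behavior
(trust, fatigue, deference to suggestions) that the oracle model explicitly
excludes; none of these are exercised by the synthetic studies.

## Problem sizes

The default studies are sized for a single CPU: workload over 10 scene seeds
(~30 s), effectiveness over 5 slide-like scenes × 4 simulated annotators
(20 paired runs, learning curves at 21 grid points × 5 repeats, ~3-4 min),
detector fidelity over 20 fifty-cell scenes, and 200 brute-force k-center
instances (n ≤ 12, budget ≤ 3).
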