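# Methods

## Slice extraction

A 3D scan is viewed along one of the three anatomical plane normals
(array axis 0 → sagittal, 1 → coronal, 2 → axial by default; the mapping is
overridable per volume, and the NIfTI affine is read only to warn about
unusual orientations — orientation correction is out of scope). For `m`
available slices and a requested count `n`, the schedule uses the interval
`i = ⌊m/n⌋`, drops `k₁` leading and `k₂` trailing boundary slices (in brain
MRI these mostly contain air or non-brain tissue), and keeps
`n_slices = ⌈m/i⌉ − (k₁+k₂)` positions `s = k₁ + j·i` subject to the guard
`s < m − k₂`. Two consequences worth knowing:

* the schedule does **not** guarantee `n_slices == n`; when they differ the
  plan reports the actual count and the CLI warns — there is no silent
  re-fitting of the interval;
* the trailing guard can drop scheduled positions, so a slice set may be
  shorter than `n_slices`.

Defaults `k₁ = k₂ = 2` ("the first and last few slices"), configurable.
Slice indexing is 0-based. Intensities are normalised per slice by min–max
to [0, 1] (a constant slice maps to zeros) before optional bilinear
resizing and 8/16-bit PNG export; per-slice min–max is the simplest scheme
consistent with 8-bit export and is applied identically at train and test
time.

## Circuit simulation

The simulator is an exact statevector implementation: amplitudes of the
N-qubit register are a complex vector of length 2^N, qubit 0 is the
least-significant bit of the basis index, and
`Ry(θ) = [[cos(θ/2), −sin(θ/2)], [sin(θ/2), cos(θ/2)]]`. These conventions
are fixed so amplitudes are bit-exact against the dense
2^N×2^N unitary-product oracle used in the tests.

Two encoding dialects are provided because the feature-map literature
writes the entangler in two ways: `eq3-cz` applies plain CZ gates after the
per-qubit data phases `P(2x_i)`; `zz-interaction` (default) applies the
pairwise phase `2(π−x_i)(π−x_j)` to the `|11⟩` component of each pair —
the standard ZZ-interaction term, with distinct indices i≠j. One ansatz
repetition (a single Ry layer) is the default.

The read-out maps the all-qubit Pauli-Z parity expectation to
`o₁ = (1 − ⟨M⟩)/2 ∈ [0,1]`; a first-qubit marginal observable is available
via configuration. Exact expectation (no shot noise) is the default, which
makes every run deterministic given its seed; shot sampling is opt-in with
an explicit generator and obeys the usual `O(1/√shots)` convergence.

Gradients: the parameter-shift rule is exact for Ry generators
(`∂o₁/∂θ_i = [o₁(θ_i+π/2) − o₁(θ_i−π/2)]/2`); gradients with respect to the
encoded angles use central finite differences with step `h = 1e-4`, which
is what lets the loss backpropagate through the encoding into the classical
layers. Raw dense-layer outputs are squashed to angles by `x → π·tanh(x)`
before encoding, keeping phases in (−π, π) and avoiding aliasing of the
phase-periodic encoding; an identity scaling is available.

## Network and training

The layer stack and parameter accounting are described in the README. All
layers, the backward pass, and the optimizers (Adam default; SGD, RMSprop,
Adagrad and a limited-memory BFGS stepper for ablation) are implemented in
numpy. Defaults follow the reference protocol: image side 128, batch 32,
learning rate 1e-3, Adam, cross-entropy. Dropout2D rate 0.25 (zeroing whole
channels), configurable; it does not alter parameter counts. No early
stopping. Training is bit-reproducible given the seed: one generator drives
shuffling and dropout, and the circuit expectation is exact.

Numerical choices:

* cross-entropy clamps its log argument at 1e-12, and the analytic
  `∂L/∂o₁` uses the same clamp;
* max-pool ties break toward the first element of each 2×2 block;
* conv/dense weights use uniform Kaiming-style init (bound `1/√fan_in`);
  circuit angles start in U(0, π), one Ry half-period;
* the 1→1 output layer is initialised as an identity-like calibration map
  (W=4, b=−2), so a circuit probability q ∈ [0,1] lands on a logit centred
  at q = 0.5. Every image's evidence funnels through this single scalar,
  and with a random init the whole early phase of training is spent merely
  recentring the decision threshold (the scalar moves at roughly the
  learning rate per Adam step);
* the logistic squash after that layer is a deliberate deviation forced by
  domain validity: the (o₁, 1−o₁) head needs o₁ ∈ [0,1], which a bare
  linear layer cannot guarantee, and the squash keeps cross-entropy
  well-defined.

The classical-control variant replaces `[Dense(4→ω) → PQC → Dense(1→1)]`
by `Dense(4→ω) → tanh → Dense(ω→1, no bias) → logistic → Dense(1→1)`. The
bias-free ω→1 bridge carries exactly ω parameters, matching the ω circuit
angles, so the two variants have identical trainable-parameter counts —
the property the comparison depends on, asserted in the tests.

Metrics come from the 2×2 confusion table at the argmax(γ) rule:
precision TP/(TP+FP), recall TP/(TP+FN), F1 their harmonic mean,
specificity TN/(TN+FP), accuracy (TP+TN)/total. The positive class
defaults to label 1 — by the package's data conventions the minority
clinical class — and is configurable. Ratios with zero denominators are
reported as 0 and flagged. Repeated-run diagnostics train R independent
replicates (per-run seeds derived from the base seed by a fixed counter;
five runs by default) and summarise run-to-run spread with a one-way ANOVA
over each run's last-3-epoch training accuracies; all-identical groups
degenerate to (F, p) = (0, 1) by convention. The last-3-epoch window is a
documented choice — any stable tail window works.

## Synthetic data

The volume phantom is an ellipsoid (plus clipped Gaussian noise inside the
foreground) sized so that every slice in `[margin, extent−margin)`
intersects it and every boundary slice is exactly zero — the geometry the
k₁/k₂ edge-trimming is designed for.

The two-class image generator shares a large central blob between classes
and displaces (and slightly brightens) a secondary blob by the similarity
gap δ between them. Every image also carries per-sample anatomy-like
variation that is *identical in distribution across classes*: blob
positions jitter by ±3 % of the image side, sizes by ±15 %, brightness by
tens of percent, plus i.i.d. Gaussian pixel noise (σ = 0.05). This
within-class variation matters: without it the network's 4-unit dense
layer sees essentially constant inputs, its ReLUs die in unison, and no
model — quantum or classical — can train. δ = 0 makes the class
distributions exactly identical; δ ≈ 20 px is trivially separable by a
nearest-centroid classifier. Separability is monotone in δ.

What the phantoms do **not** emulate: real anatomy, scanner physics,
intensity inhomogeneity, class imbalance, or the specific texture
differences between dementia grades. Passing the convergence tests
therefore shows that the architecture, gradients and optimization behave
correctly in the separable and degenerate-similarity regimes — not that
any particular clinical accuracy is attainable on real MRI.

## Convergence experiments

The end-to-end experiments train the 2-qubit hybrid model and its
classical control on δ = 20 phantoms (300 images per class, i.e. 540
training images after the 90:10 split, side 128, 10 epochs) and a δ = 0
set (100 per class, 2 epochs, three seeds). Problem sizes were chosen so
the runs mirror the reference protocol's scale of "over a thousand
images" closely enough to show the characteristic dynamics while staying
cheap: the hybrid model stagnates near chance for several epochs and then
converges rapidly; the classical control improves steadily from the first
epoch; at δ = 0 accuracy stays within three points of chance.

## Known limitations

* The simulator targets small registers (≤ ~10 qubits); no noise models,
  transpilation or hardware backends.
* The quantum layer is evaluated per batch on the CPU; input gradients are
  finite-difference (2ω circuit evaluations per sample per step on top of
  the 2ω parameter shifts).
* Only binary heads are provided; multi-class classification is out of
  scope.
* The L-BFGS optimizer is a stochastic simplification (fixed step, no line
  search) intended only for the optimizer-ablation comparison.
* Checkpoints store float64 parameters; the reported 0.05 MB figure is the
  32-bit storage footprint of the fixed parameter set.
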