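# Methods

`strucfun` predicts protein function labels (GO-term-like or EC-like) from
residue contact maps with a graph convolutional network (GCN), and localizes
each prediction onto residues with gradient-weighted class activation mapping
(grad-CAM). This note records the model, the synthetic benchmark that
establishes correctness, the numerical choices, and the limits of what the
desk-scale experiments show.

## Model

**Contact maps.** A protein of L residues becomes a binary, symmetric,
zero-diagonal adjacency A ∈ {0,1}^{L×L}. Three contact rules are supported,
all with strict (<) distance criteria:

* `CA_CA` — Cα–Cα distance below a threshold (default 10 Å);
* `ANY_ANY` — minimum distance over all atom pairs below 6.5 Å;
* `NBR_NBR` — distance between neighbor atoms (Cβ; Cα for glycine) below the
  sum of per-amino-acid neighbor radii. The radius table approximates the
  Rosetta side-chain interaction spheres and ships as editable JSON data
  (`strucfun/data/nbr_radii.json`); callers may substitute their own.

Pipelines keep chains of 60–1000 residues (inclusive bounds). PDB author
numbering is remapped to a dense 0-based index over resolved residues;
altloc conflicts resolve to the highest-occupancy conformer.

**Residue features.** Sequences are one-hot encoded over 26 channels —
the 20 standard amino acids (alphabetical), the five non-standard codes
B/J/O/U/Z, and a gap symbol that also absorbs unknown characters. An
optional second pathway supplies per-residue hidden states H^LM of a
2-layer forward LSTM next-residue language model (desk default 64 hidden
units; the architecture accommodates the full-scale 512). The LM is trained
once on a sequence corpus and frozen; downstream training never updates it.
Both pathways enter the network through a learnable fusion

    H_input = ReLU(H_LM · W_LM + X · W_X + b),

trained jointly with the GCN; with the LM disabled the first term is
omitted (the one-hot baseline).

**Graph convolution stack.** Each layer applies the symmetrically
normalized propagation rule

    H^(l+1) = ReLU( D̃^{-1/2} (A + I) D̃^{-1/2} H^(l) W^(l) ),

with D̃ the degree matrix of A + I. Three layers (default 32 channels each)
are concatenated along channels and sum-pooled over residues into a fixed
protein vector, followed by one ReLU hidden layer (desk default 64 units;
512 at full scale) and a per-term two-way softmax, so every term outputs a
(positive, negative) probability pair. The largest eigenvalue of the
normalized adjacency is exactly 1, which bounds feature growth across
layers. Alternative propagation rules plug in through
`GCNModel(conv_fn=...)`; only the symmetric-normalized rule ships.

**Loss and training.** The loss is a class-weighted cross-entropy over the
indicator pairs,

    L(Θ) = −(1/N) Σ_i Σ_j Σ_{k∈{+,−}} w_j · y_ijk · ln(ŷ_ijk),

with w_j = N / N_j⁺ so rare terms weigh more (both elements of a term's
pair carry its weight), predictions clipped to [1e−7, 1−1e−7], natural-log
convention. Optimization is Adam with mini-batches of 64, a 10% validation
split stratified per term where feasible, and early stopping on validation
loss with the best-validation checkpoint restored. `TrainConfig` defaults
carry the full-scale setting (lr 1e−4, β1 = β2 = 0.95, patience 5, max 200
epochs). The desk-scale experiments use a setting chosen by a small grid on
*validation loss*: lr 1e−3, β = (0.9, 0.999), patience 30 with a 150-epoch
floor (an epoch here is only ~5 optimizer steps, and the first ~100 epochs
sit on a class-prior plateau that would otherwise trip early stopping),
max 250 epochs, and gradient-norm clipping at 10 to tame the spiky
gradients of heavily weighted rare terms. Two further initialization
choices keep optimization sane at desk scale: the post-pooling weights
start at 0.1× Glorot and the output head at zero, so sum pooling over ~100
residues does not saturate the softmax at initialization.

A term is called positive when its positive-class probability strictly
exceeds 0.5; a score of exactly 0.5 is a negative call.

**Sequence-only baseline.** A 1D CNN over the one-hot sequence: parallel
convolutions of filter widths {8, 16, 24, 32} × 64 filters (the full-scale
16 × 512 setting is reachable through `CNNConfig`), ReLU, global
max-pooling, dense sigmoid head, trained with the same weighted loss.

**Grad-CAM.** For a chosen term, the positive-class probability y⁺ is
differentiated with respect to the final graph layer's feature maps
F ∈ R^{L×c} (a flag switches to the concatenated maps, or to the logit).
Channel importances w_k = Σ_i ∂y⁺/∂F_ik combine into the residue map
CAM[i] = ReLU(Σ_k w_k F_ik), normalized to [0,1] by its maximum (an
identically zero map stays zero). Note the source equation indexes the
feature map by a layer subscript in its final sum; it is implemented
per-residue, which is the only reading under which the map is indexed by i.
Agreement with a binary site profile is scored by tie-aware AUROC
(equivalent to the Mann–Whitney statistic and to trapezoid integration of
the swept-threshold ROC).

**Evaluation.** Protein-centric Fmax follows the CAFA convention:
precision at threshold t averages over proteins with at least one score
≥ t, recall over proteins with at least one true term; Fmax maximizes the
harmonic mean over a 0.01-step grid with t = 0 excluded (everything is
predicted there). Term-centric AUPR is the non-interpolated step-wise area
(average-precision style; trapezoidal PR interpolation is known-biased),
with tied scores collapsed into one step; the macro average skips terms
lacking both classes and logs them. Bootstrap summaries resample proteins
with replacement, seeded.

## Synthetic benchmark

Real training corpora (PDB/SWISS-MODEL scale, ~10M-sequence LM corpora) are
out of desk scope, so correctness is established on generated data in which
the ground truth is planted and every geometric contract is checkable by
brute force.

**Bead chains.** A protein is a chain of Cα-like beads with exact 3.8 Å
virtual bonds and a 4 Å self-avoidance floor between non-adjacent beads.
Unconstrained chains come from a persistent self-avoiding walk. Chains
with planted motifs are assembled around pinned anchor beads: consecutive
anchors are joined by exact circular-arc segments (equal 3.8 Å chords on
the circle through both endpoints) whose plane is rotated about the chord
until the segment clears every placed bead, and chain tails are free walks
seeded away from the motif cluster. Arc assembly is retried against freshly
sampled motif placements; bounded failure raises a `GenerationError`.

**Planted motifs.** A motif is a set of 2–12 residues pinned pairwise
within `spatial_radius` (default 9 Å, deliberately below the 10 Å contact
threshold so every planted motif is a clique in the contact graph). Motif
point sets come from dart-throwing inside the motif ball with a rotated
icosahedron template as a guaranteed fallback. Sequence placement is either
`local` (a compact window, stride 2 — sequence-adjacent residues sit at
bond distance and cannot satisfy the 4 Å motif separation) or `long_range`
(spread so that at least one pair is ≥ 50 positions apart, or ≥ L/2 for
short chains). Each term's motif also carries a short amino-acid
*signature*: planted residues draw letters from a term-specific disjoint
alphabet (3 letters per term at ≤ 6 terms), emulating the residue chemistry
of real functional sites — without a sequence signature all motifs would be
geometrically interchangeable and no classifier could tell terms apart.

**Labels.** A protein's label vector marks the motifs planted in it; each
label is then flipped independently with probability `label_noise_rate`
(symmetric noise). Planting probabilities default to a geometric ladder
0.65 → 0.065 across terms, a 10× spread of planted frequencies; after
symmetric noise folds flipped negatives into the rare terms the realized
label-count spread stays near 5–7×. Generation is
bit-reproducible from the config seed.

**What the generator does not emulate.** Physically realistic geometry
(secondary structure, packing density, sequence–structure covariation),
annotation bias (noise is symmetric), hierarchical label structure (the
planted terms are flat; DAG propagation is exercised separately on ontology
fixtures), and real residue-contact statistics (bead chains are far less
densely packed than folded proteins). Passing the benchmark shows the
machinery is correct and that the architecture detects spatially clustered,
chemically marked residue sets under label noise — not that full-scale
performance numbers transfer.

## Desk-scale experiments (`strucfun.experiments`)

* **Planted-motif recovery** — 300 train / 60 test proteins, L ∈ [60, 120],
  6 terms with motifs of 6–10 residues (`local` dispersion), 5% label
  noise, 3 seeds; GCN trained on the one-hot pathway. The LM pathway is
  implemented and tested, but on uniform-random synthetic sequences frozen
  LM features carry no label information and measurably slow learning, so
  the benchmark experiments omit them.
* **Long-range advantage** — same pipeline with `long_range` motifs of 6–8
  residues on fixed L = 150 chains, GCN vs the CNN baseline on identical
  data; run at 150 train / 40 test because chains are longer and two models
  train per seed. The contrast is relative, so the reduced size does not
  affect its meaning.
* **Noise robustness** — the trained GCN scored on test contact maps with
  each upper-triangle entry flipped at rates {0, 0.05, 0.1, 0.2, 0.4}, a
  surrogate for contact maps from degraded structural models.
* **Class-weight effect** — a 2-term set at planting 0.8 / 0.08 (10:1
  imbalance) trained with w_j = N/N_j⁺ vs uniform weights, compared by
  rare-term recall at threshold 0.5.

Observed behavior across seeds: frequent terms reach test AUPR 0.8–0.95 and
grad-CAM recovers planted residues with mean AUROC ≈ 0.9 (one-sided
Wilcoxon against 0.5, p < 1e−6); Fmax degrades monotonically with contact
noise; weighted training roughly doubles rare-term recall. The rarest terms
(planting ≲ 0.075) are a known limitation: with 5% symmetric noise, a large
fraction of their positive labels are flips with no planted motif, and the
60-protein test partition leaves only 1–6 positives per rare term, so their
test AUPR estimates are noisy and low even when the training set is fit
well. Macro-averaged AUPR therefore understates what the model learned;
the per-term table in the saliency/evaluation reports is the more
informative view.

## Numerical choices

* Float64 throughout; training is bit-reproducible given a seed and
  restoring a checkpoint is bit-exact.
* All neural components run on a compact reverse-mode autodiff engine
  (`strucfun.autograd`) written for this package: dense NumPy arrays, a
  dynamic tape, gradients retained on intermediate nodes so grad-CAM can
  interrogate feature maps directly.
* Softmax/log-softmax use max-shifted stable forms; loss probabilities are
  clipped at 1e−7; max-pool ties route gradient to the first maximizer.
* Contact thresholds are strict (<); boundary equality is no contact.
* Length-filter bounds are inclusive ("between 60 and 1000" read
  conventionally).
* Degenerate inputs fail loudly: empty coordinates, non-symmetric
  adjacencies, terms with zero positives (class weight undefined at
  label-space construction), site profiles lacking both classes, AUPR on
  single-class terms.
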