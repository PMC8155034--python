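# strucfun

Structure-based protein function prediction with graph convolutional
networks over residue contact maps, plus grad-CAM localization of each
prediction onto the residues responsible for it.

Most proteins in sequence databases have no experimentally verified
function. Sequence-only predictors struggle exactly where structure
matters: functional sites (catalytic residues, ligand-binding loops) are
often formed by residues that are far apart in sequence but adjacent in the
fold. `strucfun` is for computational biologists who want a transparent,
CPU-scale, fully tested implementation of the structure-aware approach:

* represent a protein as a binary contact map **A** ∈ {0,1}^(L×L)
  (Cα–Cα < 10 Å by default; all-atom and Rosetta-neighbor rules included);
* propagate residue features with symmetrically normalized graph
  convolutions, H^(l+1) = ReLU(D̃^(−1/2)(A+I)D̃^(−1/2) H^(l) W^(l)),
  stack three layers, concatenate and sum-pool into a protein vector, and
  classify every function term with a two-way softmax;
* train with the class-weighted cross-entropy
  L(Θ) = −(1/N) Σᵢ Σⱼ Σₖ wⱼ yᵢⱼₖ ln ŷᵢⱼₖ, wⱼ = N/Nⱼ⁺, so rare terms count;
* optionally fuse one-hot residue identities with frozen per-residue
  features from a forward LSTM next-residue language model,
  H_input = ReLU(H_LM·W_LM + X·W_X + b);
* evaluate CAFA-style (protein-centric Fmax, term-centric AUPR, bootstrap);
* explain predictions per residue with grad-CAM:
  w_k = Σᵢ ∂y⁺/∂F_ik, CAM[i] = ReLU(Σ_k w_k F_ik),
  scored against known site profiles by AUROC.

Everything — graph convolutions, the LSTM, the DeepGO-style CNN baseline,
Adam, and grad-CAM — runs on a compact reverse-mode autodiff engine over
NumPy written for this package, in float64 and bit-reproducible from a
seed. A synthetic generator builds bead-chain proteins with *planted*
spatially clustered motifs (exact 3.8 Å virtual bonds, 4 Å self-avoidance,
term-specific residue signatures), so every stage is benchmarked against
ground truth without external data. Label spaces for real data come from
OBO ontologies and annotation tables with evidence-code filtering, DAG
propagation, information content, and count-band term selection.

## Worked example

`examples/03_train_and_evaluate.py` generates 120 synthetic proteins
(three terms, noise-free), trains the 3-layer GCN on 100 of them and
evaluates on the remaining 20:

```
stopped after 150 epochs (best validation loss 3.34 at epoch 132)
test Fmax      0.768 at threshold 0.17
test macro AUPR 0.812 (prevalence 0.283 = a random ranker's AUPR)
bootstrap Fmax mean +/- sd: 0.778 +/- 0.084
```

Fmax 0.768 means that at the best decision threshold the harmonic mean of
protein-averaged precision and recall is 0.77; macro AUPR 0.81 against a
0.28 random baseline shows the network ranks annotated proteins far above
chance for every term. `examples/04_gradcam_sites.py` then asks *where* a
prediction comes from:

```
SYN00001, term MOTIF:0000:
  planted residues : [20, 22, 24, 26, 28, 30]
  top grad-CAM     : [20, 22, 24, 26, 28, 30]
  site AUROC       : 1.000
```

— the saliency profile of the trained model peaks exactly on the six
residues whose spatial clustering defined the function, without the model
ever seeing residue-level labels. The other examples cover dataset
generation, contact-map construction and degradation, the language model,
and ontology label spaces.

A thin CLI mirrors the pipeline for shell use
(`strucfun simulate | build-cmap | make-labels | train-lm | run | predict |
explain | evaluate`); see `strucfun --help`.

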