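# Methods

## The model

The package predicts protein **druggability** — the propensity of a protein
to be targeted by a therapeutic molecule — as a score in [0, 1] from two
feature families:

1. **Pooled sequence embeddings.** A protein of length *L* is mapped by a
   residue-embedding backend to a matrix *F* ∈ ℝ^{L′×D} with
   *L′* = min(*L*, `max_tokens`); sequences longer than the token budget
   (default 1024) keep their N-terminal prefix. The per-protein vector is
   the unweighted row mean, *F*pr[d] = (1/L′) Σᵢ F[i, d]. The production
   backend is a large pretrained protein language model (default: the
   33rd layer of a 650M-parameter checkpoint, D = 1280); it is config-gated
   so the package runs fully offline with the synthetic backend (below).
   When a pretrained backend emits begin/end special tokens they are
   excluded from the average — the pooled vector is a mean over residue
   positions only. This exclusion is a documented choice of this package.

2. **Binary GO vectors.** All three Gene Ontology sub-ontologies are pooled
   into one vocabulary — the sorted union of the GO ids seen on the
   *training* records — and each protein is encoded as GOpr ∈ {0,1}^V with
   a 1 where the protein carries the term. Annotations are used as given
   (no ancestor closure up the ontology graph) and out-of-vocabulary terms
   are ignored; an unannotated protein encodes to the zero vector, so
   prediction degrades gracefully when GO terms are unavailable. The
   vocabulary is data-defined, so V varies with the training split rather
   than being a constant of the method.

The final representation is the concatenation Rpr = [Fpr | GOpr], embedding
block first (indices 0..D−1), so selection-mask indices are portable across
runs.

## Feature selection

Rpr is high-dimensional relative to typical training sets, so a single-pass
filter keeps the top-k features (default k = 4000) ranked by the absolute
weights of a linear SVM (squared-hinge, C = 1.0) fitted on standardized
training data. Standardization (per-feature center/scale; zero-variance
features get scale 1, making their standardized column identically zero and
ranking them last) is fitted on the same training data and stored inside
the mask, so the identical transform is replayed at prediction time. Ties
in |weight| break toward the lower feature index; the kept set at k is
always a superset of the kept set at k′ < k for the same fit. Single-pass
ranking (rather than recursive elimination) is the design choice here; C,
tolerance and iteration budget are exposed as parameters.

Neither fitting nor applying the mask accepts held-out data or labels —
this interface is what makes the nested cross-validation leak-free, and the
test suite asserts it directly (perturbing held-out features leaves every
fitted object unchanged, and a pure-noise dataset yields chance-level CV
AUC).

## The neural head

A small feed-forward network on the k selected features:

    dense(128) → BN → ReLU → dropout(0.5)
    dense(64)  → BN → ReLU → dropout(0.5)
    dense(32)  → BN → ReLU
    dense(1)   → sigmoid

trained with Adam on binary cross-entropy plus an L2 penalty of 0.01 on all
dense weights, batch size 32, learning rate 2·10⁻⁴ halving every 5 epochs
to a floor of 2.5·10⁻⁵, and early stopping with patience 5 restoring the
best weights. Choices the architecture description leaves open are resolved
as follows: layer order is dense → batch-norm → activation → dropout (no
batch-norm/dropout after the output layer); early stopping monitors plain
validation cross-entropy on a seeded stratified 10% split of the training
data; `max_epochs` defaults to 100 (early stopping governs in practice);
scores ≥ 0.5 call the positive class.

The head is implemented directly on numpy — explicit forward/backward
passes for the dense layers, batch normalization (batch statistics during
training with running averages at momentum 0.9 for inference, ε = 10⁻⁵) and
inverted dropout — so training is exactly reproducible from the seed and
inference is batch-size independent. He initialization is used for the
hidden layers and Glorot-uniform for the output. When the training set is
too small to stratify a validation split (fewer than 1/`val_fraction`
members in a class) the model trains for `max_epochs` without early
stopping.

## Evaluation battery

Thirteen metrics per evaluation: AUC (rank-based, ties counted ½, via
scikit-learn), AUPRC (step-interpolated average precision), precision,
recall, accuracy, specificity, NPV, F1, MCC, Cohen's kappa, diagnostic odds
ratio DOR = (TP·TN)/(FP·FN), discriminant power DP = (√3/π)·ln DOR, and
DKL. Conventions:

* **DKL** is KL(Bernoulli(p̂) ‖ Bernoulli(q̂)) in nats, with p̂ the label
  prevalence and q̂ the mean predicted score (both clipped to
  [10⁻¹², 1−10⁻¹²]). This is a documented convention of this package; other
  definitions of a calibration KL exist.
* **DOR/DP** receive the Haldane–Anscombe +0.5 correction on all four cells
  only when some cell is zero; rate metrics with 0/0 are reported as NaN,
  never coerced to 0.
* **Lift** sorts by descending score (stable under ties) into near-equal
  decile bins; lift = within-bin precision / prevalence.
* **JM distance** between the classes of a feature block models each class
  as a diagonal-covariance Gaussian (per-feature variances floored at
  10⁻⁶): B = ⅛ Δμᵀ Σ̄⁻¹ Δμ + ½ ln(det Σ̄ / √(det Σ₀ det Σ₁)) with
  Σ̄ = (Σ₀+Σ₁)/2, and JM = √(2(1−e^(−B))) ∈ [0, √2]. The √-form (rather
  than the [0,2]-range form) and the joint diagonal-Gaussian treatment
  (rather than per-feature averaging) are documented choices.

The cross-validation protocol is stratified k-fold (default 10 folds,
5 independent runs; stratification is this package's choice for small-fold
class balance) with the GO vocabulary, standardizer, selection mask and
network all refitted inside each training fold. Aggregates are mean ± SD
over all fold values plus a t-distribution 95% CI. The random-label null
relabels every protein Bernoulli(prevalence) independently, five times by
default, and reruns the full nested CV per relabeling. The independent-test
protocol refuses overlapping id sets with a hard error.

## Structure representations

For the sequence-vs-structure comparison arm, two constructors operate on
curated CA traces:

* **Contact map**: binary N×N adjacency with entry 1 iff CA–CA distance is
  strictly below the threshold (default 7 Å) and diagonal fixed to 1 — the
  identity matrix is then the degenerate no-contact case.
* **Point cloud**: coordinates centered on their centroid; proteins longer
  than `n_points` (default 400) are subsampled uniformly without
  replacement with residue order preserved and re-centralized (so the
  centroid invariant holds exactly; whether to re-center after subsampling
  was an open choice); shorter proteins are zero-padded with a pad mask.
  Rotation augmentation draws uniform SO(3) rotations by the unit-
  quaternion method (scipy), default multiplicity 3; rotations fix the
  origin so pads stay at (0,0,0).

Monomer curation keeps the ATOM records of one protein chain (default: the
first chain in file order containing standard residues; the chain-selection
rule is this package's choice), drops all HETATM records, takes one CA per
residue and resolves alternate locations by highest occupancy with ties to
file order. Structure-candidate selection filters to candidates covering at
least half the full sequence, then prefers the best (lowest) resolution,
with coverage as tie-break — resolution is treated as the primary
criterion, and `covered_length` is an input rather than being computed by
alignment.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, at
conditions chosen once: 300 + 300 proteins, embedding dimension 64 with a
3-SD class mean shift on 10 designated dimensions, 100 GO terms of which 10
are enriched (carried with probability 0.8 by positives vs 0.2 by
negatives, background rate 0.05), sequence lengths uniform on [50, 400].
The shift is injected into the pooled-embedding cache — in across-protein
SD units, so the effect size is well defined — rather than via sequence
composition, which isolates pipeline behavior from embedder behavior; an
optional composition-bias mode exists for AAC-baseline experiments. Each
artifact (sequences, GO, embeddings) draws from its own named substream of
the master seed, so components are independently reproducible and outputs
are byte-identical across identical runs.

The synthetic residue embedder is a seeded-hash expansion: a residue's
vector is a standard-normal draw keyed by (seed, dim, k-mer context), which
has zero mean and unit variance per dimension in distribution over the
context alphabet. It is deterministic and sequence-sensitive but carries no
biology; passing tests therefore demonstrate the pipeline's statistical
machinery (leak-free nesting, selection, training, evaluation), not that
real proteins are separable — real-data performance depends on the
pretrained embedder and curated annotations, which the synthetic conditions
do not emulate.

Toy structures are self-avoiding random CA walks with exactly 3.8 Å
consecutive spacing and ≥ 4.0 Å between non-consecutive residues (enforced
by rejection), written as valid single-chain PDB files that round-trip
through the monomer reader.

## Problem sizes and numerical choices

Desk-scale experiments (the test suite and `scripts/acceptance.py`) run the
protocol at 5 folds × 1 run on 600–1000 proteins with 64-dimensional
embeddings, k = 64, and `max_epochs` 60 under early stopping — sizes chosen
so the full battery (including the five-repetition random-label null)
completes in well under a minute on one CPU while leaving every fitted
object at realistic shape. On very small fixtures (~100 proteins, 2–3
minibatches per epoch) the defaults' conservative learning rate and
patience underfit; protocol tests on such fixtures use a higher learning
rate (2·10⁻³) and patience 10, which changes nothing about the protocol
being tested.

Degenerate inputs are handled explicitly: empty GO vocabularies are valid
(V = 0, Rpr = Fpr); single-residue proteins pool to their own embedding;
single-class training data is an error everywhere; batch-norm variance is
floored by ε; constant score vectors give AUC 0.5.

## Known limitations

* The pretrained embedding backend requires an optional runtime and is
  untested here; all results in this repository use the synthetic backend.
* The DKL and JM conventions above may differ from other published
  formulations of those quantities.
* GO annotations are taken as direct (no evidence-code filtering, no
  ancestor propagation).
* The comparison deep models that consume contact maps and point clouds
  (point-cloud networks, 2-D CNNs, GNNs) are out of scope; only the
  representation constructors are provided.
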