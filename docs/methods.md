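# Methods

This document specifies the models, parameters, and numerical choices
implemented in `bicompdta`, the scope of the synthetic benchmark, and the
known limitations. All defaults quoted here are the values in the code.

## 1. Problem setting

Given a set of proteins (amino-acid sequences), a set of ligands (SMILES
strings), and measured binding affinities for protein–ligand pairs, the
package fits a regressor that predicts the affinity of new pairs.
Affinities are treated as continuous values on a log scale; `kd_to_pkd`
converts dissociation constants in nM via `pKd = −log10(Kd / 1e9)`.

## 2. Protein representation: combined similarity to a reference panel

Each protein is represented by its vector of similarities to a fixed
reference panel (the training-fold proteins). Two complementary
similarity channels are combined.

### 2.1 Alignment channel (Smith–Waterman)

Local alignment scores with affine gaps are computed by the standard
H/E/F dynamic program. A gap of length L costs
`gap_open + (L − 1) · gap_extend`, i.e. opening a gap already includes
the first position — the same convention as Biopython's
`PairwiseAligner`, against which the kernel is cross-checked in the test
suite. Defaults: BLOSUM62 substitution scores, `gap_open = 10`,
`gap_extend = 0.5`. The unknown residue `X` scores 0 against everything.
Scores are normalized to

    S_SW(i, j) = SW(i, j) / sqrt(SW(i, i) · SW(j, j)),

clamped to [0, 1]; the matrix diagonal is exactly 1 by construction. The
kernel is JIT-compiled with numba when available, with an identical
pure-Python fallback.

### 2.2 Compression channel (normalized compression distance)

The normalized compression distance between sequences a and b is

    NCD(a, b) = (C(ab) − min{C(a), C(b)}) / max{C(a), C(b)},

where `C(·)` is the compressed length in bytes. Because concatenation
order matters slightly in practice, the package symmetrizes by averaging
both orders before converting to a similarity:

    S_NCD(a, b) = clamp(1 − mean(NCD(a,b), NCD(b,a)), 0, 1).

The matrix diagonal is *not* forced to 1: compressor overhead makes
`NCD(a, a) > 0` and the representation records that honestly.

Compressor: raw LZMA2 stream (`lzma.FORMAT_RAW`), preset 9, with the
dictionary size pinned to 1 MiB. For inputs smaller than the dictionary
the compressed output is byte-identical to the preset-9 default (64 MiB
dictionary) while avoiding a 64 MiB allocation per call; this makes
panel-matrix construction roughly 145× faster. The raw stream omits
container headers, so small-input lengths reflect content, not framing.

Small-input caveat: for strings much shorter than ~1 kB, per-block
overhead makes single-order NCD noticeably asymmetric (differences up to
~0.06 at lengths of a few hundred characters). The symmetrized matrix is
exactly symmetric regardless; the empirical single-order symmetry audit
in the acceptance suite therefore uses length-1000 sequences.

### 2.3 Combination

The combined similarity is the Hadamard (entry-wise) product of the two
matrices, with the diagonal forced to 1 and entries clamped to [0, 1].
Alternative combiners are available for ablation: `sw_only`, `ncd_only`,
and `weighted_sum` (`w · S_SW + (1 − w) · S_NCD`). A protein's feature
vector is its row of combined similarities to the panel; proteins not in
the panel are encoded by computing both similarities against each panel
member, so cold-start folds never leak test identities into the
representation.

## 3. Ligand representation

SMILES strings are label-encoded per character: codes 1..K in order of
first appearance over the training ligands, 0 reserved for padding, K+1
for characters unseen at fit time. Sequences are truncated or zero-padded
to `max_len` (default: the longest training SMILES, capped at 200).

## 4. Model

A two-branch feed-forward network, implemented in NumPy with manual
backpropagation (no deep-learning framework is required).

* **Protein branch:** three fully connected ReLU layers over the
  panel-similarity vector (default sizes 128, 128, 64), dropout after
  each.
* **Drug branch:** embedding (dim 32) over SMILES codes, two standard
  1-D convolutions and one depthwise-separable 1-D convolution (32
  filters, kernel length 4, valid padding, stride 1), then global max
  pooling. A pure fully-connected variant (`drug_branch="fc"`) exists
  for comparison.
* **Head:** concatenation, three fully connected ReLU layers (128, 64,
  32) with dropout, and a linear output.

The depthwise-separable convolution factors a k×C_in×C_out kernel into a
depthwise k×C_in stage and a pointwise C_in×C_out stage. At kernel 8
with 32 channels this is 8·32 + 32·32 = 1280 weights versus
8·32·32 = 8192 for the standard convolution (both without bias) — a
6.4× reduction in that layer.

Training: Adam (lr 1e-3, β₁ 0.9, β₂ 0.999), batch size 64, MSE loss,
inverted dropout (rate 0.1), up to 30 epochs with early stopping
(patience 15) on a seeded 10% validation split, best weights restored.
All randomness (initialization, shuffling, dropout, validation split)
derives from the model seed, so training is bit-reproducible. A
non-finite loss raises `DivergenceError` rather than continuing.

## 5. Evaluation metrics

* **Concordance index (CI):** fraction of pairs with distinct true
  values ranked correctly by the predictions; prediction ties score 0.5.
  Verified against an explicit O(n²) oracle and `lifelines`.
* **MSE** on the affinity scale.
* **rm²:** `r²·(1 − sqrt|r² − r0²|)` with r0² from the least-squares fit
  of predictions on observations through the origin.
* **AUPR** after binarizing true affinities at a threshold (pKd ≥ 7 for
  Kd/Ki-style data, 12.1 for KIBA scores), via
  `sklearn.metrics.average_precision_score`.

Metrics that are undefined on a fold (all labels tied, one class after
binarization, too few points) are reported as `None` and skipped when
averaging over folds.

## 6. Splits and controls

Five split modes: `warm` (random records), `cold_protein`, `cold_drug`,
`cold_pair` (test pairs whose protein fold and ligand fold coincide, so
both entities are unseen), and `group_holdout`. Fold assignment permutes
entities with a seeded generator and deals them round-robin. Shuffled-
label ("straw") controls permute labels within the training partition
(S2), the test partition (S3), or both (S1); a sound pipeline scores
near chance (CI ≈ 0.5) under S1. Every run writes a provenance manifest
recording the config, data fingerprints, seeds, and which partitions
were permuted.

## 7. Synthetic benchmark: scope and generator

Real benchmark datasets require large downloads and long training, so
the package evaluates itself on a planted-structure generator:

* **Proteins:** for each family, a random ancestor of length L
  (default 240 for end-to-end runs, 400 for the similarity-recovery
  panel); members are i.i.d. point-mutated copies (substitution rate
  0.1). Family identity is the planted signal both similarity channels
  must recover.
* **Ligands:** random strings of length 20–45 over a SMILES-like
  12-character alphabet.
* **Affinity:** `family_effect(protein) + Σ_c w_c · freq(c in ligand)
  + Gaussian noise (sd 0.3)`, affinely rescaled to [4, 10] (a pKd-like
  range). A model therefore needs both branches: family structure from
  the protein side, character composition from the drug side.
* All sub-streams are seeded via `np.random.default_rng([seed, k])`, so
  each component is independently reproducible.

Study conditions used by the acceptance suite (fixed before results were
measured): 6 families × 10 proteins × 40 ligands (2400 pairs), warm
5-fold with the first fold evaluated, and the default model above.

## 8. Numerical choices

* Similarity matrices compute self-scores once and mirror the upper
  triangle, guaranteeing exact symmetry.
* `SimilarityMatrix.to_csv` writes `%.17g`, so CSV round-trips are
  bit-exact.
* Sub-unit floating-point issues are handled by explicit clamping to
  [0, 1]; clamp counts are logged.
* Training-loss overflow is allowed to reach `inf` (under a suppressed
  NumPy overflow warning) and then raised as `DivergenceError`.

## 9. Limitations

* The generator's affinity law is additive and its ligands are random
  strings; it validates the pipeline's mechanics and controls, not
  chemical realism. Results on it say nothing quantitative about real
  benchmark performance.
* The panel representation scales O(n²) in panel size for fitting and
  O(n) per unseen protein; very large panels would need batching or
  sparsification not implemented here.
* The NumPy network targets CPU and small models; there is no GPU path.
* Single-order NCD is only approximately symmetric for short inputs
  (see §2.2).
* AUPR thresholds are dataset conventions, not tuned values.
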