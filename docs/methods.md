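# Methods

## The model

`csistrat` treats interaction prediction as a two-stage problem:
representation learning from the *structure* of the interaction graph,
then supervised prediction from frozen representations.

**Stratification.** Given the positive interaction set I over compounds C
and sequences S, each stratification key induces a stratum of congruent
views:

- compound key `c`: views `[c, (s_i, s_j)]` for all unordered pairs of
  distinct sequences interacting with `c` (`i < j` under lexicographic id
  order). A compound with a single partner `s` keeps the self-pair view
  `(s, s)` so no data are discarded.
- sequence key: the mirror image with compound pairs.
- reaction-feature key: reactions `b = {R, E, P}` are grouped by the key
  (the reaction id itself, its RCLASS, or its EC number) and each group
  pools three deduplicated view lists: reactant×product pairs, compound×
  enzyme pairs with compounds drawn from R ∪ P, and unordered enzyme
  pairs per member reaction (self-pair when a reaction has one enzyme).

Pairs rather than larger subsets keep the Siamese encoders small; using
*unordered* pairs avoids presenting the same gradient signal twice.

**Encoders.** Compounds are rdkit heavy-atom graphs; node features are a
10-way element one-hot (C, N, O, S, P, F, Cl, Br, I, other), scaled
atomic mass, total valence, ring flag, formal charge, radical electrons,
chiral tag, degree, hydrogen count and aromaticity (19 dims). Bond
features (type one-hot, ring, conjugation, 6-way stereo one-hot) are
stored on the graph; the GCN itself, like GraphDTA-class models, consumes
node features only. The GCN applies symmetric-normalized adjacency
convolutions (Â = D^-1/2 (A+I) D^-1/2) with ReLU, pools nodes with a
symmetric reduction (mean by default — this is what makes embeddings
invariant to atom reindexing), and finishes with two fully connected
layers.

Sequences are tokenized over the 20 standard residues plus one unknown
symbol (B/J/O/U/Z and anything else map to it; token 0 is padding),
right-padded or truncated to a fixed length `L_max` (default 1000; the
synthetic benchmark uses 128 because its sequences are 50–120 residues).
The CNN is a learned residue embedding, same-padded convolution blocks
with ReLU, a global max pool over positions and one fully connected
layer. Convolutions run over the padded tensor by default; a
`mask_padding` flag excludes padding positions from the max pool, making
embeddings independent of anything beyond the original length.

**Dimension convention.** Within a contrastive phase both views must have
equal dimension. Pair views concatenate two weight-tied arms of dimension
d′, so the lone-object encoder of the opposite view outputs 2·d′
directly. Default d′ = 32.

**Contrastive objective.** The discriminator is
h(z, z′) = exp(cos(z, z′)/τ). The directed batch loss is the standard
InfoNCE softmax cross-entropy with the congruent term included in the
denominator; the expectation in the per-anchor term is read as the
empirical batch term itself (no extra sampling inside the loss). The
two-view loss sums both anchoring directions; the three-view loss sums
the two-view loss over all unordered view pairs with equal weights.
Batches draw `k` distinct keys and one view tuple per key, so in-batch
candidates are non-congruent by construction; a trailing short batch is
used at its reduced size (logged once), and a batch of one key
contributes exactly zero loss.

**Phase 2.** Encoders are frozen (verified by SHA-256 over all weights
before/after) and an MLP scores each pair from concatenated view
embeddings. At inference a pair (c, s) is composed as: lone-object
encoders applied directly, each Siamese arm applied to the duplicated
pair — for the two-phase model
`GCN_A(c) ⊕ [CNN_A(s)|CNN_A(s)] ⊕ [GCN_B(c)|GCN_B(c)] ⊕ CNN_B(s)`
(8·d′ features), and for the reaction model the three view encoders give
6·d′ features. Duplication preserves the dimensions the arms were trained
with; this composition is a package convention since only the
concatenation itself is canonical. The loss is cross entropy with the
positive class weighted by the train negative:positive ratio.

**Baseline.** The no-stratification reference is the same GCN and CNN
(each emitting 2·d′) concatenated into the same MLP and trained end to
end jointly — a GraphDTA-style binary predictor — on identical splits and
identical negative sets for a given seed.

## Protocol

Positives are split 8:1:1 into train/validation/test. Negatives are
drawn uniformly without replacement from C×S minus known pairs,
disjointly across splits: 5:1 for train and validation, a configurable
ratio for test (default 1:1, the convention for headline numbers; 5/10/25
are supported). Labelled negatives supplied in the input (e.g.
inhibitors) join the train pool as-is and are never re-sampled.

Phase-1 strata are built from the *train-split* positives only, so no
held-out pair influences pretraining. In reaction mode only the
compound–sequence view list contains interaction pairs; those tuples are
trimmed to the train split while the reactant–product and enzyme-pair
views, which carry no interaction labels, are kept whole.

The unseen-generalization split holds out the fraction (default 5%) of
compounds and of sequences with the fewest positives (ties broken
lexicographically); every pair touching a held-out entity moves to the
unseen table, and the train table's id registries exclude held-out
entities so negative sampling cannot touch them either.

Early stopping monitors validation loss with patience 10 and restores
the best weights. The optimizer is Adam (lr 1e-3, β = 0.9/0.999
throughout).

## Defaults and why

| parameter | default | notes |
|---|---|---|
| temperature τ | 0.07 | best value on the reference grid 0.05–0.08; configurable |
| contrastive epochs | 700 | reference protocol (benchmark uses 50) |
| predictor epochs | 200 | with early stopping (benchmark uses 30) |
| batch size k | 8 | distinct keys per contrastive batch |
| train neg:pos | 5:1 | reflects the sparsity of true interactions |
| split | 8:1:1 | train/validation/test over positives |
| d′ | 32 | arm dimension; views are 64-dimensional |
| GCN | 3 layers, hidden 64, mean pool | desk-scale; deeper stacks oversmooth small molecules |
| CNN | embed 16, channels (16, 32), kernels (7, 7) | two blocks suffice to detect 6-mer motifs |
| MLP head | (128, 32) | logit output, sigmoid at inference |

The encoder sizes are deliberately compact: the package targets CPU-scale
experimentation and the bundled benchmark, and at these data sizes wider
stacks add runtime without changing the qualitative comparisons. All are
configurable through `EncoderConfig`/`TrainConfig`.

## The synthetic generator

The block model emulates what stratification exploits in real data:
latent groups of compounds preferentially interacting with latent groups
of sequences, with group identity detectable from the raw inputs.
Compounds and sequences are assigned uniformly to G groups (each group
guaranteed non-empty); each pair is an independent Bernoulli draw with
probability `p_in` within groups and `p_out` across. Each compound is a
random alkane/ether backbone with a group-specific functional-group motif
(carboxyl, sulfonamide, trifluoromethyl, ...) appended with probability
`motif_strength`; each sequence is a uniform residue string with a
group-specific 6-mer inserted at a random position with the same
probability. Defaults: G = 4, 80×80 entities, p_in = 0.3, p_out = 0.01,
motif_strength = 0.9, sequence lengths 50–120, molecule sizes 8–20 heavy
atoms. All randomness flows from one master seed through named
`SeedSequence` children, so outputs are byte-stable.

The reaction generator draws each reaction's reactants, products and
enzymes from one matched group and allocates RCLASS/EC label spaces by
group, so same-label reactions share a group; it also returns the induced
compound–enzyme interaction table.

What the generator does *not* emulate: chemistry beyond parseability
(synthesizability, scaffold diversity), protein families or homology
structure, degree heterogeneity, or assay noise. Passing the benchmark
shows that the pipeline extracts group structure that congruent views
share — it does not certify performance on real binding data.

## Benchmarks

The block benchmark (three replicate seeds; each replicate regenerates
the dataset and refits both models) compares held-out test AP of the
stratified model and the baseline at a 1:1 test ratio, and measures the
within-group minus between-group mean cosine similarity of the
pretrained compound embeddings. The reaction benchmark fits the
three-view model on the induced table of 40 generated reactions and
reports the contrastive-loss drop and test AP. Fifty contrastive and
thirty predictor epochs per phase keep a full replicate around a minute
on one CPU; `scripts/acceptance.py` writes every number it computes.

## Numerical choices and edge cases

- Cosine norms get an ε = 1e-12 floor, but an exactly-zero vector is a
  hard error; log-sum-exp uses max subtraction.
- Ranking ties are broken by stable original-order index; permuting tied
  items can change a metric, which is documented rather than hidden.
- MAP@k truncates the candidate list at k and normalizes by min(R, k);
  "Precision@1" is the label of the top-ranked item. Groups without a
  positive are skipped and counted.
- Strata statistics (mean pairwise shared members and Jaccard over the
  non-key-side member sets) are reported as undefined, not an error, for
  fewer than two strata.
- Gradients are computed by a small reverse-mode autodiff engine on
  float64 numpy arrays; training is bit-reproducible for a fixed seed on
  a single CPU thread.

## Known limitations

- The GCN ignores bond features (they are parsed and stored); edge-aware
  message passing is a possible extension.
- Phase-1 batch assembly samples one view tuple per key per step, so very
  large strata are explored slowly.
- The inference-time duplication convention for Siamese arms is one of
  several defensible compositions.
- The autodiff backend is single-threaded numpy: adequate for the bundled
  problem sizes, not for database-scale training.
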