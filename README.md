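# csistrat

Contrastive data stratification for compound–protein interaction
prediction.

Deep interaction predictors live or die by the quality of their compound
and protein representations. `csistrat` improves those representations by
*stratifying* an interaction dataset into keyed groups of congruent views
and pretraining the encoders contrastively on them, before any
interaction label is used:

- **compound key** `c`: every unordered pair `(s_i, s_j)` of sequences
  known to interact with `c` is a view congruent with `c`;
- **sequence key** `s`: mirror image with compound pairs `(c_i, c_j)`;
- **reaction-feature key** (a reaction, its RCLASS biotransformation
  class, or its EC number): three views per key — reactant–product pairs,
  compound–sequence pairs, and catalyzing-enzyme pairs.

Views under the same key are pulled together, views across keys pushed
apart, with a temperature-scaled InfoNCE objective over in-batch
candidates. For a batch of k aligned view embeddings with discriminator
h(z, z') = exp(cos(z, z') / τ):

    L(V1→V2) = (1/k) Σₙ −log [ h(z1ₙ, z2ₙ) / Σₘ h(z1ₙ, z2ₘ) ]
    L(V1, V2) = L(V1→V2) + L(V2→V1)

and with three views the loss is summed over all unordered view pairs.
Compounds are encoded with a GCN over rdkit molecular graphs, sequences
with a 1D CNN over tokenized residues; pair views use weight-tied
(Siamese) arms. After pretraining the encoders are frozen and a small MLP
is trained on the concatenated view embeddings with class-weighted cross
entropy; ranking quality is reported as AP / R-precision overall and MAP,
R-precision, MAP@3, Precision@1 grouped by compound and by sequence.

Everything runs on plain text inputs (interaction TSV, compound TSV of
SMILES, FASTA, reaction TSV) and a bundled block-model simulator
generates complete synthetic datasets with latent group structure for
benchmarking.

## Worked example

```python
from csistrat import BlockModelConfig, CSIModel, BaselineModel, generate_block_dataset
from csistrat.benchmark import BENCHMARK_CONFIG, cosine_group_gap

table, compounds, sequences, (cgroups, _) = generate_block_dataset(BlockModelConfig(seed=0))
csi = CSIModel(table, compounds, sequences, BENCHMARK_CONFIG).fit(seed=0)
base = BaselineModel(table, compounds, sequences, BENCHMARK_CONFIG).fit(seed=0)

print(csi.test_ap, base.test_ap)
print(cosine_group_gap(csi.compound_embeddings(), cgroups)["gap"])
```

On the default 80×80, 4-group dataset this prints (about a minute on one
CPU):

```
0.8038257356703546 0.7116054382327629
0.6159981662538466
```

i.e. held-out test AP 0.804 for the stratified model against 0.712 for
the identically-split end-to-end baseline, and a 0.62 cosine-similarity
gap between same-group and cross-group compound embeddings after the
contrastive phase — the representation learned group identity from raw
SMILES before ever seeing an interaction label. `csi.summary()` prints
the split sizes, loss traces and the full metric table.

The same workflow is available from the shell:

```bash
csi simulate --out-dir data --seed 0 --with-reactions
csi run --interactions data/interactions.tsv --compounds data/compounds.tsv \
        --sequences data/sequences.fasta --seed 0
csi reaction-run --reactions data/reactions.tsv \
        --interactions data/induced_interactions.tsv \
        --compounds data/compounds.tsv --sequences data/sequences.fasta
```

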