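# microbelm

Microbial "language" models for 16S microbiome samples: treat each sample
as an ordered list of taxon tokens, pre-train a transformer encoder on
unlabeled communities, and reuse the frozen encoder for host-phenotype
prediction, taxon-level attribution, and contextualized taxon embeddings.

The package is aimed at microbiome ML researchers who want a
self-contained, CPU-runnable implementation of this workflow with a
ground-truth-known synthetic study system for validating every stage.

## The model

A sample is a relative-abundance vector over taxa (ASVs).  It becomes a
token sequence by ranking the taxa present in decreasing abundance,
truncating to the 512 most abundant, and prepending a `CLS` token; rank
order is the only abundance information retained, encoded by absolute
positional embeddings.  The encoder is a transformer: a frozen taxon
embedding layer (100-d vectors, e.g. GloVe co-occurrence embeddings), a
trainable projection to a 200-d hidden space, and 5 encoder blocks.

Pre-training is ELECTRA-style replaced-token detection: a *generator* is
trained to recover the 15% of taxa replaced by `MASK`, then a
*discriminator* learns to label each taxon of a generator-completed sample
as real or modified, with progressively stronger generator checkpoints
swapped in on a fixed cadence (reference schedule 240/30/120/15 — eight
checkpoints consumed in order).  The discriminator's encoder becomes a
universal sample encoder.

Fine-tuning attaches a two-layer head to the `CLS` state and trains only
the head, the projection and the `CLS` embedding (SGD, lr 0.01, momentum
0.9, MSE-on-probability loss, 10% random taxon deletion, minority
oversampling).  A k=10 ensemble of single-epoch heads, aggregated by mean
probability, trades in-distribution sharpness for robustness under
distribution shift.

Taxon importance uses feature-ablation attribution

    a(m) = (1/|D_m|) * sum over samples X containing m of [ M(X) − M(X\m) ]

validated across two cohorts by a confident-correct filter (top 50%
confidence), a 5% prevalence floor, a ≥5-samples-per-dataset support
floor, and a same-sign requirement.  Contextualized embeddings (mean
final-block state per taxon) are evaluated by k-means phylum purity and by
Spearman correlation against binary pathway annotations with a
1,000-permutation significance test.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Generate a synthetic world (known co-occurrence blocks, taxonomy,
pathways, and six taxa planted at 0.8/0.1 prevalence in positive/negative
patients), pre-train, and fine-tune:

```python
import numpy as np
import microbelm as m
from microbelm.electra import PretrainSchedule, train_generator, train_discriminator

world = m.generate_world(m.SyntheticConfig(n_samples=800, seed=1))
vocab = world.vocabulary()
seqs  = m.tokenize_table(world.abundance, vocab)

cfg   = m.ModelConfig(vocab_size=vocab.size, seed=1)
sched = PretrainSchedule(generator_epochs=16, generator_checkpoint_every=2,
                         discriminator_epochs=12, generator_swap_every=2,
                         learning_rate=3e-4)
gen   = m.build_model(cfg, vocab, world.embeddings, "token_vocab", rng_seed=2)
ckpts, _ = train_generator(gen, seqs[:400], sched, np.random.default_rng(3))
disc  = m.build_model(cfg, vocab, world.embeddings, "token_binary", rng_seed=5)
train_discriminator(disc, seqs[:400], ckpts, sched, np.random.default_rng(7),
                    generator_template=gen)

labels, patients = world.label_array(), world.patient_array()
runs = m.run_protocol(disc, seqs, labels, patients, m.SplitSpec(seed=9),
                      m.FinetuneConfig(epochs=3, batch_size=64), n_runs=2)
print(runs[["auroc", "aupr", "stopping_epoch"]])
```

A run of the equivalent pipeline (`scripts/acceptance.py --seed 1`) prints,
among others:

```
generator_heldout_top1_accuracy = 0.0090   # masked-taxon recovery; uniform guessing = 0.0033
discriminator_heldout_balanced_accuracy = 0.6209   # real-vs-modified detection; chance = 0.5
phenotype_auroc_mean = 0.8938              # planted-signal recovery under the blocked protocol
single_test_auroc = 0.9016                 # one fine-tuned classifier, held-out patients
single_shifted_auroc = 0.8184              # the same classifier on a distribution-shifted cohort
null_world_auroc = 0.5725                  # no planted signal: chance within sampling noise
planted_markers_in_top_positive_attributions = 1.0000   # all 6 planted taxa rank on top
cliffs_delta_contextual_vs_vocabulary_significant_r = 0.1479
```

Read: the encoder learned community structure well above chance from
unlabeled data; the frozen-encoder classifier recovers the planted
phenotype signal and holds up on a shifted cohort; with no planted signal
it scores at chance (no label leakage); ablation attribution ranks exactly
the planted taxa on top; and the contextualized embedding dimensions carry
stronger significant pathway correlations than the input vocabulary
embeddings (positive Cliff's delta), echoing the motivation for
contextualized representations.  At this desk scale the k = 10 single-epoch
ensemble trails the converged single classifier (one epoch here is only a
thousand sample presentations); see `docs/methods.md`.

## Command line

```
microbelm synth      --config world.yaml --outdir world/
microbelm pretrain   --corpus world/abundance.tsv --embeddings world/embeddings.tsv --outdir pre/
microbelm finetune   --encoder pre/discriminator.npz --corpus world/abundance.tsv \
                     --labels world/labels.tsv --mode ensemble --outdir clf/
microbelm attribute  --model clf/classifier.npz --dataset-a worldA/ --dataset-b worldB/ \
                     --taxonomy world/taxonomy.tsv --out markers.tsv
microbelm eval-embeddings --model pre/discriminator.npz --corpus world/abundance.tsv \
                     --taxonomy world/taxonomy.tsv --pathways world/pathways.tsv --outdir eval/
microbelm evaluate   --encoder pre/discriminator.npz --corpus world/abundance.tsv \
                     --labels world/labels.tsv --out runs.csv
```

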