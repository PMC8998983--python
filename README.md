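# cpinet

Compound-protein binding-affinity regression from three complementary views
of a (compound, protein) pair, for computational chemists and method
developers working on virtual screening: given a compound's SMILES string
and a protein's structural annotation, predict a real-valued affinity
(log10 IC50; lower = stronger binder) and rank candidate compounds against
a target.

## The model

Three (optionally four) channels feed a fully connected regression head:

* **SMILES channel** — symbol-level tokens (64-symbol alphabet + 4
  specials = 68) through an embedding, a 2-layer GRU encoder, additive
  attention over positions, and a 1-D convolution with global max pooling.
* **SPS channel** — the protein as a *structural property sequence*: one
  4-letter word per secondary-structure segment encoding structure (A/B/C),
  solvent exposure (E/N), dominant residue class (G/T/D/K) and length
  bucket (S/M/L); 72 words + 4 specials = 76. For example `AEKM` is an
  exposed, predominantly basic alpha helix of medium length. Same
  GRU-attention-convolution stack, dimension 256.
* **graph channel** — the 2-D molecular graph (via RDKit) under a
  degree-filtered graph convolution: for rounds L = 1..3, every atom
  updates as `r_a <- relu((r_a + sum of neighbour states) @ H[L, |N(a)|])`
  with one filter matrix per neighbour count 1..5, then additive attention
  pools atom states into the molecule vector.
* **amino channel** (four-channel variant) — a bidirectional GRU over the
  raw residue sequence, concatenated into the protein representation.

The SMILES and SPS channels can be **pretrained as GRU seq2seq
autoencoders** on unlabeled corpora; their embedding/encoder weights then
warm-start end-to-end training, which minimises mean squared error.
Evaluation uses RMSE and R² = 1 − SS_res/SS_tot; screening sorts a
compound library by predicted affinity against one protein.

A seeded synthetic benchmark (valid small molecules, block-annotated
proteins, labels from a known mechanism plus Gaussian noise) makes every
stage runnable and testable offline. All numerics run on a built-in
float64 reverse-mode autodiff engine, so fixed seeds reproduce training
bitwise. See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

`python examples/04_train_evaluate_screen.py` trains the three-channel
model on 800 synthetic pairs (noise SD 0.3) and prints:

```
612 train / 68 val / 120 test pairs; label SD 0.635, noise SD 0.3
best val RMSE 0.356
held-out RMSE 0.299, R2 0.771 (n=120)

top 5 predicted binders (lower score = stronger):
  rank  1  CCCC         score 1.832  ok
  rank  2  CCCC         score 1.832  ok
  rank  3  CCCCC        score 1.928  ok
  rank  4  NC           score 2.126  ok
  rank  5  CN           score 2.130  ok
```

Held-out RMSE 0.299 sits at the generator's noise floor (0.3) while a
mean predictor would score the label SD (0.635) with R² = 0 — the model
has recovered essentially all of the learnable mechanism. The screening
ranks pure-carbon chains strongest, exactly what the mechanism (which
penalises hetero atoms and rings) implies for this protein.

The other examples are single-capability walkthroughs: SPS encoding
(`01`), molecular graphs and the degree-filtered convolution (`02`), and
autoencoder pretraining (`03`). A thin CLI wraps the same library:
`cpinet simulate | build-vocab | encode-sps | pretrain | train | evaluate |
predict | screen` (see `cpinet --help`).

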