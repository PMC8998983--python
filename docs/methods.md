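# Methods

## Problem and model

`cpinet` regresses the binding affinity of a compound-protein pair, on a
log10 IC50 scale, from three complementary views of the pair:

1. **SMILES channel.** The compound's SMILES string is tokenized
   symbol-wise (greedy longest match, so `Cl`, `Br` and `@@` are single
   tokens), embedded, and encoded by a 2-layer GRU. Additive attention
   assigns a weight to every position; a 1-D convolution with global max
   pooling over the attention-weighted encoder outputs yields the channel
   vector.
2. **SPS channel.** The protein is represented as a structural property
   sequence: one 4-letter word per secondary-structure segment, encoding
   structure (A/B/C), majority solvent exposure (E/N), dominant residue
   class (G non-polar / T polar / D acidic / K basic), and a length bucket
   (S/M/L). The 3x2x4x3 product gives 72 legal words; with the four
   reserved specials (start/end/pad/unused) the channel vocabulary has 76
   entries. The word sequence passes through the same
   embed-GRU-attention-convolution stack as the SMILES channel.
3. **Graph channel.** RDKit parses the SMILES into a heavy-atom graph.
   Atom states are initialised by a learned linear projection of raw atom
   features (one-hot element over {C,N,O,S,F,Cl,Br,I,P,B,other}, degree
   one-hot 0-5, aromaticity flag, formal charge) and updated for R = 3
   rounds by `r_a <- relu((r_a + sum_{u in N(a)} r_u) @ H[L, |N(a)|])`,
   where the filter matrix is selected by the atom's neighbour count
   (five filters per round; degree 0 is clamped to the first filter with
   an empty neighbour sum, degree > 5 to the fifth). Additive attention
   pools the final atom states into the molecule vector.
4. **Amino channel (optional, the four-channel variant).** A bidirectional
   2-layer GRU over the raw residue sequence with the same
   attention-convolution head, concatenated with the SPS vector to form
   the protein representation.

The compound vector is the concatenation of the SMILES and graph channel
vectors; the protein vector is the SPS vector (plus the amino vector in the
four-channel variant). A two-layer fully connected head (hidden 512, ReLU,
dropout) maps their concatenation to the scalar affinity. Training
minimises mean squared error end to end. Channel subsets are first-class
configuration, so ablations such as {sps, graph} train without code
changes.

**Synchronous graph update.** All atoms update from the previous round's
states. A literal one-atom-at-a-time in-place sweep would make the result
depend on atom ordering and so break invariance under graph isomorphism;
the in-place variant is retained behind a flag (`in_place=True`) only for
comparison. Permutation invariance of the pooled molecule vector is tested
property-style.

## Seq2seq pretraining

Each sequence channel can be pretrained as an autoencoder on unlabeled
corpora: the embedding + GRU encoder produces per-position outputs and a
fixed-dimension thought vector (final hidden states of the stacked layers,
concatenated and linearly projected to the channel dimension); a 2-layer
GRU decoder with additive cross-attention over the encoder outputs
reconstructs the input under teacher forcing with masked cross-entropy.
Warm-starting the unified model copies the pretrained embedding and
encoder weights (`emb.*`, `enc.*`) into the matching channel; decoder-side
parameters are discarded.

Two optimisation schemes are exposed because both appear in the lineage of
this architecture: Adam at learning rate 1e-3 (the default — stable for
GRU training) and plain SGD at 0.5 with a 0.99 per-epoch decay. Gradient
norms are clipped at 5.0 in both schemes.

## Defaults and units

| parameter | default | notes |
|---|---|---|
| SMILES vocabulary | 64 symbols + 4 specials = 68 | base table is a reconstruction (see below) |
| SPS vocabulary | 72 words + 4 specials = 76 | exact Cartesian product |
| max lengths | 100 (SMILES), 152 (SPS) tokens | capacity incl. start/end |
| channel dims | 128 compound, 256 protein | latent = embedding dim |
| GRU layers / dropout | 2 / 0.2 | dropout between layers, train only |
| graph radius / filters | 3 / 5 per round | filters are hidden x hidden |
| conv | 64 filters, kernel 4, ReLU, global max pool | per sequence channel |
| head | 512 hidden, ReLU, dropout 0.2 | scalar output |
| pretraining | 100 epochs, batch 64, Adam 1e-3 | |
| unified training | 100 epochs, batch 64, Adam 1e-4 | 10% validation split |
| affinity scale | log10 IC50 | lower = stronger binder |

Over-length sequences are rejected, not truncated (corpus curation is the
caller's job); unknown tokens raise by default, or map to the reserved
"unused" slot under the lenient policy.

## Reconstructions and open choices

* **SMILES base alphabet.** The 64-symbol table shipped in
  `cpinet/data/smiles_base64.json` is a reconstruction: it covers the
  organic subset, aromatic lowercase forms, common two-character elements,
  digits and SMILES punctuation. It is config-overridable, and
  vocabularies can instead be derived from any corpus.
* **Residue classes.** acidic {D,E}, basic {K,R,H}, polar {S,T,N,Q,C,Y,G},
  non-polar {A,V,L,I,P,F,M,W}; table overridable.
* **Segment length buckets.** short <= 3, medium 4-7, long >= 8 residues.
  These cutoffs are package choices (no published values exist); they make
  a moderate 5-residue helix read "M", consistent with the canonical
  "AEKM" reading of an exposed basic alpha segment of medium length.
* **Tie-breaks.** Exposure ties vote exposed; residue-class ties resolve
  acidic > basic > polar > non-polar. Both rules exist purely to make the
  encoding deterministic.
* **Attention form.** Additive (Bahdanau-style) scoring everywhere —
  channel position attention, graph atom pooling, and decoder
  cross-attention — because no particular form is canonical for this
  architecture.
* **Thought vector.** Concatenation of the final hidden states of both
  encoder layers, projected to the channel dimension.
* **R-squared.** Reported as 1 - SS_res/SS_tot (can be negative); the
  SS_reg/SS_tot variant is also computed (`r2_alt`) since the two differ
  for biased predictors.
* **Screening direction.** Lower predicted log-IC50 ranks first (IC50 is a
  half-maximal inhibitory concentration, so lower means stronger); ties
  and failures preserve input order, and unparsable compounds stay in the
  output flagged as failed.

## Numerical engine

The layers run on a small reverse-mode autodiff engine over float64 NumPy
arrays (`cpinet.autodiff`): a tape of operations with explicit backward
closures, topological-order accumulation, and exactly the operator set the
model needs (matmul, elementwise nonlinearities, reductions, gather /
scatter-add, masked softmax with a detached max shift). Everything is
single-threaded deterministic: a fixed seed reproduces training histories
bitwise, and checkpoints (npz tensors + JSON manifest) round-trip
predictions exactly. Numerical safeguards: softmax and log-softmax shift
by a detached maximum; masked positions receive a -1e9 logit offset;
convolution windows are restricted to each sequence's real tokens, with
sequences shorter than the kernel keeping their first zero-tailed window
so pooling stays finite.

## Synthetic benchmark

The generator emulates the shape of a curated affinity corpus without any
download. Compounds come from a restricted grammar (linear/branched chains
and single rings over C, N, O; <= 40 characters) and are guaranteed
RDKit-parseable; proteins are 30-150 residues with block-structured
secondary structure (runs of 2-12) and random exposure. Labels follow a
fixed linear mechanism,

    label = 1.0 + 0.3 * (#O + #N atoms) + 0.6 * ring
          + 1.5 * frac(alpha segments) + 1.5 * frac(basic segments)
          + N(0, noise_sd),    noise_sd = 0.3 by default,

chosen so that the compound terms are visible to both compound channels,
the protein terms to the SPS (and amino) channels, and the overall label
needs both sides of the pair. The clean mechanism value is returned with
every sample for oracle tests. The mechanism SD is about 0.57, so labels
carry roughly twice the noise SD in signal: a mean predictor scores RMSE
~0.64 while the noise floor is 0.3.

What the generator does **not** emulate: real affinity distributions
(heavy tails, assay censoring), protein families and homology leakage
between splits, large molecules with stereochemistry or charges, and
annotation errors in secondary structure. Passing the synthetic checks
therefore demonstrates that the architecture can learn a
compound-and-protein-dependent signal at a known noise level — not that it
attains any particular accuracy on public affinity corpora.

Consecutive runs with the same secondary-structure category merge, so a
protein can legitimately encode to a single SPS word; the model handles
such 1-word sequences via the zero-tailed convolution window described
above.

## Problem sizes used by the test suite and acceptance script

Training-dependent checks run scaled-down configurations (channel dims 32,
64 filters -> 32, head 64) — widths chosen so the full pipeline trains in
minutes on one CPU while leaving the architecture untouched:

* autoencoder overfit: 200 generated molecules, 30 epochs, batch 16,
  Adam 2e-3 — reconstruction accuracy >= 0.99;
* end-to-end overfit: 64 noise-free pairs, 200 epochs, batch 16, Adam
  1e-3, dropout 0 — train RMSE < 0.1;
* generalization: 2000 pairs at noise 0.3 (70/15/15 split by two seeded
  10%/15% draws), 16 epochs, batch 64 — held-out RMSE is compared to the
  noise floor and the label SD, and the three-channel model to its
  {sps, graph} ablation, as medians over seeds 0-2.

## Known limitations

* The engine is CPU-only and unvectorised across time steps; it is sized
  for the synthetic benchmark, not for corpus-scale training.
* Greedy teacher-forced accuracy is the only decoding mode (no free-running
  or beam decoding).
* The in-place graph update exists only as a documented comparison point.
* SPS inputs assume 3-class secondary structure; 8-class annotations are
  collapsed by the standard DSSP reduction on entry.
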