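"""Train the three-channel regressor on the synthetic benchmark, evaluate
held-out RMSE / R-squared, and screen a compound library against one protein.

Labels follow a known mechanism (hetero-atom count, ring presence, the
protein's alpha and basic segment fractions) plus Gaussian noise, so the
model's held-out RMSE can be compared against the noise floor and the
screening order against the mechanism's own ranking.
"""

import numpy as np

from cpinet import (ModelConfig, SynthConfig, TrainConfig, UnifiedModel,
                    build_vocabulary, default_smiles_vocabulary, evaluate,
                    gen_dataset, screen_compounds, split_dataset, train_unified)
from cpinet.dataset import from_synthetic
from cpinet.sps import encode_sps, render_sps

synth = gen_dataset(SynthConfig(n_compounds=60, n_proteins=20, n_pairs=800,
                                noise_sd=0.3, seed=42))
cpi = from_synthetic(synth.samples)
rest, test = split_dataset(cpi, 0.15, seed=1)
train, val = split_dataset(rest, 0.1, seed=2)
print(f"{len(train)} train / {len(val)} val / {len(test)} test pairs; "
      f"label SD {cpi.labels().std():.3f}, noise SD 0.3")

config = ModelConfig(channels=("smiles", "sps", "graph"),
                     smiles_dim=32, sps_dim=32, graph_hidden=32,
                     conv_filters=32, attention_dim=16, head_hidden=64,
                     max_smiles_len=40, max_sps_len=60)
vocabs = {"smiles": default_smiles_vocabulary(),
          "sps": build_vocabulary([list(s.sps) for s in cpi.samples], "sps")}
model = UnifiedModel.initialize(config, vocabs, seed=0)
_, history = train_unified(model, train, val,
                           TrainConfig(epochs=10, batch_size=64,
                                       learning_rate=1e-3, seed=0))
print(f"best val RMSE {min(h['val_rmse'] for h in history):.3f}")

result = evaluate(test.labels(), model.predict(test.samples))
print(f"held-out RMSE {result.rmse:.3f}, R2 {result.r2:.3f} (n={result.n})")
# RMSE near the 0.3 noise floor and R2 >> 0 mean the model recovered most
# of the mechanism; the mean predictor would score RMSE = label SD, R2 = 0.

library = synth.compounds[:15]
words = encode_sps(synth.proteins[0])
entries = screen_compounds(model.screening_predictor(render_sps(words)), library)
print("\ntop 5 predicted binders (lower score = stronger):")
for e in entries[:5]:
    print(f"  rank {e.rank:2d}  {e.smiles:<12s} score {e.score:.3f}  {e.status}")
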