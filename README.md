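# pathdrug

Pathway-difference multi-omics features and an attention network for
anticancer drug-response prediction.

## The problem

Predicting how sensitive a cancer cell line (or patient) will be to a
drug is central to precision oncology: large panels measure the
half-maximal inhibitory concentration (IC50) of hundreds of compounds
against hundreds of cell lines, and models trained on these panels can
prioritize therapies for new samples. `pathdrug` is for computational
biologists who want such a model whose inputs and attention weights are
*biologically legible*: cell lines enter not as ~20,000 raw gene values
but as one difference score per biological pathway, and drugs enter as
their SMILES strings rather than fingerprints, so the model can point
back at pathways and substructures when explaining a prediction.

## The method

**Pathway features.** For a cell line and a gene set *P* over gene
universe *U*, each omics layer is reduced to a within-vs-outside
contrast between genes in *P* and genes in *U \ P*:

* expression — a two-sided Mann–Whitney U test on the two groups of
  values, with U₁ = R₁ − n(n+1)/2, U₂ = nm − U₁, U = max(U₁, U₂),
  p from the normal approximation z = (U − nm/2)/√(nm(n+m+1)/12) for
  large samples or the exact null distribution of U for small ones;
  the feature is |log₁₀ p|;
* mutation and copy number — a 2×2 within/outside × normal/altered
  contingency table scored by a hybrid statistic: Pearson's
  χ² = Σ(O−E)²/E when every expected count exceeds 5, the
  likelihood-ratio G = 2ΣO·ln(O/E) otherwise, and exactly 0 when any
  expected count is 0. Copy-number categories come from
  round(ploidy × ratio): 2 is normal, ≤1 or ≥3 is altered.

**Drug encoding.** SMILES are tokenized (bracket atoms, Cl/Br, %nn
ring closures, single characters), mapped to integer ids by corpus
frequency, and left-padded to a fixed length (default 256).

**Network.** An embedding layer (16-dim), three 1-D convolutions
(kernels 3/5/11) and a 4-layer transformer encoder produce five
sequence representations of the drug. Per omics kind, five
SMILES-attention layers (α over token positions, context = weighted
sum) and five omics-attention layers (α over pathways, output = O ⊙ α)
score drug–omics interactions via α = softmax(tanh(O′ + S′)·V). The
concatenated interaction features pass through batch normalization and
an MLP to emit LN IC50, or a probability through a sigmoid head.

Everything runs on a small numpy autodiff engine bundled in
`pathdrug.nn` — no deep-learning framework required — and is exactly
reproducible from seeds.

**Evaluation.** Mixed, cell-blind and drug-blind splits; k-fold
cross-validation; MSE/RMSE/PCC/R² and AUC-PR; z-score sensitivity calls
(z < −2 sensitive, z > 2 resistant, per cell line or per drug); ranked
pathway-attention summaries and per-token attention maps.

A synthetic-data generator (`pathdrug.simulate`) produces gene sets,
three omics layers, valid drug SMILES and responses with planted,
known structure, so the whole pipeline is testable offline; see
`docs/methods.md`.

## Worked example

```python
from pathdrug import (SimConfig, simulate, make_split, SplitSpec, TrainConfig,
                      DrugResponseModel, evaluate, train, zscore_table)
from pathdrug.experiments import (build_dataset, reduced_model_config,
                                  vocab_size_of, target_pathway_recovery)
from pathdrug.train_eval import predict_rows

bundle = simulate(SimConfig(n_genes=400, n_pathways=20, n_cell_lines=80,
                            n_drugs=12, seed=42))
dataset = build_dataset(bundle)          # expression pathway features + tokens
trainval, test = make_split(dataset.responses, SplitSpec("mixed", 0.1, seed=0))
train_rows, val_rows = make_split(trainval, SplitSpec("mixed", 0.1, seed=1))
model = DrugResponseModel(reduced_model_config(
    vocab_size_of(dataset), dataset.omics_dims(), seed=0))
train(model, dataset, train_rows, val_rows,
      TrainConfig(epochs=20, batch_size=128, lr=2e-3, patience=5, seed=0))

report = evaluate(model, dataset, test)
print(f"test MSE {report.mse:.3f}  RMSE {report.rmse:.3f}  "
      f"PCC {report.pcc:.3f}  R2 {report.r2:.3f}  (n={report.n})")

recovery = target_pathway_recovery(model, dataset, bundle, test)
print(f"target pathway in attention top-20%: "
      f"{recovery['hits']}/{recovery['n_drugs']} drugs "
      f"(chance 20%, binomial p={recovery['p_value']:.2g})")

one_cell = dataset.responses[dataset.responses["cell_line"] == "CL000"].copy()
one_cell["prediction"] = predict_rows(model, dataset, one_cell)
calls = zscore_table(one_cell, axis="per_cell_line")
print(calls.sort_values("z").head(3)[
    ["cell_line", "drug", "prediction", "z", "class"]].to_string(index=False))
```

Output:

```
test MSE 1.275  RMSE 1.129  PCC 0.912  R2 0.828  (n=96)
target pathway in attention top-20%: 10/12 drugs (chance 20%, binomial p=4.5e-06)
cell_line drug  prediction         z     class
    CL000  D06   -4.537016 -2.979758 sensitive
    CL000  D03   -0.003908 -0.727827   neutral
    CL000  D00    0.954862 -0.251534   neutral
```

The held-out correlation of 0.91 shows the model recovered the planted
pathway-mediated response; 10 of 12 drugs place their true target
pathway in the top fifth of the attention ranking (chance would be
~2.4); and the z-score view flags D06 — strongly predicted below
CL000's average response — as a sensitive call.

## Command-line interface

```bash
pathdrug simulate --seed 3 --out fixtures/                 # synthetic bundle
pathdrug features --omics fixtures/expression.csv --kind expression \
    --gmt fixtures/gene_sets.gmt --out feats.csv
pathdrug encode-drugs --drugs fixtures/drugs.csv --out tokens.csv \
    --vocab vocab.json --max-length 256
pathdrug train --features expression=feats.csv --drugs fixtures/drugs.csv \
    --responses fixtures/responses.csv --split cell_blind --seed 0 --out run/
pathdrug evaluate --checkpoint run/checkpoint.npz --features expression=feats.csv \
    --drugs fixtures/drugs.csv --responses fixtures/responses.csv
```

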