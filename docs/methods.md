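# Methods

## Problem setting

`pathdrug` predicts how sensitive a cancer cell line is to a drug — the
natural-log half-maximal inhibitory concentration, LN IC50 — from two
modalities: multi-omics measurements of the cell line summarized at the
pathway level, and the drug's chemical structure given as a SMILES
string. A classifier variant predicts a binary response probability
instead (e.g. responder vs non-responder in clinical records). Beyond
point predictions, the model exposes attention weights over pathways and
over SMILES token positions, so predictions can be inspected for which
biology and which substructures drove them.

## Pathway-difference features

Gene-level omics matrices are converted to one value per (cell line,
pathway) that contrasts genes *within* a gene set against all other
genes of the universe. The universe defaults to the genes measured in
the matrix; genes absent from the matrix are dropped from both sides.

**Expression** (continuous, log-scale values). A two-sided Mann–Whitney
U comparison of within vs outside values:

    U1 = R1 − n(n+1)/2,   U2 = nm − U1,   U = max(U1, U2)

with R1 the sum of pooled average ranks on the within side, n within
genes, m outside genes. For large samples the p-value uses the normal
approximation

    p = 2 · SF_N( (U − nm/2) / sqrt(nm(n+m+1)/12) )

without continuity correction and, by default, without tie correction to
the variance (a tie-corrected variance is available behind
`tie_corrected=True`). For small samples (`min(n, m) ≤ 8` under
`mode='auto'`; the threshold is configurable) the exact null
distribution of U is used instead, computed by the classical counting
recursion f(n, m, u) = f(n−1, m, u−m) + f(n, m−1, u); the exact branch
assumes no ties and falls back to the asymptotic branch (with a logged
warning) when ties are present. Since 2·SF can exceed 1 near the null,
p is clamped to 1; before the feature transform it is floored at 1e-300
so the feature stays finite. The feature is |log10 p| ≥ 0: larger means
a more pronounced within/outside expression difference.

**Mutation** (status codes 0 = none, 1 = damaging mutation at allele
frequency < 0.95, 2 = at frequency ≥ 0.95). Each cell line × gene set
yields a 2×2 contingency table of within/outside × normal/mutant, where
"mutant" means status ≥ 1 (the table is binary; the 1/2 distinction
encodes frequency, not kind).

**Copy number** (per-gene ratios plus per-cell-line ploidy). Ratios are
converted to absolute copy numbers, `round(ploidy × ratio)`, using
round-half-to-even at .5 boundaries (configurable to half-up). Absolute
copy number 2 is "normal"; ≤ 1 (deletion) or ≥ 3 (amplification) counts
as "altered", collapsed into one altered column of the 2×2 table. If
the stored ratios are log2(x+1)-transformed, the loader flag
`--cnv-input log2p1` inverts the transform first; the default consumes
linear-scale ratios, keeping the absolute-copy-number formula literal.

**Hybrid contingency statistic.** For both discrete kinds the feature is
the test statistic itself (not a p-value): with expected counts E from
the table margins,

* any `E = 0` → the feature is exactly 0 (degenerate margin);
* `min(E) > 5` → Pearson's χ² = Σ (O−E)²/E;
* otherwise → the likelihood-ratio G = 2 Σ O·ln(O/E), with the
  0·ln(0/E) = 0 limit convention.

The boundary is strict (`min(E) = 5` goes to the G branch) because the
Pearson condition is stated as "greater than 5". Pathways with fewer
than `min_set_genes` (default 2) genes present in the matrix yield a 0
feature with a warning — a one-gene side makes the rank test degenerate.

## Drug encoding

SMILES strings are split into language tokens — bracket atoms `[...]`,
the two-letter halogens Cl/Br, `%nn` ring closures, and single
characters — so that token concatenation reproduces the input exactly.
A vocabulary is built from the training corpus by descending token
frequency (ties broken lexicographically), ids 1..V, with id 0 reserved
for padding; construction is a deterministic function of the corpus.
Each drug becomes a fixed-length integer vector (default length 256),
left-padded. No canonicalization is applied and no start/stop tokens
are used. Pad positions participate in attention by default; an
optional `pad_mask` flag excludes them.

## Network

* **SMILES encoding network.** An embedding layer maps each token id to
  a 16-dimensional vector (256×16 under defaults). Three 1-D
  convolutions over the sequence (kernel sizes 3, 5, 11, full embedding
  depth, same-length padding so outputs stay position-aligned with
  tokens) capture substructures at multiple scales, followed by ReLU.
  A four-layer transformer encoder (post-norm, sinusoidal positional
  encoding) captures long-range dependencies. Together with the raw
  embedding this yields five sequence representations.
* **Attention network.** One subnetwork per omics kind — SGAN
  (expression), SCAN (copy number), SMAN (mutation) — each pairing the
  five representations with five SMILES-attention and five
  omics-attention layers. A SMILES-attention layer scores positions as
  α = softmax(tanh(O′ + S′)·V), where S′ = S·Ws lifts the sequence into
  the attention space (dim A) and O′ lifts the pathway vector via a
  feature map (1→A) composed with a position map (O→S); its output is
  the α-weighted sum of the sequence (a context vector). The
  omics-attention layer mirrors the construction with α over pathways
  and outputs the pathway vector gated elementwise, O ⊙ α, preserving
  per-pathway scores for interpretability. The published equations for
  the omics lift do not compose as written (a 1×A map cannot meet an
  S×A map over an O-long vector); the feature-lift-then-position-map
  reading used here is the composition consistent with the O′ + S′ sum.
  The lift is algebraically rank-1, so it is evaluated as
  (O·Wpᵀ) ⊗ Wo — identical values, far cheaper.
* **Prediction head.** All context and gated vectors are concatenated
  (width 5·C + 5·O per omics kind), batch-normalized once, and passed
  through a ReLU MLP with dropout; the final unit is linear (LN IC50)
  or sigmoid (response probability).

Only the embedding dimension (16), conv kernels (3/5/11) and
transformer depth (4) are fixed by the published design. Everything
else is explicit configuration with defaults: conv channels = embedding
dim, 4 heads, feed-forward width 128, attention dim A = 64, MLP
(512, 128), dropout 0.2.

The network runs on a small in-package numpy reverse-mode autodiff
engine (`pathdrug.nn`): tensors record backward closures, gradients are
checked against finite differences in the test suite, and training uses
Adam. Model construction, dropout and minibatch order all derive from
explicit seeds, so runs are exactly reproducible; evaluation mode is
deterministic.

## Training and evaluation

Losses are mean squared error (regression) or binary cross-entropy
(classifier); optimizer Adam. Defaults cap training at 200 epochs with
batch size 512 and early-stop on validation loss with patience 20,
restoring the best parameters. The validation set is 10% of the
training rows, split with the same strategy as the outer split.

Three splitting strategies: *mixed* (row-level), *cell-blind* (held-out
cell lines) and *drug-blind* (held-out drugs); blind strategies
partition entities before expanding to rows, so entity leakage is
structurally impossible. k-fold cross-validation partitions rows
(mixed) or entities (blind). Metrics: MSE, RMSE, Pearson r, R² and
AUC-PR (average-precision form), cross-checked against scikit-learn in
tests.

Z-score sensitivity calls standardize predictions along a chosen axis —
per cell line (comparing drugs) or per drug (comparing cell lines); the
axis is a required argument since both views are meaningful. z < −2 is
"sensitive", z > 2 "resistant". The population standard deviation
(ddof = 0) is used so the standardization identity (mean 0, sd 1) holds
exactly; zero-spread groups produce all-neutral calls with a warning.

## Interpretability

Pathway attention is summarized per cohort by averaging a sample's five
omics-attention α vectors, then averaging samples; pathways are ranked
descending and the top 20% flagged (fraction configurable). Per-layer
scores can also be exported; with several omics kinds, summaries are
per kind, not pooled. Token attention maps drop pad positions, attach
each weight to its token and character span (possible because the conv
branches preserve positions), and highlight scores above 0.01.

## Synthetic data

The generator emulates the statistical structure of the real inputs the
pipeline targets, with planted ground truth. Defaults: 1,000 genes, 50
pathways of 10–50 genes (drawn independently, so sets may overlap), 200
cell lines, 30 drugs. Each (cell line, pathway) pair is "active" with
probability 0.3; active pairs receive a +1.0 sd expression shift on the
pathway's genes, an enriched damaging-mutation rate (0.2 vs 0.02 base;
status 2 with conditional probability 0.1), and an enriched
copy-number-alteration rate (0.3 vs 0.05), with altered genes set to
absolute copy number 4 (amplified) or 1 (deleted) and ratios derived by
dividing by a ploidy drawn uniformly from 1.8–4.2 (plus 2% measurement
noise). Drugs are drawn from a bundled library of 54 hand-checked valid
SMILES spanning rings, halogens, bracket atoms, charges and ring-closure
classes; each drug gets one target pathway and a potency offset
~N(0, 1).

Responses follow

    y = 2.5 + offset_drug − 1.0 · feature_expr(cell, target pathway) + N(0, 0.5²),

where the feature is the *computed* Mann–Whitney pathway feature — so
the entire feature pipeline sits on the causal path, and end-to-end
learnability genuinely tests it. Classifier labels are Bernoulli draws
from a logistic transform of −y. The stored truth (active sets,
targets, offsets, noise draws) regenerates every response exactly.

What the generator does *not* emulate: real expression marginals and
gene–gene correlation beyond pathway blocks, mutation hotspots,
arm-level copy-number structure, drug-class structure in chemical
space, or assay noise models. Passing tests therefore demonstrate that
the pipeline recovers the kind of pathway-mediated signal it is built
for, not performance on any real pharmacogenomic dataset.

## Study problem sizes

The end-to-end study (used by `scripts/acceptance.py` and the
integration tests) runs on the generator defaults (6,000 cell-line–drug
pairs, expression features only) with a reduced-width model chosen for
the synthetic scale: embedding/conv channels 8, attention dim 32, 2
heads, feed-forward 32, MLP (64, 32), sequence length 32 (the bundled
library tokenizes to at most 26 positions), batch size 256, learning
rate 2e-3, at most 30 epochs with patience 5 (10 epochs for the
label-shuffled null, which has nothing to learn). Transformer depth
stays at 4.

## Known limitations

* The numpy engine is single-threaded and float64; it is sized for the
  synthetic study, not for hundreds of thousands of pairs at sequence
  length 256.
* The exact Mann–Whitney branch assumes tie-free data; heavily tied
  expression values always route to the asymptotic branch.
* Pathway features treat gene sets as flat memberships; no topology,
  no gene-identifier mapping, and no multiple-testing correction (the
  p-values are features, not inferences).
* With overlapping gene sets, planted signals bleed between pathways;
  attention-based target recovery is evaluated against a top-20%
  criterion rather than exact rank-1 identification for this reason.
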