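# Methods

This note records the modeling assumptions, the numerical choices, and what
the synthetic-data experiments do and do not demonstrate.

## Problem setting

A drug-combination screen measures a Loewe-additivity synergy score for a
(drug₁, drug₂, cell line) triple, possibly with replicates. The package
predicts that score and, jointly, a three-class label obtained by
thresholding it: antagonistic (score < 0), additive (0 ≤ score ≤ 30),
synergistic (score > 30). The boundary values 0 and 30 fall in the additive
class — the outer classes are defined by strict inequalities, so the closed
middle interval is the only consistent completion. Training is three-class
(dropping additive rows would also drop their regression targets), while
threshold metrics are reported on the antagonistic-vs-synergistic subset
with P(synergistic) as the ranking score, matching how imbalanced synergy
screens are conventionally evaluated. Which subset published accuracies use
is not always stated; ours is documented here, not asserted as anyone
else's.

## Molecular graph views

Molecules are parsed with rdkit; nodes are heavy atoms in parser order,
hydrogens stay implicit, and aromatic bonds keep their own label (no
kekulization). "All paths" on a cyclic graph is unbounded, so all
path-based views use *simple* paths (no repeated node) capped at
`max_edges = 6` — about the diameter of a typical drug-like ring system;
the cap is shared with the brute-force oracle used in tests. Zero-edge
self-paths are excluded: after SMILES parsing a molecular graph has no
self-loop edges, and a 0-edge path carries no bond information for the
bond-label view.

Each undirected path is counted once. A view keys a path by the
lexicographic minimum of its label sequence and the reverse (bond labels
for view II, atom labels for view IV), which is what makes the counts
invariant under label-preserving node permutations; canonicalizing by a
single fixed direction would let a relabeling flip the key. View III uses
BFS shortest-path lengths over unordered node pairs within a component.

Vector encoding is corpus-level: keys are ranked by total corpus count
(ties lexicographic) and the top `dim` keys get positions; unseen keys are
dropped. Atom-symbol codes for view I come from a corpus-level dictionary
in first-occurrence order starting at 1, and the code sequence is
zero-padded/truncated to its view dimension. Per-view lengths default to
(64, 128, 32, 128); tests and the acceptance run use (16, 32, 16, 32),
which already covers every key the ~50-molecule bank produces.

## Feature normalization

All feature families pass through the bounded tanh map
`z = 0.5·(tanh(c·(x−μ)/σ) + 1)` with per-column mean and population SD from
*training rows only* (σ←1 for constant columns). `fit_normalizer` defaults
to the classic tanh-estimator constant c = 0.01. Trained pipelines default
to c = 1.0: with c = 0.01 every value lands in (0.4975, 0.5025) and a
network trained for a CPU-scale number of epochs cannot recover the signal
(held-out predictions collapse to the training mean); c = 1 keeps the same
bounded (0,1) map while staying near-linear over ±2 SD. Descriptor cleaning
(drop any column with a non-numeric or missing entry, then any
zero-variance column) precedes normalization and is likewise fitted on
training rows.

## Neural blocks

The layers run on a minimal reverse-mode autodiff core (`multisyn.autograd`,
float64 numpy; Glorot-uniform init; AdamW with decoupled weight decay).
Everything is deterministic given the seed, which is what makes the
bitwise-reproducibility tests possible.

*Attention.* Flat feature vectors are reshaped into `d / token_dim` tokens
(`token_dim` 16 by default, 8 in tiny configurations): a softmax over a
single token is degenerate, so some token layout is required. Query, key
and value use separate rectified dense projections per head (a `share_qkv`
flag collapses them to one, the literal reading of a shared projection);
per-head width is `token_dim / heads` so the concatenated head outputs
match the input size. No `1/√d` softmax temperature by default — the
attention definition used here has none — with a `scaled_attention` flag
for comparison. The softmax runs over key tokens for each query token.

*Cross-stitch.* Both 2×2 mixing matrices initialize near identity
(diagonal 0.9, off-diagonal 0.1), the standard choice that starts tasks
mostly independent and lets training learn the coupling. The per-task dense
width between the two units defaults to the input length. The regression
head consumes the first cross-stitch output and the classification head the
second; the assignment is a convention, exposed in code rather than deduced.

*FC stacks.* ReLU after every layer; dropout 0.2 after all but the last
layer, active only in training; L2 penalties on weights (1e-4) and
activations (1e-5) are added to the loss. The regularization coefficients
are unpublished; these defaults are small enough not to dominate the task
losses at tiny scale.

## DDI pretraining

The interaction classifier uses two parallel branches with separate
parameters (interaction roles need not be symmetric), a post-concatenation
stack of [512, 256] (tests use smaller) and a K-way softmax head, trained
with a stratified 9:1 split (falling back to a random split, with a
warning, when a class has fewer than two members). Interaction features
default to the penultimate layer of the post-concatenation stack — the
layer that has already mixed both drugs — with a `ddi_penultimate="branch"`
switch selecting the concatenated branch outputs instead. Inside the
synergy model those features are tanh-normalized (statistics from fold-train
pairs) and re-encoded before the cell-line attention.

## Multi-task training

Total loss = MSE(score) + cross-entropy(3-class) + penalties, with equal
task weights by default (exposed in `ModelConfig`); nothing suggests an
asymmetric weighting, and the planted-signal experiments converge with the
unweighted sum. The two drug slots share branch parameters, consistent with
reversed-pair augmentation; the fusion concatenation itself is
order-sensitive, which the augmentation teaches the network to ignore.
Regression targets are z-scored with training-fold statistics and mapped
back at prediction (`standardize_target`, on by default): it equalizes the
initial magnitudes of the two task losses, and every reported ratio-type
quantity is invariant to it.

Published-scale training (1000 epochs, lr 1e-5, weight decay 0.025, batch
64) remains the `ModelConfig` default. `ModelConfig.tiny()` — used by the
tests, the examples and the acceptance script — shrinks every width, uses
lr 1e-3 / weight decay 1e-4 and 200 epochs, sized for minutes-scale
single-CPU runs.

## Cross-validation protocol

Replicates are averaged per unordered (pair, cell) key; labels are assigned
from the averaged score; every record then gets a drug-swapped twin
(exactly 2n rows, a provenance flag guards against double augmentation).
Fold grouping entities — unordered pair, cell line, first drug, second
drug — are shuffled with the seed and dealt round-robin into five folds, so
sizes differ by at most one entity and no entity spans folds; under the
pair scheme a record and its twin share the unordered-pair key and hence the
fold. The first/second-drug schemes group by the column as given after
augmentation, which is the order-sensitive reading of "unique first drugs".
All featurization statistics, vocabularies and target statistics are
re-fitted per fold on training rows.

Across-fold aggregation uses the Student-t interval
`mean ± t₀.₉₇₅,ₙ₋₁·sd/√n` with sample SD. This choice is verifiable: it
reproduces the printed interval endpoints of the published leave-out tables
from their printed mean ± SD to within 0.05 (a normal-quantile interval
does not).

## Synthetic data

`generate_world(seed)` emulates the four external inputs: a drug table
drawn from a curated bank of ~50 valid drug-like SMILES (no random-SMILES
generator — it risks invalid chemistry); a descriptor matrix with planted
non-numeric, missing-value and zero-variance columns; an expression matrix
whose landmark panel intersects it in exactly 875 of 1000 genes; a DDI
table whose class is the argmax of K linear scores on the concatenated
descriptors, emitting only pairs at least `ddi_margin = 2` from the nearest
class boundary so the planted classes are separable and learnable; and a
replicated synergy table with additive structure
`score = 10 + a(d₁) + a(d₂) + b(cell) + 2·I(pair) + ε`,
a, b ~ N(0, 10²), I ~ N(0, 1), ε ~ N(0, 5²). Defaults: 20 drugs, 10 cells,
1200 genes, 6 DDI classes, 600 synergy rows with 30 % replicated — these
scales put all three label regimes in the data and keep a full fold's
training under a minute.

What passing these experiments shows: the implementation can extract a
planted additive signal from molecular/expression features under the full
featurization, attention, cross-stitch and multi-task machinery, with
leakage-free fold handling. What it does not show: performance on real
screens — the generator has no dose–response structure, no tissue effects,
no descriptor–activity relationships beyond identity memorization, and its
drug-effect scale is far simpler than real pharmacology.

## Known limitations

* No GPU path and no minibatch parallelism; the autodiff core is float64
  numpy, sized for the synthetic scale, not for a 23k-sample screen at
  published widths.
* Graph views are 2-D topological; stereochemistry and conformers are out
  of scope.
* An atom symbol absent from the training corpus raises at featurization
  (no unknown-atom bucket); with the bundled SMILES bank this does not
  occur.
* The Mordred descriptor computation is treated as an upstream step; the
  package consumes descriptor CSVs and ships only the synthetic generator.
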