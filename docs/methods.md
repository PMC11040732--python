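# Methods

## Model

A compound–protein pair is scored by composable featurization toolkits
feeding a shared architecture.  The compound side builds (i) a heavy-atom
molecular graph whose vertices and edges carry discrete *r-radius
subgraph* identifiers and (ii) a whole-molecule descriptor vector; the
protein side builds (iii) overlapping n-gram word indices, (iv) a
smoothed, logistically scaled PSSM, and (v) a per-residue structural
energy representation.  Embedding tables for subgraph ids and words are
trained by backpropagation together with all network weights.

**Subgraph identifiers.** Vertex labels start as atom-type codes
(symbol, aromatic flag, total H count, formal charge) and are refined
for r rounds: each vertex is relabeled by the hash of (own label, sorted
multiset of (incident-edge label, neighbor label)), each edge by (bond
type, unordered endpoint labels).  Graph-isomorphic r-neighborhoods
therefore share one identifier; at r = 0 the identifiers are exactly the
atom-type partition.  Identifiers are interned in a per-experiment
dictionary grown on training molecules and frozen afterwards; unseen
identifiers at inference map to a reserved unknown id (0), since the
embeddings form a closed, learned vocabulary.  The same
grown-then-frozen scheme applies to the n-gram vocabulary, with
nonstandard residues (B, Z, X, U, O) masked to the unknown word by
default ("strict" raises instead).

**Encoders.** The GNN alternates simultaneous vertex and edge updates
(vertex ← ReLU(W(v + Σ incident edges)), edge ← ReLU(W(e + endpoint
sum))) for `layers_gnn` rounds.  The CNNs are stacks of
length-preserving (zero-padded) 1-D convolutions with ReLU; PSSM rows
are first projected 20 → dim.  The descriptor vector (top-10 columns by
extra-trees importance, invariant/non-finite columns removed, fit on
training folds only, standardized) passes a dense ReLU stack and enters
the compound attention as one extra position.  Energy records are
z-scored per cell against the wild-type relaxed ensemble (zero-deviation
cells map to 0, making the statistic shift-invariant), zero-padded to
the training maximum length, PCA-reduced to k = 32 components (basis
fitted on training records), projected to dim, and concatenated with the
attended sequence representation *after* attention — the sequence- and
structure-based vectors are then joined by a single dense layer.

**Attention and pairwise interaction.** Per-position scores are
ReLU(w·h + b); softmax turns them into convex pooling weights (they sum
to one, and a set of identical positions pools to that vector).  The raw
scores are retained for interpretation.  The pairwise module projects
both sides through single dense+ReLU layers and scores every pair
through a sigmoid; the head input concatenates both pooled vectors with
four order-invariant summaries of the pairwise matrix (mean row-max,
overall mean, mean column-max, overall max), keeping a hot-pair signal
at fixed length.  Heads are small MLPs: a scalar for regression, softmax
probabilities for classification.  The loss is MSE or cross-entropy plus
λ‖Θ‖² over every parameter including embedding tables.

## Training protocol

Datasets are shuffled and split into five folds; every data-dependent
fitted component (fingerprint dictionary, word vocabulary, descriptor
selection and scaling, PCA basis) is fitted on the training folds only.
The held-out fold is split 50/50 into a validation half — which selects
the epoch with minimal validation r.m.s.e. — and a test half that
produces reported metrics; cross-validation reports per-fold and mean
results.  Optimization is Adam at learning rate 1e-3 with **per-sample
updates** (batch size 1).  Per-sample updates are the convention in this
family of CPI models and matter at small dataset sizes: with a few
hundred pairs, large batches give so few optimizer steps within a
30-epoch budget that the network stays in a lazy regime — predictions
can ride on random initial embeddings while the attention never
localizes.  Regression targets are standardized to zero mean and unit
variance on the training fold and predictions mapped back, so the
default learning rate is insensitive to the label scale.

Numerical choices: the logistic scaling clamps outputs to the nearest
representable doubles inside (0, 1) (the function saturates beyond
|x| ≈ 37 in double precision); PSSM smoothing uses zero padding at the
sequence ends, preserving length and linearity; the attention scoring
vector initializes at zero with bias +1 so scores start uniform and in
the active ReLU regime (inputs are post-ReLU, so a centered random init
with zero bias would start with every score dead at exactly 0);
embedding tables initialize uniform ±1/√dim; dense layers uniform
±1/√fan-in; all randomness derives from the config seed, making runs
bit-reproducible.

Label preprocessing schemes mirror common dataset conventions:
`percentage` (identity), `log2`, `log10`, `cutoff:θ` (binary), and
`multiclass` with supplied bounds (default: zero → class 0, tertiles of
the nonzero values → classes 1–3).

## Interpretation

Attention profiles rescale raw scores min–max to [0, 1]; word-level
scores are redistributed uniformly over the n residues each word covers
and averaged per residue (PSSM positions map one-to-one).  Constant
profiles are emitted all-zero with an explicit `flat` flag rather than
as rescaled noise.  Residues above 0.5 are protein hotspots; atoms above
0.7 are high-attention subgroups with the argmax atom as the peak; both
thresholds are conventions on the rescaled scale and ranking-level
conclusions do not depend on them.  Profiles export as TSV and
optionally as a PDB copy with weight×100 in the B-factor column (an
explicit residue mapping reconciles numbering offsets).  The decoy
contrast scores paired substrate lists (with / without a functional
group) against one fixed protein and reports means, their difference
and a one-sided rank-sum p-value.

## Synthetic studies

The generator emulates every input format the pipeline reads — FASTA,
SMILES lists, PSI-BLAST ASCII PSSMs, energy tables with a wild-type
ensemble, a pairs TSV — with a planted, recoverable signal: a fixed
8-residue motif (CWHWKEYR) inserted at recorded positions into half of
the proteins, a phosphate-like group (OP(=O)(O)O) appended to half of
the compound scaffolds, and labels 10 + 50·(motif·group) + N(0, 1).
Defaults are 200 pairs drawn from 20 proteins (length 50–80) × 20
compounds; PSSM columns are boosted and energy terms shifted at motif
positions so every toolkit carries signal.  The same seed reproduces
every emitted byte.

What the synthetic study does *not* emulate: evolutionary covariance in
real PSSMs, realistic activity distributions, chemically diverse
scaffolds, or sequence homology between proteins.  Passing the
planted-signal tests therefore demonstrates that the architecture,
training loop and attention interpretation can recover a known
localized determinant at small scale — not that the model matches
benchmark accuracy on curated experimental datasets, which require
externally curated inputs out of scope here.  For the identifiability
check the point-biserial (Pearson) correlation between labels and the
planted indicator is used; a rank correlation against a binary
indicator is bounded near 0.87 even under perfect separation and cannot
certify identifiability.

## Problem sizes and defaults

dim = 10, r = 2, n = 3, w = 21, three layers per encoder, CNN kernel 3,
λ = 1e-6, Adam lr 1e-3, 30 epochs, k = 10 descriptors, k = 32 energy
components.  The validation experiments train M1 on the 200-pair study
for 30 epochs over three seeds (about 20 s per run on one CPU).  Known
limitations: the pairwise-summary reduction and the word→residue
redistribution are one defensible reading each of an under-specified
design; regression uses MSE (the natural counterpart of r.m.s.e.-based
model selection) even where classification uses cross-entropy; the
Python-level per-sample training loop does not scale to datasets of
~10^4+ pairs without batching or a compiled backend.
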