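# Methods

## Problem and model

The task is multilabel, hierarchical classification posed as generation:
map a SMILES string to one or more 5-character ATC codes covering the first
four levels of the WHO hierarchy (letter, two digits, letter, letter).  Two
encoder–decoder architectures are provided.

**BiLSTM.** The encoder runs one LSTM over the token sequence in each
direction; the final forward and backward hidden and cell states are
concatenated and passed through linear "bridge" layers with tanh to form
the decoder's initial hidden and cell state.  The bridged state is also
re-fed to the decoder as input context at every step, concatenated with the
target-token embedding.  This second path is a deliberate design choice:
with the initial state as the only channel, optimization at desk scale is
brittle — roughly half of the random seeds stall on a plateau where the
decoder reproduces the marginal character distributions and ignores the
encoder entirely.  Re-feeding the state removes the bottleneck without
changing what the decoder may see (only the fused encoder summary).

**Transformer.** Standard pre-norm encoder and decoder blocks (multi-head
self-attention, causal masking in the decoder, cross-attention to the
encoder memory, sinusoidal positions), sized small (d_model 64, 2 heads,
1 layer each by default).

**Multimodal fusion.** A standardized molecular-descriptor vector can be
fused with the encoded SMILES: for the BiLSTM it is concatenated to the
combined final encoder state before the bridge layers; for the Transformer
it is concatenated to *every* encoder memory position and projected back to
the model dimension (per-position fusion; a pooled alternative would
collapse the memory).  Downstream decoding is identical to the unimodal
case, so unimodal and multimodal checkpoints are interchangeable at the
interface.

**Training.** Each (SMILES, code) pair is one example — a compound with m
codes contributes m pairs.  Token-level cross-entropy with teacher forcing
and padding masked, Adam (default lr 1e-2 for the BiLSTM, 3e-3 for the
Transformer, batch 32, dropout 0.1, global-norm gradient clipping at 5),
early stopping on validation loss (patience 20) with best-epoch restore.
All parameters sit in a small reverse-mode autodiff core (`atcgen.nn`)
whose gradients are verified against finite differences in the test suite.

**Generation.** Beam search over full-sequence log-probabilities, no length
normalization (targets are near-constant length).  Up to k distinct
finished sequences are returned, ranked by total log-probability; sequences
end at the end token or at `max_len` generated tokens.  Decoding is
unconstrained: a generated string that violates the ATC pattern is kept and
simply scores as incorrect — silently dropping malformed outputs would
overstate precision.

## Meta-model

The number of codes to emit is itself predicted.  For each training
compound the generator produces its 10 best candidates; the label is the
smallest k in 1..10 maximizing exact-match F1 of the top-k set (smallest-k
tie-break, favouring precision).  The feature vector is the ten candidate
log-probabilities, sorted, padded with a −1e9 sentinel when fewer than ten
candidates exist.  Log-probabilities (not probabilities) are used; a flag
is not needed because the monotone transform does not change the classifier
family.  Inside the classifier the features are clipped at −50 — turning
the sentinel into a finite "no candidate" level — and standardized with
training statistics; the candidate mass itself is never renormalized.  The
classifier is a two-layer (one hidden layer, width 32, tanh) 10-way
network trained with cross-entropy under Adam.

## Evaluation metrics

Exact metrics are example-based: per compound, precision |Ŷ∩Y|/|Ŷ| (0 when
nothing was predicted), recall |Ŷ∩Y|/|Y|, F1 their harmonic mean, averaged
over compounds (mean-of-F1; an F1-of-means flag exists).  The level-wise
L-Precision/L-Recall score level n only over the cohort Cⁿ⁻¹ of compounds
with at least one prediction correct through level n−1, and within a
compound only over codes correct through level n−1, so an early mistake is
penalized once.  Correctness at level n is level-n prefix equality (prefix
lengths 1, 3, 4, 5).  Levels whose cohort is empty are reported as missing,
never as zero, and are excluded from cross-seed averaging denominators.

One consequence worth stating: because the cohort Cⁿ⁻¹ *grows* as more
candidates are generated, mean L-Recall at levels ≥ 2 is **not** monotone
in the candidate count k — a compound that newly enters the cohort can
enter below the cohort's mean.  Only exact recall and level-1 L-Recall
carry an unconditional monotonicity guarantee, and the test suite asserts
exactly those.  The implementation is cross-checked against brute-force
enumerators that quantify over every (prediction, actual, level) triple.

## Data preparation

Standardization removes monatomic charged fragments (counterions),
neutralizes remaining charges where chemically valid (RDKit MolStandardize)
and canonicalizes; one toolkit's canonical dialect is used uniformly so
string equality is a valid merge key.  Filtering drops records lacking
SMILES or codes, multicomponent structures (a `.` surviving
standardization), compounds above 900 Da *when a weight is recorded*, and
ATC codes in the first-level "V" group unless the level-4 prefix is exactly
`V03AX`; a compound survives iff codes remain.  Descriptors are RDKit's
1D/2D set (≈210 per molecule); pruning removes all-missing and constant
columns and then greedily, in column order, any column with |Pearson r| >
0.95 against an already-kept column (keep-first order makes the result
deterministic; the threshold is a common cheminformatics default).
Missing cells are imputed with the training-rows median, then each column
is z-scored with training-rows statistics (zero variance scales by 1).

## Splits and experiments

*New-drug*: compounds are partitioned 80/10/10 (defaults), stratified on
the single- vs multi-code indicator with largest-remainder apportionment,
so every partition matches the global multi-code fraction to within integer
granularity; no canonical SMILES crosses partitions.  *Repurposing*: every
single-code compound's code goes to the training side; each multi-code
compound's codes are shuffled and split ⌈m/2⌉-to-train, the remainder
becoming that compound's test annotation; validation compounds (10% by
default) are drawn out of the training list with the same stratification.
Experiments repeat over a seed list (10 by default), sweep the generated
count k, score every (model, k) cell with both metric families and report
cross-seed mean and standard deviation; aggregation is recomputed from the
stored per-seed reports, so it can be audited.

## Synthetic fixtures

The generator emulates the statistical shape of the task, not chemistry:
random strings over a 12-symbol alphabet (lengths 8–30, desk-scale stand-in
for tokenized SMILES), codes derived deterministically from string motifs,
a label-count distribution of (0.70, 0.20, 0.07, 0.03) over 1–4 codes
(most compounds one code, a minority several), optional label noise, and
16 descriptor features (normalized character counts plus Gaussian noise,
σ = 0.1 by default).  Motif design: the level-1 letter is a function of the
first character, levels 2–3 are capped counts of marker characters
(accumulative evidence, the regime recurrent encoders handle well), level 4
reads the final character.  With `descriptor_only_signal` the level-4
letter is instead driven by a latent ±1 factor observable only in
descriptor feature 0 — by construction a string-only model cannot beat
chance there, which is what isolates the multimodal advantage in tests.
What passing these fixtures does *not* show: robustness to real SMILES
syntax, to the long-tailed ATC label distribution, or to annotation
incompleteness in real databases.

## Problem sizes and numerical choices

Test and acceptance runs use n = 350–500 compounds, embedding 32 / hidden
64, beam width ≤ 10 — sizes chosen so a full verification pass stays in the
minutes range on one CPU while every qualitative property (learnability,
multimodal advantage, meta dominance) is still resolved.  Ties in beam
search are broken by token order for determinism; all RNG flows from
explicit integer seeds (numpy `default_rng`); softmax/log-softmax are
max-shifted; attention masks are additive −1e9; the forget-gate bias is
initialized to 1.

## Known limitations

* The NN core is CPU/numpy; wall-clock scales roughly linearly in tokens ×
  parameters, so it is meant for small and mid-sized corpora, not
  GPU-scale training.
* Hierarchical grammar is not enforced at decoding time; the generator can
  emit strings that are not valid codes (they score as wrong).
* Tautomer/stereochemistry reconciliation across sources is out of scope;
  merging relies solely on one canonical SMILES dialect.
* The hierarchical classifier baselines one-hot-encode previous-level
  choices and sample level 2 as a single two-digit unit; unseen prefixes at
  sampling time fall back to marginal level distributions.
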