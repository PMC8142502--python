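# Methods

This note records the models, conventions and design choices behind
`mooncop`, in the order data flows through the toolkit.

## Sequence model and input handling

All descriptors are defined on the 20-letter amino-acid alphabet
`ACDEFGHIKLMNPQRSTVWY`. Input sequences are case-folded and
whitespace-stripped; non-canonical characters are handled by an explicit
policy because silent coercion would change descriptor values
invisibly. The default policy (`map_x`) applies the conventional
ambiguity substitutions (B→N, Z→Q, U→C, O→K, J→L) and maps X and
anything else to alanine; `drop` removes such characters; `strict`
rejects them with the position named. `strict` exists for auditing —
`map_x` is the default because it keeps every protein usable by every
descriptor.

FASTA ids are the header token up to the first whitespace (matching
UniProt-style headers); the remainder is retained as a description.
Feature matrices, prediction logs and reports are tab-separated text
with the protein id as first column; writes refuse non-finite values
rather than storing NaN/inf that would corrupt cross-validation
downstream.

## Descriptors

**Composition family.** `aac` is residue frequency in fixed alphabetical
order. `aak_part_composition` (default k=3) splits the sequence into k
contiguous near-equal parts — the first `len mod k` parts take one extra
residue, a deterministic, order-preserving convention — and concatenates
part compositions. `saac` (nt=ct=5 by default) concatenates the
compositions of the N-terminal segment, middle, and C-terminal segment;
with the default 8-group reduced alphabet this is SGAAC (3×8=24).
`kmer_composition` (k=3) and `cks_pair` (gap=1) count overlapping
windows and gapped ordered pairs, normalized by the number of windows,
in lexicographic feature order. All composition blocks are non-negative
and sum to 1.

**DDE.** For each ordered dipeptide (i, j) the observed frequency
`Dc = N_ij/(L−1)` is standardized against the codon-usage expectation:
`Tm = (C_i/C_N)(C_j/C_N)` with the standard-code synonymous-codon counts
(C_N = 61), `Tv = Tm(1−Tm)/(L−1)`, and `DDE = (Dc − Tm)/√Tv`. The
grouped variant sums member codon counts per group.

**CTD.** Seven physicochemical properties (hydrophobicity, normalized
van der Waals volume, polarity, polarizability, charge, secondary
structure, solvent accessibility), each partitioning the 20 residues
into 3 classes using the standard three-class groupings of the
discriminative protein-folding feature literature. Composition is the
class fraction (21 values); transition counts adjacent unordered class
switches over L−1 (21); distribution reports the positions — as percent
of L — of the 1st, 25%, 50%, 75% and 100% occurrences of each class
(105). The percentile occurrence index is `max(1, round(q·n_c))` with
round-half-away-from-zero, so a 10-occurrence class yields positions
1, 3, 5, 8, 10. Absent classes contribute five zeros.

**Sequence order.** `socnumber` computes coupling numbers
`τ_d = Σ_i d(s_i, s_{i+d})²` for lags 1..30 over two bundled residue
distance matrices (length 2×30). `qsorder` (nlag=5, w=0.1) normalizes
residue counts and weighted coupling numbers jointly:
`Z = Σ_r f_r + w Σ_d τ_d`, features `f_r/Z` then `w·τ_d/Z` per matrix
block, each block summing to 1. Both defaults are fixed by the published
vector lengths (60 and 50).

**Distance matrices.** The Grantham (1974) amino-acid difference matrix
is bundled verbatim. The second matrix conventionally used by this
descriptor family (Schneider–Wrede) is not redistributable here, so the
bundled `schneider_wrede_synthetic.tsv` is a reconstruction in the same
spirit: the Euclidean distance over z-scored Kyte–Doolittle hydropathy,
Hopp–Woods hydrophilicity and residue volume, scaled to a maximum of 1.
It satisfies the same contract (symmetric, zero diagonal, finite) and is
clearly labelled synthetic; only length contracts and formula semantics
are guaranteed, not numeric equality with other extraction packages.

**Grouped alphabet.** Grouped descriptor variants need g=8 (forced by
the published lengths 24 = 3×8, 64 = 8², 512 = 8³). The bundled default
is the Murphy 8-letter reduction (LVIMC / AG / ST / P / FYW / EDNQ / KR
/ H); group membership affects values, never lengths, and other bundled
alphabets (2, 4, 5, 10, 15, 20 letters) can be substituted per call.

**Reduced k-tuple family.** One engine — map to a reduced alphabet,
count overlapping k-tuples — parameterized per published type. Types
with printed length 16 use g=4, k=2; length 256 implies g=4, k=4;
length 625 cannot be g² for any real amino-acid clustering (g ≤ 20) and
is read as g=5, k=4. The per-type cluster tables of the original
extraction package are not published in reusable form; the bundled
defaults assign the documented Murphy-4 and 5-letter alphabets per type,
which preserves every length contract.

**Autocorrelation.** Moreau–Broto, Moran and Geary statistics of
property-encoded sequences, for 8 bundled residue scales (hydropathy,
hydrophilicity, volume, mass, charge, aromaticity, polarity,
isoelectric point), z-scored over the 20 residues. The default
3 kinds × 8 properties × 19 lags = 456 matches the published length;
constant encodings (zero variance up to round-off, detected with a
relative threshold) define Moran and Geary as 0 rather than NaN.

## Evaluation protocol

The bench reserves a stratified 20% holdout (total test size
round-half-up of 0.2·n — 70 of 351 — apportioned over classes by
largest remainder) and runs R=100 repeats of stratified 10-fold CV on
the training portion. Stratification is used for both the holdout and
the folds to protect the minority class in small datasets. One
`FoldPlan` (all R×K assignments, identified by a SHA-256 checksum that
is stamped into every report row) is shared by all descriptor × model
cells.

Per repeat, validation predictions are pooled into one confusion matrix
and the metric set computed from it; reported values are means over
repeats. (Averaging per-fold metrics instead is possible via
`compute_metrics` on per-fold counts, but pooling is the default: with
~28 validation samples per fold, per-fold precision/recall are unstable
and their average biased.)

Metrics: accuracy, precision, recall and F-measure from the confusion
counts; MCC with the convention 0 when any denominator factor is 0
(likewise precision/recall on empty denominators); AUC as the
rank-based Mann–Whitney statistic over positive-class scores, ties
counted ½. Positive-class scores come from `predict_proba` where
available, otherwise the decision margin (SVM).

Classifier families and hyperparameters: RBF SVM (C=1), KNN (k=5,
Euclidean), Gaussian NB (features are real-valued compositions),
Gini decision tree (max depth 3, min 5 samples per split — "min-sample"
read as the split minimum), random forest (50 trees), AdaBoost (200
weak learners), MLP (hidden layers 20 and 3, SGD, ≤150 iterations),
regularized logistic regression (defaults). Z-score standardization,
fitted on training folds only via a Pipeline, is ON by default for the
scale-sensitive families (SVM, MLP, KNN, LR) and OFF for
tree/ensemble/NB; the flag is recorded per run.

All randomness derives from one master seed through a hashed
counter scheme (`derive_seed(master, stream, index)`, 31-bit outputs):
holdout, per-repeat fold shuffles, per-fit model seeds and bootstrap
draws each use a distinct stream, so any stage is reproducible in
isolation.

## Outlier detection

With a full CV log (exactly R validation predictions per protein), the
tally counts misclassified repeats. The COP rule is inclusive by
default — `count ≥ threshold`, threshold 90 of 100 — with a strict
`count > threshold` variant available, since both readings appear in
practice. COP detection runs on the full labelled dataset by default (a
flag restricts it to the training portion). COP sets from several
cells combine by exact intersection (default) or union. Reports carry
the class composition of the COP set and F.M., the fraction
misclassified in every repeat; empty COP sets report explicit nulls
rather than NaN.

`remove_and_reevaluate` reruns the whole CV protocol on the original
and the COP-removed dataset with fresh fold plans under the same seed
scheme, and refuses removals that leave a class smaller than the fold
count. `score_candidates` refits the classifier R times on bootstrap
resamples of the training set (resampling is what makes the repeats
informative for deterministic families; it can be disabled, in which
case all repeats coincide) and reports each candidate's mean and
standard deviation of predicted MP probability.

## Synthetic data

The generator emulates two compositional sequence classes: i.i.d.
residue draws from a uniform baseline tilted by ±δ on a fixed half of
the alphabet (MP-enriched set `ACDEFGHIKL`), with doubled enrichment in
the first and last five residues so split-composition descriptors carry
signal distinct from global composition. Lengths are uniform on
40–100 (minimum 31, the strictest descriptor precondition). A fraction
of records per class is drawn from the opposite class's distribution
under the nominal label; these label-flips are the ground-truth
outliers.

The default δ=0.20 was chosen so the reference configuration — 100 per
class, 10% flips, Gaussian NB on SAAC, 100×10-fold CV — operates near
0.85 mean CV accuracy, the regime where outlier detection is genuinely
tested. At that operating point the injected flips are recovered with
sensitivity ≥ 0.9 in typical draws, while the clean-protein false-flag
rate is draw-dependent (roughly 0.03–0.10 across dataset seeds):
borderline clean proteins that happen to sit across the class boundary
are consistently misclassified, which is precisely the behaviour the
COP definition targets.

What passing tests on this generator do **not** show: real moonlighting
biology has domain structure, homology clusters and organism-specific
composition that i.i.d. draws cannot emulate, and real label noise is
not symmetric class swapping. The generator validates the machinery —
counting, thresholding, fold bookkeeping, recovery under a known
ground truth — not biological performance claims.

## Problem sizes and runtime

The test suite and acceptance script use the reference sizes
throughout: 200 proteins, R=100 for detection, R=20–25 for
re-evaluation and null calibration. These run in seconds on one CPU;
the full published-scale grid (37 descriptors × 8 models × 100×10-fold)
is hours of compute and is reached through `mooncop run`'s cached
pipeline or `scripts/reproduce_study.py` instead.

## Known limitations

- Descriptor values are guaranteed to match their defining formulas,
  not the numeric output of any particular extraction package (group
  memberships, cluster tables and the reconstructed distance matrix
  differ in exactly the ways documented above).
- The CV engine is single-process; the shared fold plan makes parallel
  execution across cells trivial but it is not built in.
- `score_candidates` bootstrap variability reflects training-set
  sampling only, not descriptor or model uncertainty.
- PSSM/evolutionary features, composite "interest feature" vectors and
  expected-value descriptor variants are out of scope, as is redundancy
  reduction (inputs are assumed pre-deduplicated).
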