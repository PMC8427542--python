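# Methods

## Problem and model

`phagelift` treats phage lifestyle assignment as per-fragment binary
classification: given one DNA sequence (a read or contig), output the
probability that it derives from a virulent (strictly lytic) rather than a
temperate (lysogeny-capable) phage. The signal exploited is compositional:
temperate phage genomes spend long periods integrated in host chromosomes
and ameliorate toward host sequence signatures, so virulent and temperate
fragments differ in local k-mer/motif statistics even when they share no
genes.

The classifier is an eight-layer 1D CNN over the one-hot encoded sequence:
Conv1D (F=64 kernels of width M=6, ReLU) → max-pooling (size S1=3, stride
S2=3) → batch normalisation → dropout (P=0.3) → global average pooling →
dense (R=64, ReLU) → batch normalisation → dense (1, sigmoid). The
convolutional kernels act as position weight matrices (soft motif
detectors); global average pooling turns per-position motif responses into
a length-invariant occupancy profile, which is why one architecture works
across a 4.5× range of fragment lengths within a stratum. Training uses
Adam (learning rate 1e-4), binary cross-entropy, and batch size 32; these
five architecture constants and three optimiser settings are the published
operating point and are exposed as estimator parameters but not re-tuned
here.

One model is trained per fragment-length stratum (A: 100–400, B: 400–800,
C: 800–1200, D: 1200–1800 bp), with the model input length L equal to the
stratum's upper bound. Fragments shorter than L are zero-padded on the 3'
side; padding rows are all-zero and contribute nothing to any kernel
response (they do shift the post-BN baseline in the padded region, which is
shared between training and prediction and therefore consistent).

### Conventions the layer equations leave open

* **Convolution padding.** The conv output is defined for l = 0…L−1 with
  terms X[l+m]; we zero-pad on the right so the output length equals L.
* **Pooling remainder.** None of 400/800/1200/1800 is divisible by 3 after
  windowing; an incomplete trailing window is dropped, giving pooled length
  ⌊L/S2⌋ (for the default S1 = S2).
* **Dropout** uses the inverted convention (kept activations scaled by
  1/(1−P) at train time); inference is the identity, so prediction is
  deterministic.
* **Batch normalisation** uses batch statistics during training and running
  statistics (momentum 0.99, epsilon 1e-3) at inference, so a sequence's
  score cannot depend on batch composition.
* **Initialisation** is Glorot-uniform, seeded; biases start at zero.
* **Score exactly 0.5** is labelled "uncertain" at every cut-off, including
  t = 0: the decision rule is defined by strict inequalities and we never
  silently coerce the undefined case.
* **Strandedness.** Sequences are scored on the given strand; no
  reverse-complement averaging or canonicalisation is applied.
* **Epoch budget.** The published protocol fixes optimiser, loss, and batch
  size but not epochs; we default to max 100 epochs with early stopping
  (patience 10) on the validation loss of a genome-disjoint split of 10% of
  the training genomes, and restore the best-epoch weights.

### Ablation variants

The estimator builds five reduced architectures alongside the full one:
`kmer4` (4-mer frequency vector, dimension 256, straight into the dense
head), `no_maxpool`, `no_dropout`, `no_globalpool` (global pooling replaced
by flattening), and `no_bn` (both BN layers removed). All share the same
training loop, so variant comparisons differ only in architecture.

## Implementation

The network — forward pass, backpropagation through every layer (including
batch-norm train-mode statistics and max-pool gradient routing), and the
Adam optimiser — is implemented in numpy in float32, with the convolution
expressed as an im2col matrix product. Max-pool gradients flow to the first
position attaining each window maximum. The production forward pass is
checked against an independent, deliberately naive nested-loop
implementation of every layer equation (tests), to 1e-5 at all four input
lengths; backpropagation is checked against central-difference numerical
gradients away from ReLU kinks.

Standard steps go through established libraries: FASTA parsing conventions
follow Biopython-style semantics, fold construction uses scikit-learn's
stratified splitter, AUC is scikit-learn's (equal to the tie-aware
Mann-Whitney normalisation, cross-checked against a pairwise-concordance
enumeration in tests), and the large-sample rank-sum path uses scipy.

## Synthetic study conditions

The generator emulates the two-class compositional divergence with order-1
nucleotide Markov chains. The virulent chain is a fixed, mildly AT-leaning
transition matrix; the temperate chain mixes each virulent row 85:15 with a
GC-biased row ([0.10, 0.40, 0.40, 0.10] over A,C,G,T), emulating
amelioration toward GC-richer host chromosomes. The canonical corpus is 20
genomes of 50 kb per class. Fragment extraction draws lengths uniformly
within a stratum and start positions uniformly along the genome, with no
sequencing-error model — the corpus represents error-free assembled
contigs.

What the synthetic data does *not* emulate: mosaic genome structure and
horizontally exchanged modules shared between lifestyles, shared phage gene
content, genome-specific composition heterogeneity beyond the class chain,
within-class diversity of real phage taxa, and read errors. Passing the
synthetic recovery tests therefore demonstrates that the mechanism works —
the network recovers a known compositional difference through the full
simulate→train→route→evaluate pipeline without genome leakage — not that
real-data accuracies are reproduced; the published full-scale benchmark
requires the curated genome accessions and is out of scope here.

Cross-validation is stratified by lifestyle at the genome level (the
curated corpus is class-imbalanced, and stratification prevents degenerate
folds); automatically-labelled genomes, when present, are training-only.
Class balance in fragment corpora is enforced at sampling time (±1
fragment), not by loss weighting.

### Problem sizes

Desk-scale defaults are 8,000 training / 2,000 test fragments per stratum
(one tenth of the full-scale 80,000/20,000 design), overridable everywhere.
The recovery experiment in the acceptance suite uses 2-fold genome-level CV
on group D with 4,000/1,000 fragments and at most 8 epochs; the
length-trend check uses 2,000/500 fragments and 6 epochs for groups A and
D over three seeds. These sizes were chosen once as the smallest corpus at
which the class signal is comfortably recovered (held-out accuracy ≈0.99
for group D, ≈0.80 for group A under the canonical divergence).

## Cohort comparison

Each sample's prediction report reduces to the proportion of classified
contigs called temperate (uncertain calls excluded; undefined when no
contig is classified). Proportions are per contig by default — the
alternative, weighting by contig length, is exposed as an option since
either reading of "proportion of temperate phage DNA" is defensible. Two
sample groups are compared with a two-sided Wilcoxon rank-sum test: an
exact, tie-aware permutation null (all C(n1+n2, n1) assignments over
midranks, doubled smaller tail) for groups of at most 12 samples each,
otherwise the tie-corrected normal approximation with continuity
correction. The location difference is the Hodges–Lehmann estimate (median
of pairwise differences) with a 95% confidence interval from the order
statistics of the pairwise differences, using the exact Mann–Whitney
quantile for small groups and the normal quantile otherwise.

## Known limitations

* The classifier assumes its input *is* phage-derived; host/eukaryotic
  contigs should be filtered upstream, and bacterial sequences will tend to
  be called temperate (they resemble host-ameliorated composition).
* Scores for fragments near stratum boundaries come from different models;
  small score discontinuities across the 400/800/1200/1800 bp boundaries
  are expected.
* The numpy training loop is single-threaded CPU code; it is sized for
  desk-scale corpora, not for full-scale training runs.
* The exact rank-sum path enumerates combinations and is exponential in
  group size; it is capped at 12 samples per group.
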