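# phagelift

Alignment-free classification of **phage lifestyle** — virulent (strictly
lytic) versus temperate (lysogeny-capable) — for individual DNA fragments
from metagenomes and viromes.

Knowing whether the phages in a community sample are virulent or temperate
matters for microbiome ecology and disease studies (e.g. tracking prophage
induction in the gut), but most fragments in shotgun data come from phages
with no cultured representative and no marker genes. `phagelift` classifies
each contig or read directly from its nucleotide sequence: virulent and
temperate phage genomes carry different compositional signatures (temperate
genomes ameliorate toward their hosts' chromosomes), and a small
convolutional network can read those signatures from a single fragment.

Intended users are bioinformaticians analysing virome / metagenome
assemblies who need a per-contig lifestyle call, and methods researchers who
want a fully reproducible, dependency-light reference implementation of the
model (the network is implemented in numpy, forward and backward).

## The model

A fragment is one-hot encoded (A→[0,0,0,1], C→[0,0,1,0], G→[0,1,0,0],
T→[1,0,0,0]; ambiguity codes are all-zero rows) into an L×4 matrix **X** and
scored by an eight-layer network

```
Conv1D(F=64 kernels, width M=6, ReLU)      Y^C[l,f] = ReLU(Σ_{m,n} W^f[m,n] X[l+m,n] + b^C_f)
→ MaxPool1D(size S1=3, stride S2=3)        Y^M[l,f] = max(Y^C[lS2..lS2+S1-1, f])
→ BatchNorm (BN1)
→ Dropout(P=0.3)                           train-time only
→ GlobalAvgPool                            y^G_f = mean_l Y[l,f]
→ Dense1(R=64, ReLU) → BatchNorm (BN2)
→ Dense2(1, sigmoid)                       y ∈ (0,1) = P(virulent)
```

trained with Adam (learning rate 1e-4), binary cross-entropy, batch size 32.
Four models are trained, one per fragment-length stratum — A: 100–400 bp,
B: 400–800 bp, C: 800–1200 bp, D: 1200–1800 bp — each with input length L
equal to the stratum's upper bound (shorter fragments are 3'-zero-padded).
At prediction time a sequence is routed to its stratum's model; sequences
under 100 bp use the group-A model; sequences over 1800 bp are split into
non-overlapping 1800-bp pieces whose scores are combined by a
length-weighted average. Scores above 0.5 are called virulent, below 0.5
temperate, and an optional cut-off *t* labels scores inside
(0.5 − t/2, 0.5 + t/2) "uncertain".

Evaluation uses sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP),
accuracy Acc = (TP+TN)/total (virulent = positive), AUC, and *genome-level*
cross-validation: folds are partitioned by source genome so no genome ever
contributes fragments to both training and test sets. A built-in synthetic
generator (two order-1 Markov chains whose transition rows differ by a
GC-biased admixture) produces labelled genome corpora so the whole pipeline
is testable without downloading any accession. A cohort module compares
per-sample temperate proportions between two groups of samples with an
exact two-sided Wilcoxon rank-sum test and a Hodges–Lehmann shift estimate.

## Worked example

```sh
# 1. build a synthetic labelled corpus (no downloads needed)
phagelift simulate --out-dir corpus --n-genomes 6 --genome-length 8000 \
    --groups A,D --n-fragments 60 --seed 1

# 2. train a model per length group
phagelift train \
    --fragments A=corpus/fragments_A.fasta:corpus/fragments_A.tsv \
    --fragments D=corpus/fragments_D.fasta:corpus/fragments_D.tsv \
    --out-dir models --max-epochs 20 --seed 1

# 3. classify new sequences
phagelift predict --in corpus/fragments_A.fasta --out report.tsv \
    --models models --cutoff 0.5
```

`predict` prints a summary such as

```
{"virulent": 0, "temperate": 0, "uncertain": 60, "total": 60}
```

(here all 60 calls fall in the uncertain band — with `--cutoff 0.5` any
score in (0.25, 0.75) is withheld; an under-trained toy model scores near
0.5) and writes one row per input sequence:

```
id                  length  score   label
temperate_g0|A|0    241     0.5278  uncertain
temperate_g0|A|1    253     0.5297  uncertain
```

`score` is P(virulent); `label` applies the cut-off policy. The same
pipeline is available from Python through the sklearn-style estimators:

```python
from phagelift import CNNFragmentClassifier
clf = CNNFragmentClassifier(input_length=1800, random_state=0)
clf.fit(train_fragments, train_labels, groups=genome_ids)
scores = clf.decision_function(test_fragments)   # P(virulent) per fragment
```

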