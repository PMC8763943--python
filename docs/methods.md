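# Methods

## Overview

`metafuse` classifies host phenotype (e.g. disease vs. healthy) from shotgun
metagenome data by combining three feature modalities in a late-fusion
neural architecture:

1. **Taxonomic composition** — relative abundances of clades at one rank
   (phylum … species), taken from per-sample profiler output.
2. **Genome-level abundance** — RPKM of non-redundant representative
   contigs assembled from a random subset of training samples ("reference
   samples"), with a breadth-of-coverage presence filter. This modality
   captures strain- or genome-fragment-level signal, including unannotated
   taxa, that rank-level composition cannot.
3. **Functional abundance** — RPKM of KEGG orthologs (KOs) matched by the
   sample's reads in a protein search.

Each modality is fed to its own fully connected feedforward encoder; the
activations of the encoder's last hidden layer are its embedded
representation. The embeddings are concatenated into a shared
representation and a second, smaller network performs the final
classification. Training is two-stage: encoders are fitted first against
the class labels, then frozen while the fusion network is fitted on the
concatenated embeddings (an end-to-end fine-tune is deliberately not the
default; the frozen-encoder contract is part of the tested API).

## Feature generation

### Preprocessing

Reads are sliding-window quality-trimmed at Phred 20 over 10-base windows.
The trim points are found by scanning for the outermost windows whose mean
quality reaches the threshold and stepping to the first base at or above
the threshold inside them, so a uniformly low-quality flank is removed
entirely; reads shorter than one window afterwards are rejected. Note that
an ends-only trimmer cannot guarantee that *every* interior window of a
surviving read passes (a read may have good ends and a bad middle); the
tested guarantee is that the surviving read's terminal windows pass. Reads
containing any N are dropped. Against a host-genome alignment, a mapped
read is classified as host contamination when its mismatch count is under
10% and its soft-clipped length under 30% of the read length, both strict
inequalities — a read exactly at a boundary is kept. For paired data a
pair survives only if both mates do.

### Taxonomic features

The feature space at a rank is the union of clade names observed across
samples, zero-filled where absent. Genus- and species-level columns present
(nonzero) in at most one sample are removed as likely sample-specific; the
filter is idempotent and is applied at other ranks only on request. All
abundance matrices entering a network are transformed as
`log10(x + 1e-6)`; the pseudocount maps exact zeros to −6 and is
configurable. Base 10 and the 1e-6 pseudocount are package choices (only
"log-transform" is specified by the approach this implements).

### Genomic features

Contigs strictly longer than 5000 bp are kept; within each bin the longest
contig (ties: lexicographically smallest id) is the bin's non-redundant
representative; unbinned contigs are excluded. For sample *i* and
representative contig *j*:

    RPKM(i, j) = mapped_reads(i, j) × 10³ × 10⁶ / (total_reads(i) × length(j))
    Coverage(i, j) = covered_bases(i, j) / length(j)

`mapped_reads` counts distinct primary-alignment reads (mates counted
individually, duplicates not removed); `covered_bases` is the size of the
union of aligned reference intervals (CIGAR M/=/X/D ops). Cells with
coverage below 0.70 are set to 0 before the log transform — a fragment so
sparsely covered is treated as absent, and the downstream network needs a
dense matrix. The boundary is kept (coverage = 0.70 exactly retains the
RPKM), reading "under 70%" strictly. `total_reads` is the post-preprocessing
read count by default. Within cross-validation, reference samples are drawn
from the training fold only.

### Functional features

Protein-search hits are kept at percent identity ≥ 50, query coverage ≥ 50
and e-value ≤ 1e-10 (inclusive cutoffs; "cutoff = X" conventionally
includes X). Query coverage is computed from qstart/qend against a
query-length table because the standard 12-column tabular format lacks it.
Each read is assigned a single best KO by highest bit score, ties broken by
lowest e-value then lexicographic KO id. Per-(sample, KO) read counts are
converted to RPKM normalized by KO gene length; only KOs matched by at
least one read anywhere in the dataset become columns. Features are kept at
the KO level by default (a KO→category roll-up is a thin aggregation the
user can apply to the matrix).

## Model

All networks are dense feedforward nets: ReLU hidden layers, softmax
output (two output nodes for binary problems), categorical cross-entropy,
Adam with learning rate 0.001, β₁ = 0.9, β₂ = 0.999. Default hidden
architectures: 200-100-50 for the taxonomic and genomic encoders,
500-100-50 for the (wider) functional encoder, 50-25 for the fusion
network; the embedding dimension is therefore 50 per modality and the
fusion input is 150 for three modalities.

Defaults the approach leaves open, chosen here: **epochs = 50**,
**batch_size = 16**, He-normal initialization, no early stopping, no
dropout or weight decay. Fifty epochs were chosen because at the data
scales this package targets (tens to hundreds of samples, 10²–10⁴
features) training loss plateaus well before then — the separable-data
checks reach training accuracy 1.0 and the permutation controls stay at
chance — and the LOOCV suite halves in wall time relative to longer
schedules. The implementation is plain numpy in float64; with a fixed seed
(weight init and minibatch order draw from generators spawned from it)
training is bit-reproducible on a single CPU.

## Evaluation

Leave-one-out cross-validation holds each sample out of *everything* that
is fitted: the prevalence filter and the feature-space union are recomputed
on the training fold and the held-out sample is projected onto the fold's
columns (absent features 0); encoders and fusion are trained per fold. This
is stricter than generating features once globally — both modes exist
(pass raw matrices for strict per-fold processing, pre-transformed matrices
for global mode), strict being the default, because global feature
generation lets the held-out sample influence column selection. Accuracy,
precision and recall follow the usual confusion-matrix ratios with the
positive class = the disease label (undefined denominators are reported as
`None`, not 0). LOOCV is repeated (default 5 runs) over derived seeds and
averaged; the matrices argument may be a callable `seed -> matrices` so
each run can rebuild features (e.g. redraw reference samples). ROC
thresholds are the midpoints between consecutive distinct scores plus
sentinels beyond the extremes; AUC is the trapezoid area and equals the
normalized Mann–Whitney U statistic, which the tests verify. A majority
voting combiner over multiple classifiers is provided (ties: highest mean
probability, then first label in sorted order).

## Synthetic data

The generator produces every input the pipeline consumes, so all stages
are testable offline.

* **Feature-level**: class-conditional Gaussians on the log scale;
  informative features are shifted between classes by `effect_size` ×
  within-class SD; values are exponentiated (base 10) so they behave like
  raw abundances and the pipeline's log transform approximately recovers
  the Gaussians. The default study condition — 2 × 30 samples, three
  modalities of 100 features with 10 informative at a 2σ shift — is the
  scale at which recovery (mean 5-run LOOCV accuracy ≥ 0.9) is asserted.
* **Sequence-level** (`small` preset: 20 samples, 30 bins, 2,500 reads of
  100 bp per sample): random DNA contigs of 5.5–9 kb grouped into bins;
  per-class contig abundances from a Dirichlet prior (concentration 5)
  with a few contigs made class-exclusive (zero abundance in the other
  class, weight boosted 3×) to plant a recoverable signal; reads are drawn
  multinomially, placed uniformly, and written as error-free end-to-end
  SAM alignments (an optional substitution-error mode exists). Ground-truth
  per-(sample, contig) read counts and covered bases are recorded during
  generation, which is what makes the cell-for-cell bookkeeping check
  exact. Clade profiles use a small fabricated taxonomy with
  class-tilted Dirichlet proportions; KO hit tables pass the filter
  thresholds by construction, with a fraction of below-threshold decoy
  hits (some with higher bit scores) that the filter must remove.
* **Complementary preset**: samples are split, stratified by class, into
  as many disjoint subsets as modalities; modality *m* carries a 5σ class
  shift only for subset *m*. A single modality can resolve at most its own
  third of the samples, so fused LOOCV accuracy exceeding the best single
  modality demonstrates that the concatenated embeddings genuinely combine
  signals.

What the synthetic data does **not** emulate: sequencing error profiles,
real taxonomies and genome structure, compositional coupling between
modalities, batch effects, and class imbalance. Passing tests show the
pipeline arithmetic, leakage protocol, and fusion mechanics are correct —
not that any particular real-data accuracy is attainable.

## Numerical and degenerate-input choices

* Matrix TSV round-trip writes values with `repr`, so read∘write is exact.
* SAM coordinates convert to 0-based half-open on read; mismatch counts
  prefer NM (minus indel lengths) over MD; a mapped read with neither is an
  error rather than a silent zero.
* Prediction ties at equal softmax probability go to the first class in
  sorted label order (argmax-first semantics).
* Degenerate metrics (empty confusion, single-class ROC, one-class
  training) raise or flag rather than return a default.
* All derived seeds come from `numpy.random.SeedSequence` spawning and stay
  below 2³¹.

## Known limitations

* LOOCV retrains every network per fold; at hundreds of samples this is
  minutes of CPU, and no warm-start is attempted (by design — warm starts
  would leak across folds).
* The host-decontamination and quality-trimming stage approximates the
  common windowed-trimmer behaviour but is not a byte-for-byte clone of any
  specific trimming tool.
* Single-label binary/multiclass only; no multi-label or survival targets.
* The per-run reference-sample redraw is exposed at the API level
  (callable matrix factory) but the sequence-level pipeline must be driven
  by the caller to rebuild matrices per run.
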