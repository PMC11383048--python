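# Methods

## Problem setting

Illumina bead-array genotyping summarizes each sample×SNP observation as a
normalized total intensity R and an allelic-intensity ratio θ ∈ [0, 1],
plus a per-SNP cluster-quality statistic (GenTrain score) and the
production Gencall genotype in {AA, AB, BB, NC}. Genotypes are calls on
the array's A/B probe alleles; mapping AA/AB/BB to reference/alternate
dosage therefore needs one extra bit per SNP — whether probe allele A is
the reference allele — carried here as the `a_is_ref` field. When the
column is absent it defaults to True with a logged warning, and
concordance results should be treated as allele-convention-unverified.

## The genotyping network

Inputs are (snpID, R, θ). The snpID passes through an embedding table
(default dimension 50); the embedded vector is concatenated with (R, θ)
and fed through two dense hidden layers (defaults 64 and 160 units, both
rectified) to a 3-unit softmax output over the fixed class order
(AA, AB, BB). Both hidden layers use the rectifier; softmax appears only
on the output, which must be a 3-class probability simplex.

The loss is categorical focal cross-entropy,
`L = -α (1 - p_t)^γ log p_t`, with p_t the probability assigned to the
true class, clipped to [1e-7, 1 − 1e-7] before the log. Defaults γ = 2,
α = 0.25 (the conventional defaults of this loss); γ = 0, α = 1 recovers
plain cross-entropy, a property the tests exercise. The optimizer is Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-7, bias-corrected) at learning rate 1e-4,
batch size 512, for at most 11 epochs, with early stopping after
`patience` (default 5) consecutive epochs without validation-loss
improvement and restoration of the best-validation weights. Patience 0
stops at the first epoch the validation loss fails to improve.

The network, backpropagation, and Adam are implemented directly in numpy:
the model is small (tens of thousands of parameters) and trains on ~10⁵
records in seconds on one CPU, and a plain-array implementation keeps
training bit-reproducible under a fixed seed. Initialization is
Glorot-uniform for dense layers and uniform(−0.05, 0.05) for the
embedding. The default learning rate and epoch budget are sized for
panels of roughly 10⁵ training records; on much smaller sets (10³ or
fewer records there are too few optimizer steps at lr 1e-4), raise the
learning rate or epoch count — the package's own small-fixture tests use
lr 0.01 for this reason.

Unseen snpIDs at prediction time are refused (excluded with a logged
count) rather than mapped to an out-of-vocabulary embedding: the
embedding is per-SNP by design, and an untrained row carries no
information. Argmax ties break toward the fixed class order AA < AB < BB.
NC is never a predicted class; every prediction carries its max
probability so a downstream confidence threshold can be applied. A
simple grid search over the two hidden-layer sizes (32…160 step 32, 25
pairs, reduced epochs, ties broken toward fewer parameters) stands in for
a full hyperparameter-tuning framework.

## Preprocessing and splitting

Records missing any of {GenTrain, R, θ, genotype} are dropped; NC records
are partitioned out for later prediction. Valid records are split
90/5/5 into train/validation/test by record (sample×SNP observation), not
by sample or SNP — the same sample may appear in train and test at
different SNPs, which matches how the per-SNP totals of such experiments
are usually quoted, but means the split must not be read as a
sample-level generalization test. The 90/5/5 default is configurable
(an 80/10/10 convention also circulates). SNP vocabularies are built from
sorted distinct snpIDs so encoding is deterministic.

## Concordance and selective trust

Array calls are matched to reference callsets (imputed, WGS) by exact
sample ID and exact variant key (chromosome, position, ref, alt — no
strand or allele flipping; a ref/alt swap is reported as "allele
mismatch", not matched). Genotypes compare as discrete alt-allele dosages
0/1/2; PLINK `.raw` inputs must be hard calls — a fractional dosage is a
format error, since rounding policy belongs to the producer. NC array
calls and missing reference dosages are excluded from all denominators
(exclusion is the only well-defined choice). Per SNP and technology the
rate is concordant/matched, reported as missing (never 0) when no calls
matched; the summary rate counts a call concordant if it equals any
available reference. A SNP is high-performing when every *available*
technology rate is ≥ 0.90 — an absent technology does not veto, but a SNP
with no rates at all is not high-performing. Per-SNP denominators are
per-technology (a sample missing in one technology still counts in the
other); this convention is a documented choice. Recovered no-calls
concordant with ≥ 1 reference raise the per-SNP call rate to
(original_calls + recovered)/total, which is monotone and capped at 1.

The GenTrain-vs-concordance relationship is summarized by a Pearson
correlation against the imputed-technology rate specifically. Group
comparisons (e.g. QC-included vs QC-excluded SNPs) use a two-sided
Mann-Whitney U test implemented in-package: midranks for ties, full
enumeration of label assignments when both groups have ≤ 8 members,
otherwise the tie-corrected normal approximation (no continuity
correction); scipy's implementation serves as an independent cross-check
in the tests, never as the implementation. Reported p-values are raw;
`included/excluded` status labels are consumed from a user-supplied file,
and multiple-testing correction is left to the caller.

## Cluster-geometry QC

Given any trusted genotype labelling (imputed genotypes in the intended
use), each class's centroid (mean θ, mean R) and width (RMS Euclidean
distance to the centroid; per-axis standard deviations available behind a
switch) are computed per SNP. Flags: `too_wide` (any width > w_max),
`centroids_too_close` (any pairwise centroid separation in θ < d_min;
θ-only because θ is the allelic axis — joint (θ, R) distance is a config
option), `low_r_centroid` (lowest centroid R < r_min), and
`insufficient_data` (every present class below n_min points; never an
exclusion by itself). Defaults w_max = 0.10, d_min = 0.10, r_min = 0.20,
n_min = 3 follow the geometry of a clean SNP (homozygote centroids near
θ = 0 and 1, cluster spreads well under 0.1); they are exposed as
configuration, and the QC tests rely on planted-truth simulations rather
than these particular numbers. Flags are monotone in their thresholds.

## The synthetic-data generator

The generator emulates the study conditions end to end: 11 ancestry
strata × 44 samples (484 samples) by default; per SNP a minor-allele
frequency ~ U(0.05, 0.5) and Hardy–Weinberg genotype proportions; θ
centroids 0.05/0.50/0.95 for AA/AB/BB with per-SNP jitter (sd 0.01) and
Gaussian noise (sd 0.03); R per class from a gamma distribution with
mean 1 and shape 200 (sd ≈ 0.07 — tight, intensity-stable clusters
consistent with the QC width defaults above; class means configurable).
An optional per-stratum θ offset emulates ancestry/batch structure and is
off by default. The GenTrain-like score is a noisy decreasing function of
cluster overlap, 1 − exp(−z/6) with z the minimum centroid separation in
noise-sd units, clipped to [0, 1].

No-calls fire record-wise with weights 1 + 4·logistic((d − 0.06)/0.02) +
4·[R < 0.4], where d is the θ-distance to the nearest centroid —
no-calls concentrate on ambiguous and low-intensity points — normalized
per SNP so the marginal no-call rate equals `nc_probability` (default
0.03, matching a few-percent NC rate typical of array data). A
configurable fraction of SNPs is planted as non-clustering: all three
genotypes draw θ from one N(0.5, 0.15) cloud, the failure mode the QC
flags must detect. Field-level missingness blanks one of the four
required metrics fields in a configurable fraction of records (default
0.01). Reference callsets start from the planted truth and flip each
dosage, with the technology's error rate, to a uniformly random different
dosage, so planted error equals expected discordance exactly; sample and
variant overlap with the array are thinned to configurable fractions.

What the generator does **not** model: linkage disequilibrium, real
genome positions or probe chemistry, ancestry-specific allele
frequencies, fractional imputed dosages, or genotype-dependent intensity
artifacts (e.g. the deleted-allele low-R signature). Passing tests
therefore demonstrate the machinery is correct under clean cluster
assumptions, not that the network resolves the pathological loci real
arrays produce — on real data the selective-trust step (concordance
thresholds, QC flags) is what guards against those.

## Numerical and design notes

- Softmax is computed with max-subtraction; p_t clipping (1e-7) prevents
  log-domain errors in the loss and its gradient.
- Splits, training, simulation, and the CLI are deterministic under their
  seeds (numpy `default_rng` throughout; the training shuffle stream is
  decoupled from weight initialization).
- Sizes of train/val/test match the requested fractions to within one
  record (rounding, remainder to test).
- Concordance denominators, rates, and report rows are invariant to
  record order; report rows sort by chromosome (natural order) then
  position.
- The model archive is a single `.npz` with a JSON metadata block
  (format-versioned); save → load → predict reproduces probabilities
  exactly.
- Plots strip writer/date metadata so identical inputs give identical
  image bytes.

## Benchmark sizes

The repository's tests and the acceptance script run entirely on
generated data, sized to finish quickly on one CPU: the headline
benchmark trains on a 200-SNP × 500-sample panel (~10⁵ records, seconds
of training), chosen as the smallest scale at which the production recipe
(lr 1e-4, 11 epochs, batch 512) is well inside its convergent regime;
statistical checks (Hardy–Weinberg recovery, planted error and no-call
rates) use 10⁴–10⁵ draws and 99% binomial/multinomial intervals.
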