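# Methods

## Feature representation

A candidate sORF is a pair (upstream flank, ORF), the ORF running from
its start codon through its stop codon. Sequences are restricted to
the unambiguous alphabet {A,C,G,T}; anything else is rejected at load
with a machine-readable reason, never silently repaired. Soft-masked
(lowercase) bases are uppercased.

**TIS context.** Positions are numbered so the start codon occupies
+1…+3 (there is no position 0). The TIS window spans −7…+5 with the
start codon excluded, i.e. the last 7 nt of the flank plus the 2 nt at
+4/+5 — 9 nt in total. This is the only reading that reconciles a
−7…+5 range, start-codon exclusion, and a 36-element encoding.
Each position is one-hot encoded with the maximal-Hamming-distance
code A=0001, C=0010, T=0100, G=1000; within each 4-bit group the slot
order is (G,T,C,A) so the printed codes read off left to right. The
encoding is validated against an independent per-position code-table
concatenation oracle.

**Coding composition.** The CC window is an in-frame substring of the
ORF body starting at offset 3 (after the start codon), or 93 when the
signal-peptide skip is enabled (3 + 90 nt). 3-mers are counted
non-overlapping at step 3, ordered lexicographically AAA…TTT, and the
window never overlaps the stop codon — stop codons are a trivially
label-leaking 3-class signal, so "until the stop codon" is implemented
exclusive. For prediction-only records that lack a stop codon the
window may extend to the sequence end. Window sizes are 54, 99 and
180 nt; automatic selection takes the longest that fits. Records whose
post-start body is shorter than 54 nt (<19 aa of usable body) cannot be
scored and are excluded with a report entry.

The signal-peptide skip defaults ON in the training pipelines and OFF
in the predictor, applied symmetrically to both classes; both are
single-flag overrides.

**Scaling of the combined vector.** The public feature API reports CC
as frequencies (counts divided by window/3, summing to 1). The model
pipelines, however, consume the CC block as raw in-frame counts.
Within a fixed-window model the two differ only by the constant
window/3, so the information content is identical — but the choice
matters numerically: against 0/1 one-hot TIS bits, frequency-scaled CC
elements (~1/60) contribute ~10⁻⁴ of each squared distance under an
isotropic RBF kernel, and the combined model degenerates to a TIS-only
model. Counts share the O(1) scale of the TIS bits, letting one kernel
weigh both families; with them the combined (CP) models dominate both
single-family models at every window size, which is the expected
behavior of the unified representation. `frequency_normalized` on
`FeatureConfig` selects either mode explicitly, and each trained model
stores the configuration it was fitted with, so prediction always
reuses the training-time scaling.

## Training, calibration and prediction

Labels are noncoding=0, coding=1. Hyper-parameters are chosen by
exhaustive search over a declared grid with stratified 10-fold
cross-validation on the training split; the winner maximizes mean CV
accuracy, with ties broken by lower CV variance and then lexicographic
parameter order, so selection is reproducible. Default grids: SVM
kernel ∈ {linear, rbf}, C ∈ {0.1,1,10,100}, gamma ∈ {scale,0.01,0.1,1};
k-NN neighbors ∈ {3,5,11,21} × weights {uniform, distance}; RF trees ∈
{100,300,500} × criterion {gini, entropy} × max-features {sqrt, log2}.
The end-to-end harness and the acceptance script use a compact RBF-only
grid (C ∈ {1,10}, gamma ∈ {scale, 0.1}) — on the synthetic study data
the CV surface is flat enough that the compact grid selects equivalent
models at a fraction of the cost, and the RBF-SVM is the algorithm the
comparison suite is built around (on strongly signaled data it leads
the random forest, which leads k-NN).

Platt calibration fits `P(coding|d) = 1/(1+exp(A·d+B))` to the
validation-split decision values via logistic regression (lbfgs, weak
regularization C=10⁶). For SVMs `d` is the signed margin; for k-NN/RF
it is the positive-class probability, in either case monotone in coding
evidence, so calibration never reorders examples. Constant decision
values are a degenerate-input error. Train/validation/test
disjointness is enforced mechanically: every model stores SHA-256
fingerprints of its training records (flank|ORF content), and both
calibration and evaluation refuse inputs that intersect them.

Prediction routes each record to the model of the longest window it
supports *among the models supplied*, assembles features under that
model's stored configuration, and applies the strictly-greater-than
threshold rule: a score exactly equal to the threshold is called
non-coding. Default threshold 0.5; 0.9 is the high-precision mode for
imbalanced settings.

Models persist as single joblib archives with a format-version field, a
metadata block (algorithm, hyper-parameters, feature configuration,
Platt parameters, fingerprints) and the fitted estimator; version
mismatches are explicit errors.

## Dataset construction from a genome

Coordinates are 0-based half-open internally; GFF3's 1-based closed
convention is converted at the boundary (involutively). Intergenic
space is the per-contig complement of the merged gene intervals, minus
a 2,000-nt promoter mask immediately upstream of each gene (upstream in
gene orientation — before the start of + genes, after the end of −
genes). Intervals of 20–50 kb (closed) form the negative training
pool; intervals >50 kb form the simulated-evaluation pool, disjoint by
construction. Negatives are ATG-anchored pseudo-ORFs on the + strand
of pooled intervals, each extended to its first in-frame stop, filtered
to length bounds (default 60–450 nt), and sampled without replacement
under a fixed seed; the flank is the genomic sequence immediately
upstream of the ATG, truncated at the interval edge. The achieved mean
length is always reported: over near-uniform synthetic sequence it
settles near 120 nt (stop-codon waiting time ~20 codons), and real
genomes with different composition will differ, which is why the bounds
are configuration rather than constants to trust. Positive sets built
from a CDS FASTA + isoform table put single-isoform genes in training
and, for multi-isoform genes, only the longest isoform (ties to the
lexicographically smallest id) in the simulated set, keeping the two
disjoint by gene.

Stratified splitting floor-allocates the validation and test fractions
per label and gives remainders to training: 16,200 balanced examples at
60/20/20 yield exactly 9,720/3,240/3,240 with the class ratio preserved.

## What the synthetic generator emulates

Coding records: flank drawn from the background composition except the
9 TIS positions, which follow a Kozak-like profile (consensus weight
0.6 at each informative position: gcc**GCCACC**·atg·**GC**, purine at
−3, G at +4); body codons i.i.d. from a human-like codon-usage table
(embedded as a synthetic default, approximate by design); a uniform
stop codon. Non-coding records: ATG-anchored i.i.d. background
sequence extended to its first in-frame stop, rejection-sampled into
the length range, with a pure-background flank.

`signal_strength` mixes *both* the codon-usage table and the Kozak
profile with the background (s·model + (1−s)·background). At s=0 the
two classes' feature distributions are exchangeable — coding bodies are
uniform over sense codons, and a non-coding body conditioned on
reaching its length is exactly that too — so held-out accuracy sits in
the binomial chance band, which the test suite and acceptance script
verify. The default peptide length range, 61–99 aa, keeps every record
long enough for the 180-nt window under predictor-style (skip-off)
extraction while staying under the 100-aa sORF bound.

What the generator does **not** emulate: positional composition
structure within real ORFs (signal peptides, codon-usage ramps), GC
heterogeneity and repeats of real intergenic DNA, splice structure,
near-cognate starts, and any Ribo-Seq or conservation signal. Passing
the synthetic study therefore demonstrates that the pipeline recovers a
codon-usage + TIS contrast of realistic magnitude end to end — not a
performance claim for any particular genome.

Study sizes (chosen as the package's standard conditions): 1,000+1,000
records for the balanced study (test split 400), 1,000 vs 20,000 for
the imbalanced study, a three-stretch (10/30/60 kb) mini-genome for
interval logic. The 10,000-record distributional checks in the test
suite bound empirical codon frequencies within ±0.01 of the target
table.

## External-metric reports

FLOSS, ORFscore, PhyloP and PhastCons are consumed as pre-computed
columns of a tab-delimited sORF table; missing values are nulls and
leave denominators rather than counting as zero. Positivity cut-offs
ship as overridable configuration (FLOSS ≤ 0.28 — low disagreement
with the coding footprint-length profile is coding-like; ORFscore ≥ 6;
PhyloP ≥ 1; PhastCons ≥ 0.5). Reports: per-annotation-class positive
counts and percentages per metric (percentages always recompute from
their own counts), Venn-region counts over a 2–5 metric subset
(restricted to rows with values for every metric in the subset; regions
partition the positive-anywhere set), and confusion metrics treating
one annotation class as truth-positive and another as truth-negative
(default Ensembl-annotated sORFs vs intronic). Undefined ratios
(empty denominators) are reported as null.

## Known limitations

* Training and evaluation assume ATG starts; near-cognate starts are
  out of scope.
* Records shorter than 19 usable body codons cannot be scored at all —
  the smallest composition window is 54 nt.
* The synthetic negative model (i.i.d. background) is easier than real
  intergenic sequence with repeats and composition structure; absolute
  synthetic accuracies should not be read as genome-scale estimates.
* Pseudo-ORF sampling scans only the + strand of intergenic intervals
  by default.
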