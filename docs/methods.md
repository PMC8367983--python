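# Methods

## Scope and data model

`polyatails` operates strictly downstream of basecalling, mapping, and
signal-level tail estimation: its unit of input is one row of a Nanopolish
`polya` table — a read with a transcript assignment, a tail-length estimate
in adenosines, and a QC tag. Reads mapping to the reverse strand and
supplementary alignments are assumed removed upstream by the mapping
pipeline; ingest does not re-check coordinates and keys everything on the
transcript id. Only `PASS` estimates enter any statistic. All tabular
formats are plain TSV (UTF-8, tab-delimited only); annotation is BED6 with a
seventh biotype column, 0-based half-open.

## Summaries, pooling, and normalization

Per transcript and library we report the read count and the arithmetic mean,
median (mean-of-middle-two for even n), and geometric mean of tail lengths.
The geometric mean floors each tail at 0.01 A first so zero-length tails do
not annihilate it; 0.01 matches the pipeline-wide placeholder scale.
Replicates that correlate well are pooled at read level — counts add and tail
statistics are depth-weighted — rather than by averaging replicate summaries,
which would weight a shallow replicate equally with a deep one. (Averaging of
summaries remains possible by summarizing replicates separately.)

Transcripts seen by ≤ 5 reads are not removed but set to the 0.01 sentinel
for count and tail statistics alike, so they remain alignable across
libraries. The library total used for normalization is the sum of all mapped
PASS reads, computed *before* the placeholder substitution; this keeps
normalization independent of the detection filter. Normalized counts are
library fractions; the ×1,600,000 factor (roughly the largest library's
mapped-read count) is display-only. Expression bins are defined on
log2(library fraction): high ≥ −10, moderate-high (−12, −10), moderate-
minimal (−14, −12], minimal ≤ −14. As printed, the value −10 belongs to two
bins; we assign boundary values upward (−10 → high). The optional qPCR
coefficient is one multiplicative scalar per library, supplied in the sample
sheet, correcting strains whose poly(A)+ yield differs systematically; its
derivation from Ct values is out of scope.

## Annotation building

Sources are unioned; LTRs, transposons, tRNAs, and replication origins are
discarded; noncoding features shorter than 50 bp are dropped (unmappable at
DRS read lengths — mRNAs are exempt); overlapping same-strand noncoding
features are merged into one feature spanning the union, its id the
`|`-concatenation of constituents in coordinate order. When constituents of a
merged feature disagree on biotype the merged feature takes the first
constituent's biotype — coordinate order makes the choice deterministic, and
downstream analyses treat all noncoding classes identically apart from
reporting granularity.

## Oligoadenylation caller

Oligo-(dT) selection loses molecules with tails shorter than roughly the
capture midpoint (~10 A). A transcript with a substantial oligoadenylated
subpopulation therefore appears >1.2-fold more abundant in a total-RNA
library than in the matched poly(A)+ library *and* shows a decrease in mean
tail at least as large as the replicate-to-replicate noise of the mean-tail
estimate. That noise grows as expression falls, so one cutoff is computed per
expression bin: the sample SD of each transcript's per-replicate mean tails,
averaged over the transcripts of the bin (mean-of-SDs; a pooled
root-mean-square alternative is exposed as an option — with per-transcript
replicate counts of 2–3 the two differ little, and the mean is robust to a
few high-variance transcripts). Bin lookup uses the poly(A)+ library, the
reference fraction. The published four per-bin cutoffs
(1.727579/2.080906/2.763902/4.157491 A) are shipped as defaults so the rule
can be applied without replicate data; they are thresholds on the magnitude
of the decrease, equivalently on the signed delta being ≤ the negative
cutoff. A zero cutoff is rejected as degenerate input rather than silently
flagging every upregulated transcript.

## Substrate classification

For each mutant, Δtail is the per-transcript mean-tail difference against its
matched control, evaluated only on transcripts detected (non-placeholder) in
both libraries; abundance change is the log2 ratio of normalized counts. The
matched control is declared in the run configuration, never inferred, and any
library may serve as reference (e.g. a double mutant against a single
mutant). Transcripts with Δtail ≥ 10 A are confident substrates: wild-type
replicate comparisons keep mean-tail estimates within about ±10 A, so larger
elongations are unlikely to be artifacts. The exosome set and the union of
PAN2/3 and CCR4-NOT sets partition annotated mRNAs into exosome-only /
cytoplasmic-only / both / unaffected / undetected; percentages of substrates
are reported over both detected and annotated mRNAs. Noncoding biotypes are
excluded from this classification and summarized separately (tail means and
the per-class read load relative to protein-coding counts, in which annotated
but undetected loci count zero).

## Statistics

Kruskal–Wallis uses mid-ranks, the tie correction 1 − Σ(t³−t)/(N³−N), and a
χ²(k−1) p-value at any n (matching standard R behavior; exact small-sample
tables are not implemented). If all observations are tied the data carry no
ordering information and (H=0, p=1) is returned rather than an error. The
effect size is ranked epsilon squared, H·(n+1)/(n²−1). Dunn z-statistics use
the joint mid-ranks with the tie-adjusted variance
N(N+1)/12 − Σ(t³−t)/(12(N−1)); two-sided p-values from the standard normal
are Holm-adjusted within one comparison family (all pairs of one omnibus
test), untruncated before adjustment. Pairs are marked significant at
Holm-adjusted p ≤ 0.001. Pearson correlations are computed on the
intersection of transcripts measured in both inputs, with placeholder
sentinels excluded first — they are codes, not measurements.

## Synthetic data generator

The generator emulates the statistical structure of the study system, not its
sequences or signal:

* **Expression.** Per-transcript weights are 2^Normal(μ, σ) with σ = 2 by
  default, spanning roughly four orders of magnitude; library counts are
  multinomial over the weights. When no library size is given it is derived
  so the least-expressed transcript expects a configurable minimum read count
  (default 50), which pins the depth regime tests operate in.
* **Steady-state tails.** Mean tails interpolate linearly in log2 expression
  between 30 A (highest expression) and 55 A (lowest), reproducing the
  anticorrelation between expression and tail length; the functional form is
  a modeling choice, as only the pattern is observed. Within-transcript
  biological spread is Normal with SD 10 A — chosen as realistic for the
  breadth of per-transcript DRS tail distributions; no per-transcript SD is
  published.
* **De novo tails.** Export-blocked strains draw every tail from a
  Normal(50, tail_sd) truncated to [0, 200] — nuclear polyadenylation with
  its observed cap, before any deadenylation.
* **Mutant effects.** A strain's effect is an additive mean-tail shift and an
  abundance fold factor applied to a declared target set only.
* **Oligoadenylation and capture.** A configurable fraction of transcripts
  carries an oligo component: each read is, with probability `oligo_weight`,
  Uniform(0, 9) A. Poly(A)+ libraries retain each read with probability
  logistic((tail − 10)·steepness) evaluated on the noise-free tail (capture
  acts on the molecule, not the estimate); infinite steepness gives a hard
  step. No quantitative oligo-(dT) capture curve is published; the logistic
  form and steepness live in the config as explicit assumptions.
* **Measurement.** Estimates are the component tail plus Normal(0, 5 A)
  noise, floored at 0 (the signal-level estimator's error model is not
  published; additive Gaussian is the simplest adequate choice). A
  configurable fraction of reads receives a random non-PASS QC tag so the QC
  filter is exercised. Spike-ins emit reads at designed lengths 10–90 A.
* **Determinism.** Every sample file has its own RNG stream keyed by
  (seed, CRC32(sample id)); transcript-level layout uses a dedicated stream.
  Identical config + seed gives byte-identical files, and adding a sample
  never perturbs existing ones.

What the generator does *not* model: sequence content, squiggle-level signal,
isoform/3′-UTR structure, kinetic deadenylation dynamics, batch effects, or
transcript-specific capture biases beyond tail length. Passing recovery tests
therefore demonstrates that the analysis chain is correct and well calibrated
under the stated statistical assumptions, not that those assumptions exhaust
real DRS data.

## Validation study design

`scripts/acceptance.py` (and the mirror tests in `tests/test_acceptance.py`)
recomputes, at run time:

* the display-scale and placeholder constants by running single-transcript
  and 5-read libraries through the normalizer, and the bin and classifier
  thresholds (−10/−14, 1.2-fold, 10 A) by bisection on the decision
  functions themselves;
* substrate percentages from the published category counts
  (1643/625/1588 over 4665 detected and 6230 annotated mRNAs);
* maximal deviations of Kruskal–Wallis, Dunn, and Holm from independent
  implementations (scipy, a from-scratch rank computation, statsmodels) over
  120 random tied instances, plus the KW type-I error over 2000 null
  simulations of 3 groups × 30;
* planted-parameter recovery: a 3000-transcript experiment (≥ ~50 reads per
  transcript after QC, 5 A noise) for the global 40 A mean and a planted
  +12 A, 200-transcript target set; a 1000-transcript paired total/poly(A)+
  experiment (≥ ~200 reads, 10% oligo transcripts at weight 0.4) for the
  oligo caller;
* the spike-in round trip at 10–90 A, noise SD 2 A, 10,000 reads per length.

Problem sizes were chosen so the full study runs in well under a minute on a
single CPU while keeping Monte-Carlo error far below every tolerance used.

## Known limitations

* The chi-square approximation for Kruskal–Wallis is anti-conservative at
  very small group sizes; the validation exercises n ≥ ~30 per group.
* The oligo caller's per-bin cutoffs assume ≥ 2 replicates per transcript
  when computed from data; with exactly 2 the SD estimate itself is noisy and
  only its bin-level average is meaningful.
* Reproducing the original study's dataset-level numbers (global means per
  mutant, the 840 oligoadenylated mRNAs, the 1643/625/1588 category counts)
  requires the archived raw sequencing datasets; only the arithmetic
  downstream of such counts, the printed analysis constants, and the
  statistical machinery are validated here.
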