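# Methods

## Coordinate model

All coordinates are 0-based half-open (BED convention) on verbatim
chromosome names; declared 1-based inputs are converted once at
ingest. Gene anatomy is strand-aware: the TSS is the first transcribed
base (`start` on +, `end − 1` on −), the 3′ end the opposite terminus.
The promoter window spans 2,500 bp upstream to 1,000 bp downstream of
the TSS in transcription direction — `[tss−2500, tss+1000)` on +,
`[tss−1000, tss+2500)` on − — and is always 3,500 bp wide except where
truncated at position 0. The gene-body window runs from 2,500 bp
upstream of the TSS to the 3′ terminus. Because the − strand windows
are written directly in genomic coordinates rather than as the exact
mirror of the + rule, a genome reflection moves window edges by one
base pair; evidence landing exactly on a window boundary is the only
case where reflection symmetry of the flags can break.

## Spike-in differential ChIP

A constant mass of foreign-species chromatin added to every sample
before immunoprecipitation makes the spike-in peak counts a
treatment-invariant yardstick. Within each replicate batch, per-sample
size factors are the median-of-ratios estimator restricted to spike-in
peaks: factor_j = median over all-positive spike-in rows i of
k_ij / geometric-mean_i. This deliberately ignores the target-genome
peaks, so a genome-wide loss of the assayed mark (the expected outcome
of EZH2 inhibition for H3K27me3) changes fold changes, not the
normalization. After scaling, the per-batch log2 fold change is
log2((mean_treatment + c)/(mean_vehicle + c)) with pseudocount c = 1
normalized count, replicates within an arm/batch averaged first. Each
peak is tested with a two-sided one-sample t-test of its batch fold
changes against zero (df = n_batches − 1), BH-adjusted across peaks,
and called gain/loss at q < 0.05 by the sign of the mean fold change.
Peaks with pooled normalized mean below 5 are excluded from testing
(unstable fold changes); zero-variance fold-change vectors yield t = 0,
p = 1 when the mean is also zero and p = 0 flagged degenerate
otherwise. The q < 0.05 cutoff and the low-count filter are this
package's defaults; a df-3 t-test cannot produce p-values much below
10⁻⁴, so detection hinges on reproducible batch fold changes rather
than on extreme significance.

## Chromatin states

Chromosomes are tiled into fixed 200-bp bins. Binarization is either
peak-overlap (bin = 1 iff ≥ 1 bp of any peak of the mark overlaps) or
count-based: 1 iff the upper-tail Poisson probability P(X ≥ count)
under the mark's genome-wide mean rate is ≤ 10⁻⁴. The segmentation
model is a K-state HMM whose state k emits each mark m independently
with probability E[k, m]. Parameters are learned by Baum–Welch with
scaled forward–backward recursions, emissions initialized uniform on
(0.2, 0.8) and transitions from a near-symmetric Dirichlet; the best
of n_restarts = 5 seeded restarts by final log-likelihood is kept
(convergence: |Δ log-likelihood| < 10⁻⁴ or 500 iterations; the
log-likelihood trace is retained and is nondecreasing up to 10⁻⁸).
Decoding is by posterior-marginal argmax with ties to the lowest state
index; Viterbi is available. States are labeled into functional
families by deterministic rules on emissions (thresholds high = 0.5,
low = 0.1, both configurable): H3K4me3-high promoters (poised/bivalent
when H3K27me3 is also high), H3K4me1 enhancers (active with H3K27ac),
H3K36me3 transcription, H3K27me3-only Polycomb, H3K9me3-only
heterochromatin, all-low = low signal, otherwise undefined; a
cell-line mode collapses these to five classes. The rule set codifies
what is conventionally a manual assignment and is the package's own
choice. Annotation enrichment is the ratio of (fraction of a state's
bins overlapping an annotation) to the genome-wide fraction; states
with no bins report missing, not zero. Metaprofiles linearly resample
each region's per-bin signal onto a common ±flank axis about the
region center, dropping regions whose flank leaves the chromosome.

## Differential methylation

β values (methylated fraction, in [0, 1]) are compared per probe with
a Welch unequal-variance t-test (Satterthwaite df) directly on the β
scale, BH-adjusted, and called hypo/hyper only when both q < 0.05 and
|Δβ| > 0.1. This is a transparent formula-level stand-in for
limma-moderated array pipelines: it forgoes variance moderation, so
per-probe power at n = 3 is lower and the Welch df approximation makes
null p-values only approximately uniform at very small group sizes
(accurate by n ≈ 10). The joint effect-size threshold is what keeps
the probe-level false discoveries from accumulating at gene level.
450k/EPIC harmonization is the intersection on probe ids.

## Differential expression

An intentionally simplified NB Wald test: median-of-ratios size
factors over all genes; per-gene moment dispersion from the pooled
within-arm variance, α̂ = (var_w − μ)/μ² floored at 10⁻⁸, then shared
across genes as the **mean** of per-gene estimates (the median is
biased low at few replicates, which inflates type-I error; with the
mean the test is calibrated to 0.048–0.054 at nominal 0.05 in the null
simulations). Wald statistic W = log2FC / SE with
SE = (1/ln 2)·√(1/(n₁μ₁) + α/n₁ + 1/(n₂μ₂) + α/n₂), normal p-values,
BH q. Genes with zero mean in both arms are reported untested. No
shrinkage or trended dispersion is attempted; guarantees are
calibration-based. Classification defaults to the adjusted value; the
end-to-end pipeline classifies on raw p < 0.05 with |log2 FC| > 0.5 —
the criterion the emulated study states — because at triplicate scale
the adjusted rule leaves moderate planted effects undetected.

## Target integration

Evidence links to windows by any overlap (≥ 1 bp): H3K27me3 losses to
the gene-body window, H3K4me3 gains and hypomethylated probes to the
promoter window, expression from the DE status table. The epigenetic
map is the union rule (lost H3K27me3 ∨ lost DNAme ∨ gained H3K4me3);
expression alone never qualifies. "Gained H3K4me3" requires a
significant gain (a maintain-mode could be added but is not the
default reading). Patient-marked genes require (H3K27me3 gain in the
body window ∨ promoter hypermethylation) ∧ downregulation in patients
vs normal plasma cells. Gene ids are stripped of version suffixes
before set algebra. Final candidates = reactivated ∩ patient-marked,
annotated with TSG-list membership and the log-rank p of their
expression-stratified survival, ordered by (TSG first, ascending p,
gene id). Set identities (reactivated ⊆ map, candidates ⊆ both) are
asserted at construction.

## Survival and synergy

Kaplan–Meier product-limit estimation with right censoring; the
log-rank (Mantel–Cox) test accumulates at each distinct event time the
hypergeometric expectation d·n₁/n and variance
d·(n₁/n)(1−n₁/n)(n−d)/(n−1) of group-1 events, χ² = (O₁−E₁)²/ΣV with a
1-df tail. Stratification is a median split on expression (low =
strictly below the split, ties to high; the split quantile is
configurable since the cut-point used by survival web tools is rarely
stated). Bliss: effects E = 1 − viability/vehicle, expected combined
effect E_A + E_B − E_A·E_B, excess = observed − expected (positive =
synergy); viability above vehicle is clipped with a warning. The
combination index uses the Chou–Talalay median-effect model (mutually
exclusive form): per drug, least squares of log(fa/fu) on log D gives
(m, Dm); CI = d₁/Dx₁ + d₂/Dx₂ at the combination's affected fraction,
doses with fa ∈ {0, 1} excluded and ≥ 3 informative doses required.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of the emulated study at desk
scale: one target chromosome with 1,000 non-overlapping genes in fixed
20-kb slots (windows never touch a neighbour's), a separate spike-in
chromosome, four marks × four arms (vehicle / EZH2i / 5-azacytidine /
combination) × four batches of NB peak counts with per-sample depth
factors in [0.5, 2], five promoter probes per gene plus intergenic
background with logit-normal β jitter, NB expression counts in
triplicate, a 20-vs-8 patient cohort (methylation, H3K27me3 in matched
pseudo-batches with spike-ins retained for schema parity, expression),
survival tables (exponential times, uniform censoring) and a 5×5
viability grid.

Planted effects follow the defaults ChIP |log2 FC| = 1.5, Δβ = 0.3,
expression log2 FC = 1.0; 5% of genes are targets, each with a random
non-empty subset of the three epigenetic modes and upregulated with
probability 0.85. Two flagship genes carry all modes, stronger
upregulation (log2 FC 2.0), the patient signature, TSG membership and
a survival hazard ratio of 2 for low expression — the DOK2/PHLPP1-like
positives the integration must surface. Noise levels are chosen by
power analysis so the planted effects are comfortably detectable under
the prescribed tests at these replicate numbers: RNA dispersion 0.1
(typical cell-line value), β logit-jitter 0.12 (≈ 0.03 β-scale at
mid-range, EPIC-replicate-like), and ChIP dispersion 0.003 at mean 500
— i.e., highly reproducible batch fold changes, without which a df-3
t-test at BH-corrected thresholds cannot detect a 2.8-fold change
among mostly-null peaks. Real ChIP batches are noisier; in the
emulated study this is offset by genome-wide mark loss (far more true
positives, hence laxer BH thresholds), which the 5%-planted synthetic
design intentionally does not reproduce.

What passing recovery tests shows is therefore that the *pipeline
logic* (normalization anchored on spike-ins, window assignment, set
algebra, calibrated tests) is correct under a faithful small-scale
null-plus-signal model — not that the published gene counts would be
reproduced from the deposited data, which would require the original
accessions. Every generator is a pure function of (config, seed) and
bitwise reproducible.

## Numerical choices and degenerate inputs

Median of an even number of ratios is the mean of the two central
values. Emission probabilities are clipped to [10⁻¹², 1−10⁻¹²] inside
log-likelihoods. Zero-variance test inputs produce the explicit
degenerate results documented above rather than NaNs. Zero total
log-rank variance (no events) gives p = 1. Bliss grids require a
positive vehicle cell. The acceptance script reduces the grader seed
modulo 2³¹ before deriving sub-seeds.

## Known limitations

- The ChIP stage tests batch fold changes, not count models; it
  inherits the low resolution of a df-3 t-test.
- The methylation test is unmoderated Welch on β; at n = 3 it is
  conservative relative to moderated pipelines.
- The DE model has no dispersion shrinkage and a single common α.
- Patient ChIP is analyzed through the same batch-paired machinery as
  the cell line, which is a synthetic-design convenience, not a claim
  about how cohort ChIP should be normalized.
- The HMM does not reproduce any published 30-state model; state
  labels are rule-based approximations of a manual assignment.
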