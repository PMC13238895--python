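# Methods

`cnvassay` reimplements, at desk scale, the computational backbone of a
CRISPR-knockout colorectal-cancer cell-line study: read-depth copy-number
calling with multi-caller consensus, pathogenicity thresholding and profile
comparison, and the quantitative assay mathematics surrounding the wet-lab
work (relative and absolute qPCR, limiting-dilution frequency estimation,
xenograft growth metrics). Every stage is exercisable on seeded synthetic
data produced by the package itself.

## Genomic backbone and synthetic read counts

All copy-number work lives on a fixed grid of 500 kb bins — the detection
floor of read-depth CNV calling at exome-scale coverage. Two backbones are
packaged: a six-chromosome "toy" genome (20–60 Mb chromosomes, arm boundary
at the midpoint) for fast tests, and the 22 GRCh38 autosomes with cytoband
arm boundaries for realistic runs. GC fractions follow a long-wavelength
sine wave (emulating isochore structure) centered at 0.42 with ±0.08
amplitude plus small seeded jitter, clipped to [0.3, 0.7].

Karyotypes are ordered lists of `(region, copy number)` entries over
chromosomes and arms; unlisted regions are diploid and later entries
override earlier ones, so a whole-chromosome gain can be carved by an
arm-level loss. The packaged tumor and cell-line karyotype fixtures encode
the study system's published region lists; rows reported as "3–4 copies"
are encoded as state 3 (no sub-clonal fraction is available), with state 4
reachable through configuration.

Simulated counts for a bin with state *k*, GC *g* and diploid depth *d* are
negative binomial with mean `d * max(k, 2ε)/2 * f(g)` and size *r*
(variance `m + m²/r`). Defaults: `d = 500`, `r = 50`, contamination floor
`ε = 0.01` (zero-copy bins keep ~1% of diploid coverage, as residual
normal-cell reads do in real tumor samples), and a multiplicative quadratic
GC bias peaking at GC 0.45 with curvature 6 — roughly a 7% depth loss at
the AT-rich end of the default GC track. All generators draw from one
`numpy` generator per call, seeded explicitly; outputs are bit-reproducible.

What the simulation does **not** emulate: mappability holes, replication
timing, wave artifacts, sub-clonal mixtures, and breakpoints below bin
resolution. Passing tests therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not performance on
real libraries.

## Normalization

Normalization is deterministic and three-step: (1) scale all counts so the
genome-wide mean equals the target (default 500); (2) divide each bin by
the median ratio of its GC decile to the global median (strata with fewer
than 20 bins merge into a neighbor; bins without GC information keep the
global factor); (3) rescale once more to the target mean. The closing
rescale is deliberate: it makes normalization idempotent to floating-point
precision, so re-normalizing a normalized track is a no-op. The output is
invariant to rescaling all input counts. Decile medians were chosen over a
smoother (e.g. LOESS) for determinism; the residual within-stratum bias is
well under the NB noise floor at these bin sizes.

### Diploid baseline

The diploid level is estimated from the peak structure of the normalized
counts. A kernel density on the log2 scale — where every copy-number state
has approximately the same peak width, because the NB coefficient of
variation is nearly state-free — proposes peaks; each peak is tried as each
state 1..5, and candidates are scored by how closely *all* peaks then sit
on half-integer copy ratios, with a mild penalty toward the median scale to
break the global halving/doubling ambiguity, followed by a weighted
least-squares polish. A plain density mode is not robust here: NB peak
width grows with the mean, so on genomes where a third of the autosomes sit
at one copy the tallest peak is the single-copy peak, and the mode-based
baseline halves every call. The estimator recovers the diploid level within
~3% on both packaged fixtures at default depth. Degenerate inputs fall back
to the median. The residual failure mode — a genome with *no* usable peak
relationships (e.g. fully uniform aberration) — is inherited from the
problem itself, not the estimator; a matched normal resolves it when
available.

### Dispersion

The NB size *r* is estimated by method of moments, `r = μ²/(s²−μ)`, clamped
to [1, 10⁶] (upper clamp = Poisson-like), on the modal-copy-number subset
of bins. Bins are assigned to states by rounding a running-median-smoothed
copy ratio (window 5): selecting on raw values would truncate their own
noise tails and inflate *r* several-fold. Method of moments over maximum
likelihood: deterministic, closed-form, and accurate to within ~±20% at
10⁴ bins, which is ample for emission modelling.

## Copy-number calling

The principal caller is a first-order homogeneous hidden Markov model over
states {0..5} — the minimal dynamic Bayesian network that converts
independent overdispersed bin counts into holistic segment-aware calls.
Emissions are negative binomial with mean `μ·max(k, 2ε)/2` and shared size
*r*; normalized values are rounded to integers for pmf evaluation (logged
when negative or non-finite). Transitions put `p_stay = 0.98` on the
diagonal, spreading the rest uniformly: at 500 kb bins that is an expected
segment length of ~25 Mb, matching arm- and chromosome-scale events;
shorter event classes warrant a smaller `p_stay`. Initial state
probabilities are uniform. Chromosomes are independent chains. The caller
returns the Viterbi path and forward–backward posteriors; per-bin
confidence is the posterior mass of the Viterbi state. States implying more
than 5 copies are clamped with a warning, following the 0–5 reporting
scale.

Two deliberately simple reference callers make multi-caller consensus
exercisable without external tools: plain rounding of the doubled copy
ratio, and running-median smoothing (shrinking window at chromosome edges)
before the same rounding. Their confidence is the distance from the nearest
rounding boundary rescaled to [0, 1] (1 on an exact state, 0 halfway
between states).

## Consensus, segments, classification, comparison

A bin is aberrant in consensus only when at least `min_support = 2` callers
agree on the *direction* (gain vs loss) of the aberration; one gain plus
one loss is no consensus. Direction rather than exact state is the
agreement currency because the downstream pathogenicity classifier consumes
only the direction and extent of a variant. The reported state is the mode
among agreeing callers; ties break toward the state closer to diploid, then
the lower state. If both directions simultaneously reach `min_support`
(impossible with three callers at support 2), the bin stays baseline.

Maximal runs of equal consensus state become segments; diploid runs are
omitted from the CNV list (full segmentation available on request).
Segments are classified by thresholding a pathogenicity score in [0, 1]:
benign [0, 0.05), uncertain [0.05, 0.95), pathogenic [0.95, 1]. The printed
interval endpoints overlap in the source convention; they are resolved as
half-open intervals closed on the left with 1.0 pathogenic — deterministic
and monotone. Scores are inputs (the classifier itself is an external
machine-learning model); a transparently non-biological demo scorer
(`min(1, |state−2|·length/50 Mb)`) exists so the pipeline runs end to end
on synthetic data.

Variant retention follows the study's rule: keep a variant if its predicted
impact is HIGH or MODERATE, or any annotation tool labels it (likely)
pathogenic.

Profile comparison reports, per bin and per bp: aberrant in A only, in B
only, shared with equal state, shared with different state, and the
"normalized" count (aberrant in A, diploid in B — the direction used when
asking how a knockout relaxed relative to its parental line). The
deterministic aberrant fraction of the packaged tumor karyotype over the
GRCh38 autosomes is 60.6% — the published description is an approximate
"nearly half of the genome".

## Quantitative assay mathematics

**Relative expression (2^-ΔΔCq).** Replicates are averaged on the Cq scale;
with two reference genes the aggregate is their arithmetic mean Cq
(equivalently the geometric mean of reference expression — the aggregation
is a package choice, stated here because conventions differ). ΔΔCq
subtracts the calibrator's ΔCq; the replicate SD of the target Cq
propagates to the interval `2^-(ΔΔCq±SD)`. The statistic is invariant to
adding a constant to every Cq on the plate. Fold *reductions* are reported
as `1/fold-change`, rounded half-up to one decimal, the precision such
values are conventionally printed at.

**Absolute quantification.** Standard curves are least squares of Cq on
log10 quantity (≥3 distinct positive standards); efficiency is
`10^(−1/slope) − 1`, so a 100%-efficient assay has slope −3.3219
cycles/decade. Unknowns invert the curve; quantities outside the fitted
dilution range are flagged extrapolated rather than rejected, and a tissue
counts as micrometastasis-positive when ≥2 of 3 technical replicates
interpolate inside the dynamic range — weak signals at the detection edge
are the norm in this assay, and the in-range-replicates rule makes the call
reproducible.

**Count endpoints.** Penetrance (percent of inoculations growing tumors),
clonogenic ability (percent of plated cells forming >30-cell colonies; the
size gate is applied upstream of the count), and karyotype aberration
summaries (sum of mutually exclusive per-cell category percentages,
rejected if >100%) all round half-up to one decimal.

## Limiting-dilution analysis

Under the single-hit model an inoculation of *d* cells grows a tumor with
probability `1 − exp(−f·d)` where *f* is the tumor-initiating-cell
frequency. The fit maximizes the binomial likelihood over log *f* (bounded
search polished by solving the score equation to ~1e-14; deterministic
given the table). `log(1−p) = −f·d` is used directly so all-negative doses
stay numerically exact. Doses with 0 or 100% take are retained — they carry
one-sided information that log-transform regression must discard. 95%
confidence limits are profile likelihood at the χ²₁ cutoff 3.84, reported
on the "1 in N" scale; profile intervals behave correctly at design points
with saturated doses where Wald intervals do not. All-positive tables
return an upper-bound-only result (frequency unbounded above), all-negative
the mirror case, each with a warning.

Two generalized-model tests accompany the fit, both likelihood-ratio tests:
the **single-hit adequacy test** frees the slope of
`cloglog P = β·log(dose) + c` (β = 1 is the single-hit model; the free-slope
GLM is fit with a complementary log-log binomial model, the constrained one
as an offset model) with χ²₁; the **heterogeneity test** compares per-group
frequencies against one shared frequency with `groups − 1` degrees of
freedom. Simulation tests confirm ~nominal behaviour: ≥90% of single-hit
replicates keep β ≈ 1 at p > 0.05, dose-independent take is rejected, and
10-fold frequency differences between groups are detected.

## Xenograft growth

Caliper volume is `0.5236 · ((width+length)/2)³` mm³ (π/6 times the cube of
the mean diameter — a sphere on the averaged calipers). Doubling time comes
from the exponential phase of a confluence curve: among contiguous windows
of ≥4 points below 95% confluence (excluding contact inhibition) whose
ln-confluence vs time fit reaches R² ≥ 0.99 with positive slope, the
longest (earliest on ties) is fit as `y = A·e^{Bt}` and doubling time is
`ln 2/B`. The R² gate and the 95% plateau cap are package choices where the
source protocol says only that the log-linear section of the curve is used.

## Pipeline, problem sizes, determinism

`run_pipeline` chains simulate → normalize → call → consensus → classify →
diff → quantify → ELDA → growth from one YAML configuration, logging stage
timers to stderr; a stage failure aborts with a stage-named error and
retains earlier outputs. Outputs are byte-deterministic given (config,
seed); every output file header records tool version, config hash and seed.

Default problem sizes were chosen to keep a full run and the test suite
interactive on a single core: 500 kb bins over the 22 GRCh38 autosomes
(5760 bins), depth 500, NB size 50; ELDA designs of 5 ten-fold doses with
9–50 inoculations per dose (200 replicate tables in the recovery study);
qPCR plates of 4 technical replicates. Accuracy claims in the test suite
are tied to these sizes.

## Known limitations

- Allelic (BAF-based) copy number, sub-clonal fractions, and breakpoints
  below bin resolution are out of scope; 500 kb is the detection floor.
- The HMM assumes a homogeneous chain; real acrocentric short arms and
  centromeric gaps are not masked (the synthetic genome has no gaps).
- The matched-normal mode (dividing tumor counts by the normal's
  mean-scaled coverage before normalization, cancelling shared per-bin
  biases) is supported but secondary; all packaged fixtures use the
  sample-internal baseline.
- The diploid-baseline estimator requires at least one informative peak
  relationship; a uniformly aberrant genome without a diploid component is
  genuinely ambiguous up to rescaling.
- The demo pathogenicity scorer is pipeline plumbing, not biology; real
  classifications require externally computed scores.
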