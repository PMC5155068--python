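# Methods

## Signal model

SMRT sequencing reports an interpulse duration (IPD) for every incorporated
nucleotide; N6-methyladenine on the template strand delays incorporation of
the complementary thymine, so larger IPDs indicate modification. At a given
GATC adenine a bacterial population is a mixture: a fraction f of cells
carry the methyl mark, so each sequencing read samples the methylated
kinetic law with probability f and the unmethylated law otherwise. All
inference is relative to a *dam* deletion strain sequenced under the same
protocol — a biological negative control that supplies the unmodified IPD
distribution at every position, in contrast to in-silico kinetic reference
models.

## Filtering

Raw IPDs above 50,000 are discarded as instrument outliers before any
transformation. A site is analysed in a sample only if ≥ 20 reads survive,
applied per stranded adenine position and per sample (a site excluded in
one sample remains testable in others; temporal tests additionally require
presence at all seven time points, and excluded sites are listed in
`temporal_exclusions.tsv`). Whether coverage should be pooled across
strands is not settled; this implementation counts per strand and says so
in the run manifest.

## Normalization and centering

The shared shifted Box-Cox transform y = ((x + α)^λ − 1)/λ (log limit for
|λ| < 1e−8) with defaults α = 0.311, λ = 0.151 makes the right-skewed IPD
distributions near-normal so Welch/ANOVA machinery applies. Optional
refitting minimizes Σ(skewness² + excess kurtosis²) over samples on a
coarse α × λ grid in [0.01, 1]² followed by a Nelder–Mead polish; moments
use the biased sample estimators g₁ and excess g₂. The optimum is shallow
in α, so recovery is validated on λ.

Each sample is centered by subtracting one grand mean over **all** observed
reference positions. The reference set must be dominated by unmethylated
positions: if centering were computed over the tested GATC sites alone, a
sample in which every GATC is methylated would have its entire signal
absorbed into the offset. The synthetic generator therefore also emits
non-motif background adenine positions (truth label "none", unmethylated in
every sample, by default two per duplex GATC) and centering pools them with
the motif sites — the synthetic analogue of genome-wide centering, where
GATC adenines are a small minority. Per-position centering was rejected
outright because it nulls the per-site contrast against the control.

## Detection

Welch's unequal-variance two-sided t statistic (Welch–Satterthwaite df) on
centered transformed values, and a Wilcoxon rank-sum on raw values (exact
null for combined n ≤ 25 without ties, otherwise normal approximation with
mid-rank tie correction and continuity correction; rank tests are invariant
under the monotone transform, so raw vs transformed is immaterial and is
asserted by a test). Degenerate inputs (zero variance in both groups, all
values tied) return flagged outcomes rather than silent zeros.

False-discovery control uses Storey q-values per sample cohort (the scope
is recorded in output metadata): π₀(λ) = #{p > λ}/(n(1 − λ)) on
λ ∈ {0, 0.05, …, 0.90}, smoothed with a degree-3 least-squares polynomial —
the closest numpy analogue of the reference smoothing spline with three
degrees of freedom — evaluated at λ = 0.90 and clamped to (1/n, 1]. With π₀
fixed at 1 the q-values coincide exactly with Benjamini–Hochberg, which the
tests exploit as an oracle. The 1/n floor only matters when nearly every
hypothesis is non-null, where it makes q-values slightly conservative.

Sites that come out non-significant are re-tested under equalized coverage:
the larger group subsampled without replacement to the smaller's n, and
both groups bootstrap-resampled at the common n, each summarized as the
median p over (by default) 100 seeded resamples. These re-tests are
reported as robustness columns confirming that a negative call is not a
coverage artifact; they do not promote sites into the detected set, which
remains q < FDR.

## Temporal testing and patterns

One-way fixed-effects ANOVA on centered transformed values and
Kruskal–Wallis (tie-corrected, χ² with k − 1 df) on raw values across the
seven time points, with Storey q-values per method. Two thresholds are
carried through: q < 0.05 (strict) and q < 0.3 (the pattern-formation
screen). Time is treated as an unordered factor; no time-series modeling.

Sites passing the screen are summarized as IPD ratios — mean raw sample IPD
over mean raw *dam* IPD at the same stranded position, so 1 means no
kinetic shift. Ratios use raw means: centered Box-Cox values can be
negative, making ratios ill-defined. Because the raw mean is linear in f
((1 − f)·E[unmeth] + f·E[meth]), a ratio trajectory is an affine image of
the fraction trajectory and preserves its shape.

Clustering is agglomerative Ward (minimum-variance, ward.D2 convention:
heights are √(2·ΔESS), verified against a brute-force oracle that computes
every candidate merge's ESS increase from the raw rows), cut at k = 4.
Cluster labels A–D are assigned by z-normalizing each cluster centroid and
each of the four template trajectories (A: flat 8–16 h then monotone rise;
B: 24–72 h decline then recovery; C: peak at 72 h; D: peak at 24 h with a
late rise) and solving the one-to-one assignment minimizing total Euclidean
cost; z-normalization makes the label depend on shape, not amplitude. With
fewer than four clusters the best-fitting subset of labels is used and a
warning emitted.

## Enrichment

A duplex site maps to a gene if it lies in the gene span, otherwise to any
gene whose start is within a 300-bp upstream window on the correct strand
(both genes of a divergent promoter may match; the window is configurable —
no principled value exists, 300 bp covers typical bacterial promoters).
Terms are tested by Fisher's exact test (two-sided by the point-probability
rule; one-sided "greater" available by flag) against the universe of all
annotated genes (configurable; the choice changes p-values and is recorded
in the manifest). Raw p-values are thresholded at 0.1 with no
multiple-testing correction, by design. Flat term membership only — no
ontology-graph propagation.

## Assays

LC-MS: bulk methylation is [meA]/([meA] + [A]) from dilution-corrected
(area × dilution factor) extracted-ion peak areas, averaged over
replicates; error is the percent coefficient of variation (100·sd/mean),
propagated across biological samples as the root sum of squares; Chargaff
ratios (A + meA)/T and G/C flag response drift beyond a configurable
tolerance (default 10%).

qRT-PCR: adjusted CT = CT·log₂(1 + E) − log₂(mass/reference mass), where
E ∈ (0, 1.2] is the primer-pair efficiency (E = 1 is perfect doubling,
reducing to plain 2^ΔCT) and the mass term credits one cycle per doubling
of loaded RNA. The fold change between strains is 2^(adjCT_test −
adjCT_reference), replicate-matched, reported as mean ± sd. The exact
normalization arithmetic behind published 2^ΔCT values is rarely stated;
this form is documented and configurable precisely because it is a choice.

## Synthetic data

The generator emulates the study design: seven time points (8, 16, 24, 48,
72, 96, 120 h), a *dam* control and a WGA control (both simulated at f = 0;
they differ only in label, matching their indistinguishable IPD profiles).
Defaults: log-normal IPD laws with μ_unmeth = 0, μ_meth = 1.0, σ = 0.6 on
the log scale (positive, right-skewed, a ~1.7σ kinetic shift); coverage
Poisson with mean 50 truncated at ≥ 1 (the study's sequencing averaged
~67× with a 49× minimum); outliers uniform on [50,001, 10⁶] at rate 0.005
to exercise the cutoff; fraction trajectories piecewise-linear between
per-pattern anchors chosen to realize the four qualitative archetypes, with
94% of sites constant at f = 0.9 (temporally changing sites are a small
minority of a nearly fully methylated methylome). IPD units are treated as
a dimensionless positive real. Not simulated: sequence-context kinetic
effects, read errors, instrument file formats, within-site strand
asymmetry. Passing tests therefore demonstrate correct statistical
machinery and calibration under the assumed mixture model, not robustness
to context-dependent kinetics in real instruments.

## Problem sizes and determinism

The shipped verification uses 1,000 stranded GATC sites per dataset for
calibration and power (200 replicates for the null false-detection rate),
1,000 duplex sites with 60 temporally changing for recovery, and 50 seeded
replicates for clustering/label accuracy at a 3σ template separation
(per-coordinate noise sd = one third of the minimum pairwise template
distance, scaled by √7) — sizes at which Monte-Carlo error is small
relative to every asserted margin. Every stochastic step takes an explicit
seed (child seeds spawned via `numpy.random.SeedSequence`), identical
config + seed reruns are byte-identical, and the pipeline manifest records
seed, parameters and input checksums.

## Known limitations

The 37,452-site census and per-site results on the real genome require the
original kinetics data; nothing here depends on them, and the published
site lists (66 temporally changing sites; 5 ANOVA vs 6 Kruskal–Wallis at
strict FDR) are not reproducible from printed tables alone. Enrichment
p-values depend on the universe choice. The equalized-coverage summary
(median of resample p-values) is one defensible aggregation among several.
Pattern labels are template matches, not model-based classifications; with
trajectories unlike all four archetypes the nearest template still wins.
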