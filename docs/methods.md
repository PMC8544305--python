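# Methods

This note documents the models, numerical choices and known limitations of
`methylaging`. It describes what the code computes; every number quoted as an
output here is produced by the test suite or by `scripts/acceptance.py`, not
asserted from memory.

## Data model

The central container is a site × sample matrix of (methylated,
unmethylated) read counts with 1-based inclusive coordinates matching the
Bismark-coverage dialect. Cytosines on opposite strands are distinct sites
and are never merged. Percent methylation is derived from counts; a missing
cell is a cell with no counts (or counts removed by filtering). After
k-nearest-neighbour imputation the dataset carries an explicit, fully
observed percent matrix and the counts stop being the authoritative signal —
which is why the preprocessing chain treats an imputed dataset as already
processed (this makes the chain exactly idempotent from the second
application onward).

## Preprocessing

Order-fixed chain: coverage filter → coverage normalization → uniting →
KNN imputation → near-zero-variance removal.

- **Coverage filter** masks cells with total coverage outside [5, 100];
  bounds are inclusive at both ends (a literal reading of "less than 5× or
  greater than 100×"). Sites with no surviving cell are dropped.
- **Normalization** scales each sample's counts by
  (reference median coverage / sample median coverage) with the reference
  equal to the median of per-sample median coverages. Totals are rounded to
  integers; methylated counts are re-derived from the pre-scaling fraction,
  so each cell's methylation fraction is preserved within 1/(2·coverage).
  Whether the upstream protocol normalized before or after the coverage
  filter is not documented anywhere we could rely on; this package fixes
  filter-first.
- **Uniting** keeps sites observed in ≥ 5 samples of *every* group and
  raises if any group is smaller than the quota (the criterion would be
  unsatisfiable).
- **KNN imputation (k = 4)** replaces each missing percent value with the
  mean over the k nearest sites observed at that sample. Distance is the
  unscaled Euclidean distance over pairwise-complete samples; ties are broken
  by site order. The implementation preselects candidates with
  `argpartition` and falls back to a full scan whenever the preselection
  cannot supply k observed neighbours, so it is exactly equivalent to the
  brute-force definition (the tests verify this equivalence directly).
- **Near-zero-variance removal** drops a site when (most common value count /
  second most common count) > 19 and (distinct values / samples) ≤ 0.10 —
  the standard frequency-ratio/unique-percent screen, with the 19 boundary
  excluded (a ratio of exactly 19 survives).

## Age association

Spearman ρ per site against age in days (midranks for ties), Pearson r kept
alongside; ages enter untransformed (the log10 transform is reserved for the
elastic-net clock and the natural-log transform for the PDR model). p-values
use the t approximation for n ≥ 10 samples and exact permutation enumeration
below that; constant sites are recorded with ρ = 0, p = 1 and a `degenerate`
flag rather than NaN. FDR control is Benjamini–Hochberg throughout (the
upstream differential-methylation tool defaults to SLIM; BH is the
documented substitution). A site is age-associated iff |ρ| > 0.5 (strict).
The seven correlation bins assign boundary values ±0.25 and ±0.5 to the bin
farther from zero, and only exactly-zero coefficients land in the "0" bin.

DMCs pool counts within groups and use a two-proportion likelihood-ratio
(G) test, df = 1 — the binomial logistic model of methylation state on group
with no covariates. Fisher's exact test is available behind a flag as a
cross-check, not as the default. A DMC requires |Δ percent| ≥ 25 and
q ≤ 0.01. The early-vs-late rate analysis uses the actual metadata ages in
days for the elapsed time (not calendar-month conversions) and a paired
t-test on per-day absolute rates; when all paired differences are exactly
zero the statistic is reported as t = 0, p = 1.

## Clocks

All three families flatten to `transform⁻¹(intercept + Σ w·percent)`, and a
site absent from a prediction dataset contributes zero to the weighted sum —
the documented degradation path when a clock is applied to a cohort with
incomplete coverage.

- **Linear top-k** ranks sites by training-set |Pearson r| (ties broken by
  coordinate order) and greedily skips any site within 100 bp (inclusive) of
  an already-chosen site on the same chromosome, then fits OLS of age on the
  k = 10 selected sites.
- **Elastic net** minimizes (1/2n)‖y − b₀ − Xb‖² + λ(α‖b‖₁ + (1−α)/2·‖b‖²)
  with α = 0.5, y = log10(age days), predictors standardized with the
  population SD (glmnet convention). λ is picked by leave-one-out CV —
  standardization redone inside each fold — over 100 log-spaced values from
  λ_max (the smallest λ zeroing all coefficients) down four decades. The
  coordinate-descent solver is scikit-learn's `enet_path`, whose objective
  matches this parameterization exactly; λ = 0 is solved by least squares
  and reproduces OLS (a test asserts agreement to 1e-6). Predictions are
  back-transformed to days before any MAE is computed.
- **PCA clock** selects training-set age-associated sites (|Spearman ρ| >
  0.5), centres and scales them (sample SD, ddof = 1 — whether the original
  analysis scaled is not documented, so scaling is on by default and
  switchable), takes PC1 oriented to correlate positively with age, and fits
  OLS of age on PC1. PC1's variance-explained is the squared first singular
  value over the total.

R² is the coefficient of determination on the day scale (1 − SSres/SStot),
not a squared correlation — the distinction matters for the test split.
Overfit is assessed by a Welch two-sample t-test on absolute errors of the
train vs test split; exposure-group comparisons use one-way ANOVA on
predicted ages. Serialized models are plain JSON and reload to bit-identical
predictions.

## Genomic context and motif scanning

CpG islands: 100 bp windows, step 1 bp; a window passes when GC ≥ 50% and
ObsCpG/ExpCpG ≥ 0.6 with Exp = #C·#G/100; overlapping passing windows are
merged and merged runs ≥ 200 bp are reported with mean window statistics.
N bases count as non-GC. The exact merge rule of the classic cpgplot-style
tool is unstated, so merge-then-length-filter is the documented choice, and
the unit tests pin it against a brute-force per-window oracle. Context labels
use the bp gap to the nearest island edge: 0 = island, ≤ 2000 shore, ≤ 4000
shelf, else open sea (boundaries closed on the right). Genic context is exon
if inside any exon block, else intron if inside a gene span, else intergenic;
exon takes precedence across overlapping transcripts.

Enrichment uses the two-sided exact binomial test (minimum-likelihood
method, `scipy.stats.binomtest`) of focal category counts against the
background proportion.

Motifs: PFM → PPM (column-normalized) → PSSM in bits, log2(PPM/0.25), with
zero entries floored at ε = 1e-6 instead of pseudocounts, preserving
"impossible base" semantics while keeping scores finite. The null score
distribution under i.i.d. uniform bases is computed exactly by positionwise
convolution after discretizing per-position scores to a 1e-3-bit grid; the
survival function is therefore exact on that grid (the tests compare it with
exhaustive enumeration up to motif length 8). Both strands are scanned (the
elements are double-stranded); hits require p < 1e-4. Windows containing N
are skipped. Overlap with a focal site uses the symmetric 2 kb window (1 kb
each side).

## Read-level discordance (PDR)

A read is eligible with ≥ 2 CpG calls; its methylation level m = 100·mean of
calls classifies it as discordant iff 10 ≤ m ≤ 90, concordant otherwise.
Thresholds act on the exact fraction — no rounding — and levels in the gaps
(9, 10) and (90, 91), reachable only for reads with more than ten CpGs, fall
to concordant so the classification is total. PDR is the percentage of
discordant among eligible reads. The age trend is a linear mixed model
PDR ~ ln(age days) with a random intercept per library batch, fitted by
REML; the slope p-value uses a t statistic on n − 2 residual degrees of
freedom (a deliberate simplification — with two batches any finer df
correction is unstable). With a single batch the fit falls back to OLS with
a warning, and when the batch variance collapses to the boundary the slope
SE falls back to the OLS information matrix.

## IR × aging interaction

Per-dose DMC tables (control vs each arm) are unioned ("affected by at least
one dose"). The bin-enrichment background is the *intersection* of the aging
and exposure site sets with their aging-continuum bins; the focal set is the
shared IR DMCs (the alternative background — the full aging set — is
available via the `ir_covered_keys` argument). Directionality: per shared
DMC, the age direction is sign(ρ) and each significant dose contributes
sign(Δ percent); the relation is dose-dependent when significant doses
disagree, same when the common sign matches the age direction, otherwise
opposite; sites with ρ exactly 0 are excluded and reported as undefined.
The same/opposite split per bin is tested against a 50:50 binomial null — a
documented assumption, since no other null is specified anywhere upstream.

## Synthetic-data generator

The generator emulates the structure of the study the package targets:

- **Aging cohort**: 7 age groups at 61/122/152/183/274/365/426 days with
  n = 7/6/6/8/6/8/6 males (47 total), two library batches assigned by age
  group.
- **Latent trajectories**: null sites constant at a Beta(0.4, 0.4) baseline
  (bimodal, as methylation fractions are); planted age sites (default 0.5%
  of sites) follow a piecewise-linear trajectory in age with the breakpoint
  at 183 days and an early:late per-day slope ratio of 2, reproducing the
  roughly twofold faster early-life change. Total lifespan change per planted
  site is drawn uniformly from [0.75, 1]·effect_scale (default 40 percentage
  points); 80% of planted trends gain methylation with age. No per-site
  effect-size distribution is documented for the real data, so these defaults
  are calibrated only to reproduce the headline fractions (a small minority
  of sites with |ρ| > 0.5; an early:late ratio near 2) and to make planted
  trends recoverable.
- **Observation model**: logit-normal site×sample jitter (SD 0.3 on the
  logit scale — chosen to keep fractions in [0,1] without truncation
  artifacts), additive percent-scale batch shifts (SD 2), negative-binomial
  coverage (mean 30, dispersion 5, spanning the 5–100× range), binomial
  methylated counts, and 8% of cells masked as missing.
- **IR cohort**: 4 arms (0/5/50/500 mGy/day) × 6 fish at 232 days (6-month
  fish after a 7-week exposure). IR-affected sites are drawn from truth sites
  whose *empirical* aging-cohort correlation bin is in the configured target
  bins (latent trajectories are monotone, so their latent ρ is ±1/0 and
  cannot define moderate bins — the empirical ρ of the generated cohort is
  recorded in the truth table for exactly this purpose). Affected sites shift
  by ±30 percentage points at every nonzero dose, with direction opposite to
  the age trend by default; optional per-bin planting weights let a scenario
  concentrate effects in the moderately age-associated bin.
- **Read patterns**: truncated-Poisson CpG counts per read (mean 3, ≥ 1);
  among eligible reads the discordance probability equals
  2 + 3.01·ln(age days) percent (the slope equals the real study's reported
  estimate, used purely as a simulation setting), plus a per-batch offset
  (SD 0.5 points) so the random-intercept model is well posed.
- **Genome**: i.i.d. background at 40% GC with background CpGs depleted
  (70% of background CG dinucleotides broken — vertebrate genomes are
  CpG-poor outside islands, and an undepleted background produces spurious
  island calls), planted CG-dense segments of 250–600 bp, gene models with
  2–6 exon blocks, and exact motif consensus instances at recorded positions.
  CpG sites are then sampled from the realized sequence and carry true
  context labels derived from the planted features.

All randomness flows from one integer seed through named substreams
(`SeedSequence` children), so every output is byte-identical across runs at
a fixed seed.

### What the generator does and does not emulate

It reproduces the study's design (group sizes, batch structure, coverage
spread, missingness, effect directions and rough magnitudes) but not the
genomic autocorrelation of methylation, CpG-density-dependent coverage of a
real reduced-representation protocol, sequencing or bisulfite-conversion
error, or linkage between neighbouring sites. Passing tests therefore
demonstrate that the statistical machinery recovers planted structure under
the stated noise model at desk scale — they do not certify performance on
real RRBS data, and the real study's headline metrics (e.g. training/test
MAE of its clocks, its DMC counts) are not reproducible without the deposited
sequencing data.

## Problem sizes used in tests and the acceptance script

Unit tests run on hundreds to a few thousand sites; the clock-recovery and
acceptance runs use the full 47-sample × 20,000-site default study; the
IR-directionality power scenario uses 20 replicates of a 4,000-site study
with 5% planted IR sites weighted 3:1 toward the weak-positive bins (the
weighting makes both weak-positive bins simultaneously testable: with purely
occupancy-proportional planting the sparse moderate bin receives too few
effects for a well-powered exact binomial test at these sizes); the
enrichment-calibration check draws 1000 null focal sets of 500 sites with
replacement (matching the binomial sampling model of the test). These sizes
are the package's chosen desk-scale defaults.

## Known limitations

- The mixed model's residual-df t approximation is crude with two batches;
  it is the documented trade-off against unstable df corrections.
- The exact binomial test is discrete, so its realized type-I error sits
  slightly below the nominal level for small focal sets.
- KNN imputation is O(sites²) in the worst case; the candidate preselection
  keeps the default study fast, but very large site counts would need a
  different neighbour index.
- The elastic-net LOO-CV refits the full path per left-out sample; this is
  exact but the dominant cost of a full run.
- `percent()` rounds half-up via decimal arithmetic so reported one-decimal
  percentages are stable; values computed from floating-point inputs may
  still differ in the last digit from a different rounding convention.
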