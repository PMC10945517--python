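# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical conventions. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic study designs (`simulate`)

The generators' defaults are the study conditions the analyses assume:

- **Cross**: 737 F2 individuals from two fully homozygous opposite-allele
  parents; 10 % phenotypic tails; 75 plants per bulk. Meiosis uses the
  Haldane map function r = (1 − e^(−2d/100))/2 with no crossover
  interference — the standard minimal model when none is specified.
  Dosages count the high-parent (alternate) allele.
- **Genome**: seven chromosomes of 150 cM / 230 Mb (≈1.6 Gb total, the
  pearl-millet scale), markers evenly spaced so genetic and physical
  positions are exactly co-monotone. 2000 markers/chromosome is the scan
  default; 6853/chromosome is used for full-scale filtering runs so that
  the post-cascade marker set lands in the study's density regime
  (~2 SNP / 100 kb; the 25th/95th depth percentile window removes ~30 % of
  sites by construction).
- **Phenotype**: Σ_q [a_q(dosage_q − 1) + d_q·1{dosage=1}] + N(0, σ²);
  with residual SD 1, an additive effect a is directly in phenotype-SD
  units (the power analyses use a = 0.8).
- **Sequencing**: mean bulk depths 1028X / 814X; negative-binomial site
  depth with dispersion 0.2 (GBS depth is overdispersed; dispersion 0
  selects Poisson); base error 0.001 folded into the binomial read-draw
  success probability rather than simulated per read. Parents are emitted
  perfectly homozygous at a fixed depth equal to the mean of the two bulk
  depths (a convention; parent depth carries no signal here). Equimolar DNA
  contribution per bulk member is assumed.
- **Panel**: 122 lines, Poisson plants/line (mean 7, min 1), Gaussian line
  effects and residuals; optional small fixed year and block-within-year
  shifts give the adjusted-means machinery something to absorb.
- **Cell profiles**: cells laid end to end from the quiescent center; each
  cell's (distance, length) pair lies exactly on the logistic curve (the
  midpoint is solved by fixed-point iteration), then Gaussian noise
  truncated at 1 µm. With ~10 µm meristem cells and x0 = 3 mm, a profile
  needs a few hundred cells to span both shoulders — fits on shorter
  profiles are flagged unconverged rather than trusted.
- **Weather/soil**: daily rain is a Bernoulli wet-day chain with gamma
  depths — a generic semi-arid stand-in, *not* a calibration to any
  station. The bucket holds `ttsw` mm of transpirable water, starts
  quarter-full, loses `demand × min(1, FTSW/0.3)` per day (never more than
  is available) and spills overflow above capacity; water is conserved to
  1e-9 mm by construction.

What the generators do **not** emulate: real linkage-disequilibrium decay
and marker ascertainment of GBS, mapping/calling artifacts, shared
environment within blocks beyond an additive shift, curvature of real root
transects, phenology responding to stress, or any real crop physiology
(the bucket replaces a full crop model). Passing tests therefore
demonstrate correctness of the statistical machinery under its stated
assumptions, not robustness to every artifact of field data.

## Filtering cascade (`filtering`)

Order matters and follows the documented sequence: parental/biallelic step
(parents confidently homozygous — major-allele fraction ≥ 0.9 at depth ≥ 5,
thresholds the study leaves open — and opposite; re-polarized so the
low-growth parent is reference), then multi-allelic, pooled bulk
alternate-allele frequency < 0.25, total-depth percentile window,
missingness > 50 % (a sample is missing at a site when its depth is 0),
and pooled-count MAF < 5 %. "Total allele frequency" is read as the pooled
alternate-read fraction across both bulks, and AF/MAF filters operate on
read counts, not genotype calls — both points the study leaves
unspecified; both are configurable.

Percentiles use the nearest-rank definition (1-based rank ⌈p/100·n⌉) on the
table as it stands after the frequency step, with a closed retention
interval — sites exactly at a boundary are kept, so a degenerate
all-equal-depth table loses nothing. Because a percentile window
recomputed from an already-truncated distribution would truncate further,
the resolved absolute bounds are materialised into the returned report
(`report.attrs["resolved_config"]`); the cascade re-applied with its
resolved configuration is a no-op, which is the precise sense in which it
is idempotent.

## BSA scan (`scan`)

ED is implemented as the between-bulk Euclidean distance over the two
allele frequencies, `sqrt((fa_H−fa_L)² + (fA_H−fA_L)²)`; for biallelic
sites this is √2·|fa_H − fa_L|, symmetric under bulk swap and invariant to
global allele relabeling. Markers with zero depth in either bulk are
excluded (count logged), not imputed.

Windows hold 100 consecutive markers, slide one marker at a time (disjoint
tiling behind a flag; whether the original windows slide or tile is not
stated), never span chromosomes, and assign `(Σ ED)⁴` to the window's
midpoint marker. A chromosome with fewer markers than the window yields a
single flagged whole-chromosome window. Window sums are computed by direct
per-window summation (no cumulative-difference cancellation), so they agree
with a naive double loop to ~1e-12 relative.

**Null threshold.** The default null simulates unlinked markers: each
bulk's true frequency is Binomial(2·75, ½)/150, read counts binomial at the
model depths. Two quantile modes: *pooled* (q-quantile of all null window
statistics — the per-window 95 % band) and *familywise* (q-quantile of
per-genome maxima — controls the genome-wide false-positive rate, to which
the type-I-error calibration applies). Both are deterministic given the
seed.

The unlinked null is knowingly anti-conservative for genome-wide calls:
with 75-individual bulks, allele-frequency drift is strongly autocorrelated
along a linked chromosome, and windowed sums under linkage dwarf the
unlinked null even without any QTL. An optional linked null (`pos_cm`
argument, or `genetic_map` on `BulkSegregantScan`) therefore simulates the
two bulks as 150 recombining F2 individuals with no QTL; its familywise
threshold is the genome-wide honest choice and is what the README example
uses. The unlinked protocol remains the default because it is the declared
reference protocol and the calibration properties are defined against it.

Significant windows contribute ±8 Mbp intervals (1-based, closed; clipped
to the chromosome), overlapping intervals merge, the region peak is the
maximal window statistic with leftmost tie-breaking, and BED export
converts to 0-based half-open. GWAS intersection treats region bounds as
closed and validates chromosome names when a reference set is supplied.

## Heritability (`heritability`)

Method-of-moments components from the unbalanced one-way ANOVA:
Var(res) = MS_within, Var(line) = (MS_between − MS_within)/n₀ with
n₀ = (N − Σnᵢ²/N)/(k−1); negative line variance is truncated to 0 with a
warning. MoM was preferred over REML as the default because the estimator
is closed-form and exactly testable; REML (`method="reml"`, via a
random-intercept mixed model) agrees with it on balanced designs and is
the cross-check in the tests. H² uses the exact formula with n̄ = N/k, the
arithmetic mean of plants measured per line; it is the line-mean
repeatability, so it exceeds the single-plant ratio whenever n̄ > 1.
Degenerate inputs (all values equal) report H² = 0 with a flag rather than
0/0.

Adjusted line means fit `value ~ line + year×block` by OLS with treatment
coding and average each line's prediction with equal weight over the
year×block cells observed anywhere in the data (not all theoretical
cells); on balanced designs this equals the arithmetic line mean.
Rank-deficient designs are solved by pseudo-inverse with a warning.
Correlations are Pearson on pairwise-complete line means; zero variance
returns NaN with a warning.

## Kinematics (`kinematics`)

Wall detection is peak finding with prominence and minimum-separation
constraints; of two peaks closer than the separation the higher survives,
and plateaus resolve to their leftmost sample. The first detected wall is
taken as the quiescent-center origin (image registration is upstream).
Cell distance is the midpoint between its bounding walls.

The logistic fit is 4-parameter (nonzero l_min floor — meristematic cells
have real length, so a 3-parameter curve through zero is the wrong shape;
the 3-parameter variant is behind a flag). Initialisation is data-driven
(5th/95th length percentiles, half-range crossing, central slope for k);
the lower bound on lengths is min(0.1 µm, 1e-3·max length) so a coherent
unit change does not clamp the fit. Non-convergence and flat profiles
return `converged=False` instead of raising.

Cell production = elongation rate / l_max uses the fitted asymptote as the
"maximum cell length" (the observed-95th-percentile fallback is available
for unconverged fits); elongation rate is an externally measured input,
mirroring how the experiment measures root length gain per day.

## Stress patterns (`stress`)

Sowing is the first day with ATSW ≥ 10 mm (inclusive); the rain gap counts
days strictly between the first two rains > 10 mm. DTW is the classic
dynamic program (match/insert/delete, |a−b| local cost, no window by
default, optional Sakoe–Chiba band). Seasons, aligned by days after
sowing, are clustered by average-linkage on the pairwise DTW matrix; k is
chosen in 2..6 by maximal mean silhouette on those distances (a silhouette
criterion replaces a multi-index vote whose deciding index is unknown);
identical seasons collapse to one degenerate cluster. Everything is
deterministic.

Classification: a day is stressed when FTSW < 0.3. Early stress = any
stressed day before flowering (so stress between panicle initiation and
flowering counts as early; the strict pre-panicle-initiation boundary is a
parameter); late stress = any stressed day in [flowering, maturity];
otherwise no stress. Lowering the onset threshold can only shrink the
stressed set. Penalties are 100·(mean_no-stress − mean_label)/mean_no-stress
per label, requiring at least one no-stress season with yield as baseline.

## Problem sizes

The test suite and acceptance script run the power and calibration checks
at the study scale the designs state: 7×2000-marker genomes with 737
individuals for QTL recovery (100 replicates), 2000-marker null genomes
(500 threshold simulations + 400 fresh replicates), a 6-cell heritability
grid × 200 seeds, and a 47,971-marker full-scale filtering run. These
sizes were chosen so each guarantee is exercised at the scale it is stated
for while a full run stays in the tens of seconds.

## Known limitations

- The unlinked default null understates genome-wide significance under
  linkage (see above); use the linked familywise threshold for region
  calling on whole genomes.
- MoM variance components can be noticeably noisy below ~50 lines; REML
  shares the problem but truncates differently.
- The adjusted-means model has no line×year interaction; with strong G×E
  the equal-weight cell averaging is a definition, not an inference.
- The bucket model has one soil layer, no runoff/drainage separation, no
  canopy development: FTSW trajectories are qualitatively, not
  quantitatively, like a crop model's.
- DTW clustering on raw daily series can split seasons that differ mainly
  in length; the optional band mitigates but does not remove this.
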