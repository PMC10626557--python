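# Methods

## Scope and model

The package grades chilling injury in cucumber seedlings from PAM
chlorophyll-fluorescence induction curves, without labels. The chain is:

base signals (Fo, Fm, F, Fm′, Fo′) → 15 derived parameters → 3σ outlier
filter → min–max normalization → feature extraction (PCA / UMAP) → fuzzy
C-means with GA-optimized initial centroids → severity classes 0–3.

Severity classes are defined operationally: four clusters, ordered by
decreasing cluster-mean Fv/Fm (the maximum quantum yield of PSII
photochemistry, ≈0.84 in healthy leaves, collapsing toward ~0.1 under
severe chilling). Four classes reflect the observed regimes — a stable
unstressed plateau, a reversible slight-injury band, and two
progressively irreversible bands.

## Parameter derivations

All quenching parameters are computed exactly from base signals at full
floating precision; rounding happens only at output formatting. Y(NO) is
taken literally as F/Fm — the instrument-dialect convention under which
Y(II) + Y(NPQ) + Y(NO) = 1 holds as an identity — rather than the
alternative lake-model expression. Records with Fm′ ≤ Fo′ are rejected
rather than clamped, because qP and qN divide by Fm′ − Fo′ and a
light-adapted maximum at or below the light-adapted minimum indicates a
measurement fault, not a physiological state.

Electron transport rates use ETR = Y × PAR × 0.84 × 0.5 with the
absorptance (0.84) and photosystem partitioning (0.5) held at their
conventional constants; no leaf-specific absorptance is resolved.
Y(CEF) = ETR(I) − ETR(II) is a proxy for cyclic electron flow and is
non-negative whenever Y(I) ≥ Y(II) at the same PAR.

MDA content follows the thiobarbituric-acid colorimetry formula
C = {6.45[D532 − (D510 − D560)/2] − 0.56·D450}·N/W (nmol·g⁻¹), linear in
extract volume N and inversely proportional to fresh mass W.

## Preprocessing

**3σ rule.** A row is removed when any feature deviates from its group
mean by more than three standard deviations, with the candidate row
excluded from the statistics (leave-one-out, sample std). Including the
candidate would mask a single aberrant value in an otherwise tight group
— the regime the rule exists for. Filtering is per temperature × day
group by default (a global mode exists), runs as a single pass, and makes
no idempotence claim: re-running on the filtered output may remove more
rows, since group statistics shrink. With 8-plant groups the
leave-one-out variant is deliberately strict; on the default synthetic
cohort it removes ~15% of rows. Groups under 3 rows pass through with a
warning.

**Normalization.** Column-wise min–max to [0, 1] (Y = (X − Xmin)/(Xmax −
Xmin)) applied after filtering, so extreme rows cannot compress everyone
else's range. The (Xmin, Xmax) pairs are stored for exact inversion.
Constant columns are an error naming the feature.

**Correlation screening.** Standard product-moment (Pearson) correlation;
verbal strength bins on |r| are half-open on the left except the top bin:
[0, 0.2) uncorrelated … [0.8, 1.0] extremely strong, so a boundary value
takes the stronger label. Group summaries use mean-centered (original)
Levene's test and fixed-effects one-way ANOVA; a feature with zero
within-group variance but distinct means reports F = +inf with a
degeneracy flag.

## Feature extraction

PCA runs on the normalized matrix with column centering (covariance PCA —
normalization has already equalized scales; correlation PCA is an
option). The retained count k is the smallest with cumulative explained
variance ≥ 95%. Loading signs are fixed so each column's
largest-magnitude element is positive, making biplots reproducible.
Rank-deficient input (the 15-parameter matrix always is: Fv = Fm − Fo and
the yield partition are exact linear identities) caps k at the rank with
a warning.

UMAP embeds into exactly 4 features with a 5-neighbor graph and zero
minimum embedding distance, seeded and therefore reproducible run-to-run.
UMAP coordinates are meaningful only up to the algorithm's internal
layout stochasticity, so every downstream assertion is about cluster
recovery or relative geometry, never raw coordinates.

## Clustering

FCM minimizes J = Σ u^m d² (fuzzifier m = 2.0 by default; any m > 1) by
the standard alternating stationarity updates, which are the
first-order conditions of J. Convergence is declared when the max-abs
membership change drops below 1e−5 (configurable); J is recorded after
every full update cycle and is non-increasing. A sample coinciding with a
centroid takes membership 1 there (no division by zero). The "initial
movement error" reported in variant comparisons is J evaluated at the
initial centroids with the memberships they induce, before any update;
"iterations" counts full update cycles to the tolerance.

The GA evolves flattened C×d centroid candidates sampled within
per-column data ranges: fitness 1/(1 + Σⱼ minᵢ‖xⱼ − vᵢ‖²) (crisp
nearest-centroid distortion; a fuzzy-J fitness is selectable),
fitness-proportionate (roulette) selection with 1-elitism, arithmetic
crossover with probability 0.8, per-gene Gaussian mutation (σ = 0.1 ×
column range) with probability 0.2, population 100, 50 generations.
Elitism makes the best fitness non-decreasing. The GA's terminal
precision is bounded by the mutation scale; it is an initializer, and the
subsequent FCM iterations do the local polishing.

Four variants are provided for comparison: FCM on all 15 parameters,
ChlF-FCM on (Fv/Fm, Fo, Y(NO), qP), PCA-FCM on the retained PCs, and
UMAP-GA-FCM on the 4 UMAP features with GA initialization (the others
draw C distinct samples as centroids). Every variant's input
representation is column-wise min–max scaled before clustering so the
objectives — and hence the initial-error diagnostics — are on comparable
scales across representations of different dimension and unit.

Cluster → class assignment sorts clusters by decreasing cluster-mean
severity proxy (default: each sample's Fv/Fm); ties break toward the
lower cluster index. Hard labels follow argmax membership. Fewer than
four non-empty clusters triggers a warning and classes are assigned to
the non-empty ones only. C is fixed at 4; cluster-number selection is out
of scope.

## Synthetic data generator

The generator exists because the study's raw measurements are not
deposited. It emulates the study conditions: 4 temperatures (8, 10, 12,
14 °C) × days 0–5 × 8 plants per group, 5% relative measurement noise.

Records are drawn in base-signal space, never in derived-parameter space,
so every definitional identity holds by construction and the parameter
matrix inherits realistic inter-parameter correlation from shared base
signals (its singular spectrum shows two exact null directions and ~5
dominant latent dimensions). Per (temperature, day) cell the profile
fixes a target Fv/Fm and a severity tier: day 0 is unstressed (0.84);
colder/longer exposure deepens the tier (8 °C turns severe from day 2;
14 °C stays slight until day 4). The cell target blends the tier anchor
(0.84/0.65/0.45/0.15, weight 0.7) with a monotone temperature/day
trajectory (weight 0.3), so tiers form well-separated bands (gaps ≥ 0.1
in Fv/Fm, ≈7× the Fv/Fm noise sd) while preserving within-tier ordering
by treatment. Latent draws (Fv/Fm, Fo, Y(NO), Y(II), the Fo′ fraction)
are Gaussian with truncation by resampling (signals > 0, Fm/Fo ∈ [1.05,
10], Fo′ < F < Fm′; at most 100 attempts before erroring). At zero noise
every record hits its profile value exactly.

What it does **not** emulate: day-to-day autocorrelation within a plant,
instrument drift, heteroscedastic extremes at 8 °C, leaf-position
effects, or any specific empirical covariance structure — the
inter-parameter correlation is emergent, not fitted. Tests passing on
this generator therefore demonstrate the pipeline's algorithmic
correctness and its ability to recover planted class structure of
realistic shape, not field performance.

MDA samples scale expected content per class as (1, 1.1907, 1.2814,
1.6724) × a 12 nmol·g⁻¹ baseline (a typical unstressed leaf value), with
the assay's N = 5 ml, W = 0.5 g and D532 solved from the target so zero
noise reproduces the ratios exactly. RLC yields scale baseline saturating
curves per class — Y(I) and the Y(I)−Y(II) gap down, Y(ND) up —
multiplicatively over the PAR gradient (0…2256 μmol·m⁻²·s⁻¹), so the
planted percent changes hold at every light level; the baseline Y(ND)
curve is capped at 0.45 so the severe-class scaling stays below 1.

## Numerical choices and problem sizes

Default tolerances: FCM tol 1e−5, max 300 iterations; objective
monotonicity asserted to 1e−12; membership row sums to 1e−10. The FCM
oracle test compares against a dense 201-point grid search (with analytic
memberships, polished by Nelder–Mead) on 1-D instances of n ≤ 6 — small
enough for the oracle to be exhaustive, large enough to exercise local
minima, with multi-restart FCM since a single run is only a local
optimizer. Pipeline-level checks use the default 192-record cohort, 10
seeds for clustering comparisons and 20 for GA recovery; these sizes keep
every property comfortably resolvable (ARI, error orderings) at
interactive runtimes.

## Known limitations

- Severity classes are relative to the cohort being clustered; the model
  does not transfer calibration across cohorts.
- The GA uses raw roulette selection as specified; with near-uniform
  fitness its late-stage convergence is slow, which is acceptable for an
  initializer but would be a poor stand-alone optimizer.
- UMAP with n_neighbors = 5 on small cohorts can occasionally split or
  bridge a tier for some seeds; the variant comparison reports per-seed
  diagnostics so such runs are visible.
- The 3σ leave-one-out filter is strict on 8-plant groups (see above);
  use the global mode for small cohorts if retention matters.
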