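# Methods

## Data model

A trial panel is a long-format table of plot-level observations with key
(genotype, season, treatment, replicate) and a percent pollen viability value
in [0, 100]. Exactly two treatment levels exist, `normal` and `stress`;
labels are normalised case-insensitively and anything else is a validation
error rather than a silent coercion. Viability of exactly 0 is legal (fully
sterile pollen under severe stress is a real outcome). Unbalanced panels are
accepted at I/O and means level but flagged; the ANOVA refuses them (below).
The optional registry maps genotypes to release year, breeding era and
pedigree; advanced lines without a release year remain era-unassigned.

## Susceptibility index

The index inputs are genotype means over replicates within a season; grand
means are unweighted means over the genotype means, restricted to genotypes
with both treatment means present (genotypes with a zero normal mean are
excluded from both the grand means and the classified set, and reported in an
exclusion list rather than dropped silently). Each season is screened against
its own grand means, not against values pooled across years: the published
per-year index pairs are separate per season, and pooling would mix panel
responses of different severity.

The published class bounds leave [0.99, 1.0) unassigned ("0.5–0.99" versus
"> 1.0"). We close the partition with half-open intervals: tolerant on
(−∞, 0.5), moderately tolerant on [0.5, 1.0), susceptible on [1.0, ∞). This
is contiguous, order-preserving, and matches the evident intent. Negative
index values (a genotype that improved under stress while the panel declined)
are retained and classed tolerant; discarding them would bias class counts.
Both cut points are configurable at the screening and CLI level.

Two exact identities are worth noting and are used as tests: the index is
invariant to rescaling all viabilities by any c > 0, and the normal-mean-
weighted average of the index over the classified panel is identically 1.
The second identity has a practical consequence: no panel consisting solely
of below-average (HSI < 1) genotypes can exist, which is why the published-
table fixture (below) carries susceptible anchor genotypes.

## Factorial ANOVA

The combined model is `y = μ + Treatment + Year + Genotype +
Treatment:Genotype + ε`, all factors fixed, with no block term and no
Year×Genotype or Year×Treatment terms — that residual pooling is the only
decomposition under which the published degrees-of-freedom column
(1, 1, G−1, G−1, N−1−2(G−1)−2) adds up for a G × 2 × 2 × 3 design. In the
balanced layout the sources are orthogonal, so sums of squares are computed
directly from marginal and cell means and add exactly to the total; each F
statistic is MS_source / MS_residual with an upper-tail central-F p-value.
Zero residual variance yields an infinite-F sentinel rather than an error.

Only balanced panels are analysed. The expected-mean-square algebra behind
the variance components holds only under balance; approximating it on
unbalanced data (Type I/II/III machinery, REML) would change the estimand,
so unbalanced input is refused with the offending cells named. Sums use
numpy's pairwise summation, which keeps the additivity identity tight at
panel sizes of 10⁴ records.

## Variance components and genetic parameters

From the per-condition one-way genotype ANOVA, σ̂²e = MS_error and
σ̂²g = (MS_genotype − MS_error)/r, clamped at zero with a truncation flag
(under a null genotype effect the clamp fires about half the time; this is
expected method-of-moments behaviour, not a defect). The two seasons pool by
default, making r the per-genotype observation count (replicates × seasons);
pooled error then absorbs season variance, which lowers heritability
estimates slightly relative to a single-season analysis — a per-season
option is provided.

Phenotypic variance defaults to the plot basis σ²p = σ²g + σ²e, the usual
convention in coefficient-of-variation studies following Allard, and the more
conservative (lower-heritability) of the two common choices; the genotype-
mean basis σ²g + σ²e/r is a switch. PCV% and GCV% are 100·√variance/mean;
broad-sense heritability is σ²g/σ²p; genetic advance is GA = k·√σ²p·h² in
trait units (percent viability), with the standardized selection differential
k = 2.06 (5% selection intensity) configurable. GA as a percent of the mean
is reported as an extra column, not the headline value.

## Descriptive summaries

Viability bins default to the decade bins 100, 90–99, …, <60, with genotype
means rounded to the nearest integer percent before binning (the bins are
integer-labelled); unrounded binning is an option. Index–viability
correlations are Pearson r with two-sided t-transform p-values, pairs aligned
by genotype and season; when every genotype shares one normal mean the index
is affine decreasing in stress viability and r(hsi, stress) = −1 exactly,
which serves as a closed-form test. Breeding eras derive from release year
with default cuts at 1965 (start of post-green-revolution) and 2001 (start of
modern); the cuts are configuration, not constants, since era definitions
vary between programmes. Era summaries are computed on season-averaged index
values per genotype, and the underlying per-era value table is the canonical
output (violin-plot rendering is cosmetic and untested).

## Synthetic trial generator

Observations are drawn from
`y = μ + year_s − δ·1[stress] + g_i + gt_i·1[stress] + ε` with independent
Gaussian effects and residuals, then clipped to [0, 100]; clip events are
counted and a warning fires above 5% because clipping biases variance
estimates. Gaussian-with-clipping was chosen over a logit-scale model
because it matches the percent scale of the real assay, keeps closed-form
truth for every estimand, and clipping is monitorable. The random stream is
split per component (genotype effects, season effects, residuals, registry),
so changing the replicate count does not reshuffle genotype effects, and a
fixed seed reproduces the panel byte for byte.

Defaults emulate the screening-study conditions: 200 genotypes, 2 seasons,
2 treatments, 3 replicates, grand mean μ = 90% viability, stress decrement
δ = 8 points, σ²g = 8, σ²gt = 4, σ²year = 2, σ²e = 4 (squared-percent
units). The interaction variance acts only under stress, so stress-condition
genetic variance exceeds the normal-condition value by construction; the
implied plot-basis heritabilities are 8/12 ≈ 0.67 (normal) and 12/16 = 0.75
(stress) — moderately-to-highly heritable, as pollen viability behaves in
field screens — and typical values stay
inside [0, 100] with under 1% clipping. Truth records the latent effects,
the true per-condition heritability, and a noise-free index per genotype
computed from expected season-averaged means, plus the implied tolerant set.

What the generator does not emulate: spatial field autocorrelation and block
effects, weather-driven stress severity, non-Gaussian assay error (counting
error on a bounded scale), and genotype-by-year interaction. Passing
recovery tests on this generator therefore demonstrates correctness of the
estimators under the stated model, not robustness of the index to field
artefacts.

## Published-table fixture

The fixture panel reconstructs the 12 cross-season heat-tolerant genotypes
from their 24 published per-season index values by inverting the index
formula: all genotypes get a normal mean of 95% and stress means
x_n·(1 − HSI·D̄) at a chosen panel mean reduction D̄ = 0.10. Because the
panel-weighted mean index is identically 1, four synthetic susceptible
anchor genotypes (named `ANCHOR-k`, clearly not real cultivars) are added
with index values solving the closure condition, so that screening the panel
reproduces each published value exactly and the cross-season tolerant
intersection is exactly the 12 published names. One naming discrepancy in
the source material ("MH-21" in the table, "MIH-21" in running text) is
resolved in favour of the table.

## Problem sizes in the validation suite

The simulation-based checks run at: 200 random balanced designs (G ≤ 6,
S ≤ 3, r ≤ 4) for ANOVA oracle equivalence; 1000 null simulations at G = 20,
r = 3 for F-test calibration (99% binomial band around α = 0.05); 500
simulations at G = 200, r = 3 per heritability level {0.30, 0.50, 0.755}
for recovery (median within ±3 points); 1000 random mean-square draws for
the GCV ≤ PCV ordering. These sizes give Monte-Carlo error comfortably
below the asserted tolerances.

## Known limitations

* Balanced designs only; no mixed-model or REML path for unbalanced data.
* Fixed-effects ANOVA throughout; genotypes are not modelled as random
  beyond the method-of-moments component extraction.
* Single trait; no multi-trait indices (STI, GMP) though the structure
  admits them.
* No narrow-sense heritability: the design cannot separate additive from
  non-additive genetic variance.
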