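# Methods

## The model

The package rests on the strict-molecular-clock approximation: along any
lineage, substitutions accrue at a constant rate μ (substitutions per site
per million years). For two species whose most recent common ancestor
(MRCA) has age t, the expected uncorrected p-distance — the fraction of
differing sites among pairwise-comparable aligned positions — is, under the
Jukes–Cantor model,

    E[p] = 3/4 · (1 − exp(−8μt/3)),

which is ≈ 2μt while 2μt ≪ 1 and saturates at 3/4. In the unsaturated
regime, divergence time is therefore (approximately) linear in distance:
with x in percent and y in My, y ≈ x / (200μ). The calibration step
estimates that line empirically from species pairs with published node
ages, without needing to know μ; placement inserts a new taxon's distance
into the line. The estimate is a *minimum* divergence time: p-distance
concavity (multiple hits) biases deep predictions downward, never upward.

## Distances

p-distances use **pairwise deletion**: a column contributes to a pair only
when both rows carry an unambiguous A/C/G/T there; gaps, `?`, `N` and all
IUPAC ambiguity codes are missing data. `U` maps to `T` and input is
upper-cased. Complete deletion (drop a column when *any* row is missing)
is available via `deletion="complete"`; the two agree whenever missingness
is identical across rows. A pair with no comparable sites is *missing*
(never 0) and is excluded from range summaries with a logged count; pairs
below 50 comparable sites warn, because a percent estimated from so few
sites is unstable (binomial SE at p = 0.05, m = 50 is ±3 percentage
points). Species summaries report min–max of 100·p over all
cross-individual comparisons, rounded half-away-from-zero to 1 decimal —
the display convention of published distance tables; fractions are kept at
full precision internally and for the matrix CSV.

## Chronograms

Node ages are tree height minus root distance; tips within a relative
tolerance ε (default 1e-6) of the maximum path are snapped to age 0
(extant). Ultrametricity is checked as (max − min root-to-tip path)/height
≤ ε and violations warn rather than fail, since published trees are often
rounded. Divergence time of a pair is the age of its MRCA; with a species
map, the MRCA of the union of the two species' tips is used, and a
non-monophyletic species warns (the union MRCA never underestimates the
pair time). A `cherries_only` flag restricts the pair table to pairs whose
joint MRCA subtends no third taxon — the node-defining pairs — since which
pairs a published regression used is often unstated; the default is all
pairs. All pairs of an ultrametric tree are mutually constrained (the
three-point condition), and species-pair times are phylogenetically
non-independent; like the workflow it implements, the default regression
ignores this.

## Calibration and prediction

Unconstrained fits use closed-form OLS with centred R² = 1 − SSres/SStot.
Through-origin fits use slope = Σxy/Σx² with **uncentred**
R² = 1 − SSres/Σy²: with no intercept the centred formula can exceed 1 or
go negative and is not comparable across modes. The x value for a
calibration pair defaults to the midpoint of its percent range (`min` and
`max` are available), matching the convention of summarising a published
min–max range by its mean. Prediction uncertainty defaults to the ordinary
regression prediction interval at 95% (t-quantile, n−2 df unconstrained,
n−1 through origin; needs ≥3 points and a fit carrying its data); a fixed
half-width in My can be supplied instead to mirror the convention of
reading uncertainty bars off a published figure. Negative bounds are
clipped to 0 and flagged. Display rounding is 0.1 My; machine-readable
output keeps full precision.

The placement report contains both fits and both predictions. The
unconstrained line is the headline (it is the form quoted in the empirical
workflow this package operationalises), but on clock data the truth passes
through the origin and the through-origin prediction avoids propagating
intercept-estimation noise into small-distance predictions — see
*Validation*, below. The "pre-dates the Quaternary" flag compares the
interval's lower bound (or the point, by option) to 2.58 My, the ICS value
for the base of the Quaternary.

A leakage guard enforces that the focal taxon never informs its own
calibration: placement refuses a chronogram that contains the focal
species, and all focal pairs are excluded when joining the distance and
time tables.

## The simulator

`simulate_yule_chronogram` draws a pure-birth tree forward from the crown
split (waiting times Exp(λk), uniform lineage choice, observed one wait
after the n-th species) and rescales branch lengths so the crown age is
exact; the result is ultrametric to floating-point accuracy.
`simulate_alignment_jc` evolves a uniform-random root sequence down the
tree, substituting each site with probability (3/4)(1 − e^(−4μb/3)) per
branch of length b, uniformly to one of the other three bases — so each
pair's mismatch count is exactly Binomial(L, E[p]) given the tree, and the
closed form above is an analytic oracle. Conspecific individuals radiate
from a star ancestor at a fixed shallow depth on the terminal branch
(default 5% of crown age, capped at 90% of that branch): two parameters
fewer than a coalescent, yet enough to produce realistic within-species
percent ranges. All randomness flows from one seed through one generator,
and scenario files are written in the exact formats the pipeline reads
(FASTA/Newick/TSV), so tests exercise the real I/O paths.

Default conditions (12 species, 2 individuals each, crown 30 My,
μ = 5×10⁻⁴/site/My, L = 1600 sites, λ = 0.2/My) emulate a single
mitochondrial fragment across a small radiation: intraspecific distances
well under 1%, interspecific from under 1% to a few percent, far from
saturation. What the simulator deliberately lacks: rate heterogeneity
across sites or lineages, indels and alignment error, non-JC base
composition, and coalescent gene-tree/species-tree discordance. Passing
the synthetic validation therefore demonstrates that the *pipeline's
statistics are correct under its own assumptions*, not that those
assumptions hold for any particular real locus.

## Validation, problem sizes, and what the numbers mean

- The distance engine is checked entry-wise against a naive double-loop
  recount on random alignments up to 20 × 200, plus hand-counted fixtures.
- Pair times are checked against dendropy's patristic distances (halved)
  on Yule trees up to 64 tips, and every tip triple must satisfy the
  three-point condition.
- Regression fits are checked against `numpy.polyfit` and against ±δ
  perturbation of the residual sum of squares; prediction intervals match
  `statsmodels` OLS prediction intervals.
- Simulator calibration: at L = 10,000, ≥99% of pairs fall within 3
  binomial SEs of the JC expectation (marginally each pair's mismatch
  count is exactly binomial, so ~99.7% is the theoretical coverage).
- Held-out recovery: 20 scenarios (10 species, L = 2000, μ = 5×10⁻⁴, crown
  30 My). At these sizes a single pairwise distance carries binomial noise
  of ≈0.19 percentage points ≈ 2 My on the time scale, and Yule trees
  produce many young splits, so relative error on young focal taxa is
  dominated by that noise floor. The *through-origin* prediction achieves
  median relative error ≤ 20%; the unconstrained prediction is noticeably
  worse for young focals (typical median ≈ 0.24) because the fitted
  intercept (SE ~0.5 My here) is a large fraction of a small prediction —
  a known cost of the headline convention, inherited by design.
- Slope recovery: the through-origin slope at L = 5000 is compared to the
  strict-clock value 1/(200μ) = 10 My/percent as a mean over 8 replicate
  simulations; pairs on one tree share branches, so a single replicate has
  ~7% tree-level noise while the mean is stable (and slightly above 10, as
  p-distance concavity shrinks x at deep nodes).

These sizes keep the full test suite under ~10 s on one CPU while leaving
each check statistically meaningful.

## Known limitations

- The calibration transfers any bias of the source chronogram directly
  into predictions; distances are topology-free, but the y-axis is not.
- Species-pair points are non-independent (shared phylogenetic history);
  prediction intervals are therefore approximate.
- No distance correction is applied (by design — the method is defined on
  uncorrected p), so deep placements are compressed toward the present.
- Ties and non-monophyly are warned about, not resolved.
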