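# Methods

## Read-depth copy-number genotyping

A diploid copy number is estimated as `DCN = 2 × unit_DOC / genome_DOC`,
where `unit_DOC` is the arithmetic mean per-base depth over the repeat-unit
interval (zero-depth positions included) and `genome_DOC` is the mapped-base
total divided by a reference length supplied by the caller (default
3.1 Gb; whether unplaced/decoy contigs belong in the denominator depends on
the mapping target, so the length is a logged configuration value, never a
constant).  Depth input is three-column pileup text (contig, 1-based
position, depth); positions absent from the file inside the declared
interval are depth 0, matching pileup tools that omit zero-coverage sites.
The repeat-unit interval (hs37d5:7,361,154–7,366,066) and the single-copy
right-junction control (17:41,400,862–41,401,838) ship as named defaults.

DOC is a mean, not a median, so it equals the pileup base count divided by
interval length.  No GC-bias correction is applied by default; coverage
dips in GC-extreme repeat units bias DCN (small arrays slightly under-,
large arrays slightly over-estimated in practice), and an optional linear
recalibration fitted from truth pairs (`linear_recalibration`) is provided
for users who have an orthogonal truth set.  Validation statistics are
ordinary least squares (r², slope, intercept) and Kruskal–Wallis H with
average ranks and the standard tie correction (df = groups − 1; the
chi-squared tail p-value is available separately).

## Lineage accounting

Each founder-mutation group is a star phylogeny: member families radiate
independently from the MRCA, each along one branch of `g_mrca`
generations.  The ancestral array size is the allele carried by the most
families (ambiguous sets, e.g. `{13, 35}` from an unphased heterozygote,
count toward every member allele; ties are reported and provably yield the
same generation counts under either resolution).  Accounting:

* `T0` = all observed unchanged within-family meioses
  + (ancestral-allele families × g_mrca), summed over groups;
* one mutated lineage of length `g_mrca` per non-ancestral family.

Within-family meiosis counts are inputs (published totals cannot be
re-derived from partial pedigrees); for fully genotyped pedigrees
`count_meioses` counts each genotyped parent→child pair whose transmitted
allele is identifiable by Mendelian tracing — a documented rule, not a
claim about how any published per-family total was obtained.

The minimum-event count per group is (distinct resolvable alleles − 1):
families sharing a derived allele are parsimoniously assigned one shared
event, while an ambiguous set merges with any resolved allele it
intersects and otherwise counts as a single unknown allele.

## Poisson star-phylogeny rate likelihood

Mutations on a lineage of t generations are Poisson(μt); reversions are
neglected (at the rates and timescales involved, a back-mutation to the
exact ancestral copy number within an observed lineage is second-order).
The likelihood multiplies `P(X_T0 = 0)` with `P(X_tj ≥ 1) = 1 − e^(−μ tj)`
per mutated lineage — always the exact zero-truncation, never a
single-event approximation.  Lineage terms are evaluated with `expm1` so
small μt loses no precision.

The score `−T0 + Σ tj/(e^(tj μ) − 1)` is strictly decreasing, so the MLE
is the unique root, found by Brent bracketing on [1e-8, 1] to relative
tolerance 1e-12 (a tighter and better-conditioned route than maximizing
the likelihood directly; the test suite keeps an independent 10⁶-point
grid maximization as an oracle).  The likelihood depends on the data only
through μ·t, hence scaling every count by k scales μ̂ by 1/k exactly —
asserted as a property test.

Wald intervals are built in λ = log μ: the likelihood in μ is visibly
skewed and the normal approximation works far better on the log scale.
At the MLE, `d²ℓ/dλ² = μ̂² ℓ''(μ̂)` (the first-order term vanishes with the
score), giving the analytic observed information
`I(λ̂) = μ̂² Σ tj² e^(tj μ̂)/(e^(tj μ̂) − 1)²`; a central-difference Hessian
(h = 1e-4) cross-checks it in the tests.  The z quantile is 1.959964 at
level 0.95.  The interval `exp(λ̂ ± z·I^(−1/2))` is log-symmetric:
`sqrt(lower × upper) = μ̂` by construction.

Because the MRCA ages are themselves estimates with CIs, a sensitivity
envelope rebuilds the generation counts twice — every age at its upper
bound (maximum exposure → smallest rate) and every age at its lower
bound — refits MLE and interval for each, and reports the outer envelope.
Which bound maps to which envelope end is a design choice of this package;
other combination rules (e.g. per-group extremes) would give slightly
different envelopes.

## Stepwise-mutation-model θ estimators

`θ̂_x̄ = 1/(8x̄²) − ½` uses the mean allele frequency, which for any
spectrum equals exactly `1/n_A`; the exact reciprocal is used rather than
a rounded decimal (with 53 alleles, 1/53 gives 350.6 while the 4-d.p.
rounding 0.0189 gives 349.4 — a documented sensitivity).  `θ̂_NA` inverts
the simulation-calibrated expectation
`n_A = (c₀ + c₁ ln θ + c₂ ln²θ)·√(1 + 2θ)` with the n = 500 coefficients
(c₀ = 2.0357, c₁ = −0.07910, c₂ = −0.00007).  That curve is **not**
monotone over the full bracket [1e-3, 1e7]: the logarithmic factor
dominates as θ → 0 and the curve turns up again below its minimum near
θ ≈ 0.04, a region far outside the calibration's intent.  The root is
therefore taken on the increasing branch only, after verifying
monotonicity there on a log grid; an allele count below the curve's
minimum raises an explicit bracketing error.  Applying the n = 500
calibration to nearby sample sizes (e.g. n = 504) is standard; a mismatch
beyond 20% warns rather than errors.

Both estimators assume single-step mutation with no directional bias.
Macrosatellite mutations are mostly multistep, which inflates allelic
diversity per event and is the expected reason the two estimators
disagree with each other on real data; they are reported for
order-of-magnitude comparison against `4Nₑμ̂` only.

## Haplotype-decay MRCA age

For each marker at recombination fraction rᵢ from the disease locus
(Haldane map function on cM distances; 1 cM = 1 Mb by default, or linear
interpolation between known anchor points), the ancestral allele survives
G generations with probability `ρᵢ = ((1 − rᵢ)(1 − marker_mu))^G`.  The
relative likelihood of a haplotype (descended vs independent) multiplies
`ρᵢ·1{allele = ancestral} + (1 − ρᵢ)·pᵢ(allele)` over markers and divides
by `Π pᵢ(allele)`; missing markers contribute 1.  Unphased carriers are
expanded into all genotype-consistent haplotypes (guarded at 2²⁰),
weighted by the partner haplotype's population probability under marker
independence and normalised per individual.  G is maximized over integers
(default 1–500, generations being discrete), and the support interval is
the outermost G within 0.86 log10 units of the maximum — the printed
convention for a ~95% support region, kept as 0.86 even though
3.84/(2 ln 10) ≈ 0.834.

Markers are treated independently given descent status.  This ignores the
contiguity of the surviving ancestral segment (a recombination event
removes a whole flank, not one marker), which makes the likelihood
slightly over-confident on real, densely linked maps; with the 17-marker
3.2 Mb maps used here the support intervals still cover the truth in
≥ 90% of simulated replicates.  Population growth and allele-frequency
drift over G generations are not modelled.  The default per-marker
mutation rate is 0 (SNP markers).

## Synthetic-data generators

All generators take an explicit integer seed and are deterministic given
it.  They emulate, in order of the pipeline:

* **Depth tracks** — independent per-base Poisson depth with mean
  `genome_DOC × CN/2 × gc_bias_factor` (default interval length 4913 bp,
  the repeat-unit default).  No mappability structure, read-length
  correlation or reference bias: recovery tests show the estimator is
  unbiased under the sampling model, not that real coverage is unbiased.
* **Star transmissions** — the study design as shipped
  (`PAPER_STAR_DESIGN`: one private family with 17 meioses; four founder
  groups of 2–4 families at ages 87/73/61/72 with the published meiosis
  counts); each branch draws K ~ Poisson(μg) events applied sequentially,
  each meiosis K ~ Poisson(μ).  Meioses with a visible copy-number change
  are reported separately (`mutated_meioses`) and become length-1 mutated
  lineages in `observed_generation_counts`, exactly as an observer would
  score them; a meiosis whose events cancel to no net change is counted
  as clean, and a family branch mutating onto another family's allele
  merges with it — both are honest estimator-facing artefacts, not bugs.
* **Coalescent SMM spectra** — Kingman genealogy of n lineages (time in
  units of 2Nₑ generations), mutations Poisson with rate θ/2 per lineage
  per time unit (the convention matching θ = 4Nₑμ), default ±1 steps.
  Constant population size only.
* **Haplotype decay** — ancestral-allele survival per marker with
  probability ρᵢ, otherwise a draw from population frequencies; phased
  output, weight 1.  This is sampling from the estimator's own model, so
  the recovery tests check calibration, not robustness to model error.
* **Pedigrees** — a descending-line template (founder couple, sibship
  sizes per generation, married-in spouses from a founder allele pool)
  with per-meiosis mutation probability 1 − e^(−μ).

The default mutation step distribution is a symmetric geometric over
±{1, 2, …} with success parameter 0.2 (mean absolute step 5 units),
reflecting that observed macrosatellite mutations usually involve many
units; the θ-estimator tests switch to strict ±1 steps, the estimators'
home model.  Copy numbers are floored at one unit (a zero-copy array
would be invisible to the assays being emulated).

## Problem sizes and numerical conventions

Simulation studies in the test suite use: 100 depth-track replicates per
true copy number ∈ {10, 40, 94}; 500 star-transmission replicates at
μ = 5 × 10⁻³; 200 haplotype-decay replicates per G ∈ {30, 73, 87} with 30
carriers on a 17-marker map; 200 coalescent spectra at θ = 400, n = 500 —
sizes at which the Monte-Carlo error of each checked statistic is well
inside its assertion band.  Root/score solves use Brent's method (rtol
1e-12 for the rate, 1e-10 for θ); ties in the integer G search resolve to
the smallest G; degenerate inputs (no mutated lineage, monomorphic
spectrum, empty groups) raise explicit errors rather than returning
boundary values.
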