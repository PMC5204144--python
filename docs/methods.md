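# Methods

## Data model and selection

The pipeline operates on stem-level census records: one row per stem per
census with date, diameter at the point of measurement (POM), POM height,
alive flag, a tape/non-tape measurement flag and — at a POM-change census —
the diameter at the new POM. Dates are decimal years; intervals are plain
differences (the sub-day error of ignoring leap days is orders of magnitude
below diameter measurement noise).

Plot selection follows the standard envelope for lowland moist forest:
annual precipitation ≥ 1300 mm yr⁻¹ and elevation < 500 m. The
precipitation bound is applied inclusively (sites at exactly 1300 mm are the
lower edge of the intended gradient). Plots passing the static criteria but
monitored for less than 2 years remain available for wood density and
potential size, and are excluded only from the growth/mortality subset.
Stems not identified to genus are dropped. The exclusion log plus the kept
set exactly partitions the input — a property the tests enforce.

## Trait derivation

**Effective diameters.** When a tree's POM moved, the census where it moved
contributes the arithmetic mean of the old-POM and new-POM diameters; other
censuses pass through unchanged. A POM change recorded without the new-POM
diameter is an error, not a guess.

**Growth.** Per census interval, annualized growth is Δsize/Δyears, with
size measured as diameter, basal area π(D/200)², or above-ground biomass
(AGB). The biomass conversion applies the same allometry at both interval
endpoints with constant wood density and E — only D changes. Stem mean
growth averages the interval rates; stem maximum growth takes their
maximum. Excluded from growth (but not from size): palms (no secondary
growth), stems with negative mean diameter growth, stems with any interval
above 8 cm yr⁻¹ (recording errors), and stems with any non-tape
measurement. The 8 cm yr⁻¹ cut is applied per interval while the negative
cut uses the stem mean, because the two rules target different artefacts
(a one-off recording error versus systematic shrinkage/damage).

**Genus aggregation.** Potential size is the 95th percentile of the
per-stem maximum sizes; maximum growth is the 95th percentile of stem
maximum growth; mean growth is the arithmetic mean of stem mean growth.
Quantiles use linear interpolation at h = (n−1)p + 1 (the default in most
scientific software; no alternative is mandated by the problem). Size and
growth traits require ≥ 20 stems per genus after exclusions. The ×wd
variants multiply the genus size value by genus mean wood density.

**Allometry.** Tree AGB:
ln AGB = c₀ + c₁E + c₂ ln wd + c₃ ln D + c₄(ln D)², defaults
(−1.803, −0.976, 0.976, 2.673, −0.0299) from the pan-tropical
diameter–density–environment model of Chave et al. (2014); palm AGB uses
the diameter-only Arecaceae model of Goodman et al. (2013),
ln AGB = −3.3488 + 2.7483 ln D. Coefficients live in configuration with
provenance strings, not in code, and are overridable per run. The (ln D)²
term makes the tree curve non-monotone at absurd diameters; no clamping is
applied because census inputs are bounded.

**Mortality.** Stem i survives its monitoring period tᵢ (first to last
census) with probability exp(−mᵢtᵢ); the log hazard is
ln mᵢ = α_g + β·zᵢ with zᵢ the standardized log initial diameter and β
shared across genera. The Bernoulli likelihood is maximized jointly
(L-BFGS-B with an analytic gradient); standard errors, when requested, come
from the observed information (central differences of that gradient). In
the equal-time, no-covariate case the MLE collapses to −ln(s̄)/t, which the
tests assert to 1e−8. Genera with zero deaths sit on the likelihood
boundary and are reported as 0 % yr⁻¹ with a flag. The reported genus rate
is 100 × the mean fitted hazard over the genus's stems. Genera require
≥ 100 stems. No plot random effects enter the mortality model; the output
manifest records this (`mortality_plot_random_effects: false`).

**Plot adjustment.** Systematic plot differences are removed with a linear
mixed model on the log scale: log(value) ~ genus (fixed) + plot (random
intercept), fitted by ML (not REML — deterministic and comparable across
nested fits). Mean-type traits report the back-transformed genus effect
(the value at an average plot); percentile-type traits subtract the BLUP
plot offsets from the log stem values before the genus quantile is taken.
With a single plot (or a boundary/singular random-effect fit) the
unadjusted values are returned with a warning. Both adjusted and unadjusted
values are written, along with their Kendall rank correlation per trait.
By default only the diameter-scale traits are adjusted
(`adjust_metrics=("d",)`); basal-area and biomass scales are near-monotone
transforms of the diameter scale, and one representative per family keeps
the result tables and mixed-model fits compact. The tuple is configurable.

**Intrageneric SEs.** Genus SE = sd/√k over the k ≥ 2 species-level values
of that trait; genera with fewer species receive the mean SE of the
multi-species genera. Species-level size/growth values require ≥ 20 stems
per species; species-level mortality values (which exist only to feed these
SEs) use a closed-form rate per species with ≥ 20 stems rather than the
full joint model — a deliberate simplification, since a 100-stem
species-level threshold would leave almost no genus with two estimates at
realistic sample sizes.

## Phylogenetic signal

The phylogenetic covariance C has Cᵢⱼ = shared root-to-tip path length,
built by a single postorder traversal; trees are read force-rooted and must
have strictly positive branch lengths and ≥ 2 children at the root (a
basal polytomy is accepted; an explicitly unrooted flag cannot be
distinguished from one in plain Newick). Dropping tips subsets C directly —
pruning cannot change shared path lengths among the kept tips.

Blomberg's K follows the GLS formulation given in the README. The
error-aware variant estimates σ² by full ML (not REML; simpler, and the
choice is recorded in the result metadata) under covariance
σ²C + diag(se²), then evaluates the K formulas on the working matrix
C + diag(se²)/σ̂². If σ̂² collapses to the search floor the trait is
declared indistinguishable from its stated noise and an error is raised;
the pipeline records such traits as missing rather than fabricating a
value. With all-zero SEs the error-aware path reduces exactly to plain K.

Significance uses tip randomization: trait values (jointly with their SEs —
the pair belongs to the genus) are shuffled across tips 1000 times, and the
observed K is called significant outside the 2.5–97.5 percentile band. The
band is two-sided exactly as stated; no multiple-testing correction is
applied across traits. A single seeded generator drives each run and the
seed is stored in every result.

Pagel's λ multiplies the off-diagonal of C; σ² is profiled analytically
(or optimized numerically when SEs are supplied) and λ is found by bounded
scalar search on [0, λ_max] with tolerance 1e−6, where λ_max is computed
from the matrix (largest rescaling keeping every tip variance above its
covariances, shrunk until the Cholesky factorization succeeds) rather than
assumed to be 1. Because the bounded search never touches the interval
endpoints, estimates within 10 tolerances of an endpoint are snapped to it
when the endpoint likelihood is at least as good. Both a likelihood-ratio
test against λ = 0 (χ², 1 df — conservative at the boundary) and the
log-likelihood are reported, since either convention is defensible.

## Phylogenetic PCA

Traits are standardized with ordinary (non-phylogenetic) mean and sample
sd first — each trait contributes equal marginal variance — and the GLS
phylogenetic mean is then removed inside the PPCA; the evolutionary
covariance S = (Z−1a)ᵀC⁻¹(Z−1a)/(n−1) is eigen-decomposed. Loadings are
unit-norm with each column's largest-magnitude element made positive
(determinism across LAPACK implementations); scores are the GLS-centred
data projected on the loadings. With C = I the whole construction reduces
element-wise to ordinary PCA, which the tests assert to 1e−10. The default
axis input is the four core traits (wood density, potential diameter,
maximum diameter growth, mortality), restricted to complete-trait genera.
PPCA axis scores carry no natural intrageneric SE, so their signal is
computed without one.

## Synthetic data

The generator emulates the structure of a lowland-Amazon plot network at
desk scale. Defaults: 100 genera on a Yule tree (birth rate 1), 10 plots of
1 ha, 3 censuses at irregular ~4.4 ± 1 yr intervals, 150 stems per genus,
initial diameters truncated log-normal (median 15 cm, floor at the 10 cm
census limit), genus mean diameter growth log-normal around 0.26 cm yr⁻¹,
stem-level log-normal growth heterogeneity (sd 0.5 on the log scale),
multiplicative plot offsets (log-sd 0.2), additive measurement noise
(sd 0.1 cm), genus log hazards centred on −4.5 (≈1.1 % yr⁻¹) with a shared
size slope β = −0.2, POM changes with probability 0.02 per surviving
census (5 % diameter drop at the new POM), 5 % palms, 0.1 % non-tape
stems, and genus wood densities centred on 0.61 g cm⁻³. These centres match
the magnitudes a basin-wide census synthesis reports for the same
quantities; the spreads are chosen so the exclusion rules and thresholds
are all exercised.

Genus-level parameters are driven by independent BM (or λ / shuffled)
traits evolved on the simulated tree, so phylogenetic signal propagates
from the tree through the census records to the estimated traits. Truth
tables store both the generating parameters and the realized per-genus
values (mean stem growth, mean hazard, 95th percentile of true maximum
size); recovery tests read generated truth, never hard-coded numbers, and
all outputs are bit-reproducible from (config, seed).

What the generator does **not** emulate: spatially structured environments
(E is a per-plot scalar), recruitment of new stems between censuses,
correlated trait evolution (the three parameter traits evolve
independently), diameter-dependent growth, and taxonomic misidentification.
Passing recovery tests therefore demonstrate estimator correctness under
the stated model, not robustness to these real-data complications. Genus
differences in potential size arise only through growth differences (all
genera share the initial-diameter distribution), so size traits carry
weaker signal than growth traits in synthetic data — visible in the demo
output as low naive K for `max_*` traits.

## Numerical and design choices

* All C-solves go through Cholesky factorization; a factorization is shared
  across the 1000 permutations of a trait (the permuted-K computation is
  fully vectorized when no SEs are involved).
* σ²-profile optimizations run on the log scale with bounded Brent search;
  permutation refits reuse the observed fit as a warm start at a slightly
  looser tolerance (1e−5) than the headline estimates (1e−6).
* Monitoring time for mortality runs first-to-last census per stem; stems
  recruited mid-series enter at their first record.
* Wood density is matched species-first, then genus mean; stems whose genus
  is absent from the density table fall back to the table-wide mean for the
  biomass allometry only, and the manifest counts them.
* The species-level sensitivity mode relabels stems by binomial and runs
  the identical machinery; the wood-density lookup still uses the true
  genus/species fields.
* Problem sizes in the test-suite recovery experiments (e.g. 500 BM
  replicates on 200 tips, 100 λ replicates per value on 300 tips, 5000-stem
  mortality recovery, 100-genus end-to-end run) are the package's chosen
  desk-scale study conditions: large enough for the Monte-Carlo intervals
  asserted, small enough to keep the whole suite in a coffee break.

## Known limitations

* The mortality model omits plot random effects; with strong plot-level
  hazard heterogeneity, genus rates absorb plot composition.
* The error-aware K treats intrageneric SEs as known, not estimated.
* The λ likelihood-ratio p-value is conservative at the λ = 0 boundary
  (the proper null is a χ² mixture).
* The plot-adjustment mixed model assumes a shared plot offset across
  genera (no genus × plot interaction).
* Adjusted mean-type traits are back-transformed log-scale effects
  (geometric-mean-like) while unadjusted means are arithmetic; the two
  coincide only without heterogeneity, which is why the identity test uses
  noiseless data.
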