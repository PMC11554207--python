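# Methods

## Scope and data model

The pipeline quantifies how far native freshwater fish assemblages have been
"contaminated" by non-native species in a long-term floodplain survey. Its
unit of observation is a *sampling unit*: one gillnetting or seining event at
one locality and campaign, with a sampled area in m². Catches are stored one
row per (unit, species) as an individual count and the summed weight of those
individuals — per-individual weights are never needed, because the biomass
density `B_j = W_j / A` depends only on the sum. A species registry assigns
each species to `native`, `non_native`, or `unclassified`.

Structural rules enforced by validation: positive sampled area; locality
codes drawn from the nine monitored sites, with the "l"/"r" prefix agreeing
with the lake/river habitat; seining occurs in lakes only; one record per
(unit, species); weight strictly positive whenever individuals were caught.
Validation is total — it collects every violation into a report instead of
raising — and a survey with errors is refused by the metric and trend layers.

Species of unclassified origin are kept in the tables but excluded from all
richness and biomass totals: the indices partition species strictly into
native and non-native, and silently assigning the unclassified to either
side would bias every index. Campaign season is the calendar quarter;
continuous time for trend fits is fractional years since the first campaign.

## Contamination indices

With `R_n, R_nn` the native/non-native richnesses of a unit and `B_n, B_nn`
the summed biomass densities:

* `CI_r = R_nn/(R_nn+R_n)` and `CI_b = B_nn/(B_nn+B_n)` — proportions of
  richness and biomass;
* `CI_e = R_nn·B_nn/(R_nn·B_nn + R_n·B_n)` — the "ecosystem" form, which
  amplifies whichever side dominates both richness and biomass (if every
  species weighs the same, `CI_e = x²/(x²+y²)` lies farther from ½ than
  `CI_r = x/(x+y)`);
* `CI_a = (CI_b + CI_r)/2` — additive mean;
* `CI_sq = sqrt(CI_b · CI_r)` — multiplicative form, implemented as the
  geometric mean. The geometric mean is the only reading consistent with
  published locality-average tables (e.g. component means of 0.64 and 0.55
  give a printed multiplicative value of 0.59 = sqrt(0.352), while the plain
  product would give 0.35) and with the AM–GM ordering `CI_sq ≤ CI_a` that
  those tables obey throughout; the plain product remains available via
  `ci_sq_form="product"`.

A zero denominator (an empty assemblage, or zero total biomass) makes an
index *undefined* (NaN). Undefined units are excluded from group means
rather than coerced to 0 or 1, because coercion would drag contamination
means toward whichever bound the empty units happened to fall on. Indices
are computed per sampling unit first and then averaged (mean ± sd, and the
median alongside), matching how locality-average tables are built. Report
tables round to two decimals, half away from zero.

## Kempton's Q and the biomass–richness correlation

For one assemblage (locality × campaign × origin class, gears pooled by
default) with per-species biomass vector `B` of length `R`,
`Q = (R/2)/ln(B_4/B_2)`, where `B_4` and `B_2` are the 75th and 25th
percentiles under linear interpolation between order statistics — the
estimator must be pinned down because Q's value depends on it. Q is
dimensionless, invariant to rescaling all biomasses, high when the
assemblage is rich and even, and undefined when the quartiles coincide
(e.g. all biomasses equal); undefined localities are skipped and counted
when averaging Q across localities per campaign.

The Spearman correlation between unit biomass and unit richness is the
Pearson correlation of mid-ranks (tie-corrected). Its two-sided p-value is
exact by permutation enumeration for n ≤ 8 and uses the t approximation
with n−2 df otherwise. A constant margin leaves rho undefined. Rho is
computed both per locality across campaigns and per campaign across
localities, pooling gears.

## Smooth temporal trends

The trend model for a response series (a CI, Q, rho, biomass, or richness;
seined biomass is log10(x+1)-transformed first to tame its heavy tail) is

    y = intercept + locality random intercept + f(time) + AR(1) error,

with `f` a cubic B-spline smooth (basis dimension 10, equally spaced knots,
second-order difference penalty, so straight lines are unpenalized) under a
sum-to-zero constraint for identifiability. Random intercepts are
ridge-penalized dummy columns — the standard "random effect as penalized
fixed effect" device — with their own shrinkage parameter. Both penalties
are chosen by generalized cross-validation with the Kim–Gu inflation
(gamma = 1.4), which guards against the undersmoothing that makes
smooth-term tests anticonservative.

The AR(1) coefficient phi is estimated by iterated feasible GLS against the
*parametric-plus-linear* model (Cochrane–Orcutt, tolerance 1e-4, at most 20
iterations), followed by the Orcutt–Winokur small-sample bias correction.
Estimating phi against the selected smooth instead was implemented and
measured first, and rejected: the data-driven smooth absorbs serial wander
into the trend, phi converges far below truth, and the smooth-term test
rejects a majority of pure-AR(1) nulls. Estimating against a deliberately
rigid mean is calibrated under the null; a genuinely curved trend inflates
phi somewhat, which errs on the conservative side. The final penalized fit
is computed on data whitened at a one-sided upper plug-in (phi + one
standard error, only when phi > 0), so that phi estimation noise cannot
leave positive correlation for the smooth to absorb. A fit that reproduces
the data essentially exactly sets phi to zero — there is no residual
process left to model.

Reported per fit: effective degrees of freedom of the smooth (trace of its
block of the influence matrix), reference df (tr(2A − AA) over the same
block), an approximate F comparing against the parametric-only model on the
whitened scale (numerator df = reference df), adjusted R², phi, and *beta* —
the OLS slope of the fitted values against time, in response units per
year, with its standard error. Beta is a deliberately scale-honest summary
of the smooth; it is not comparable to slope columns whose units another
analysis left unstated. Measured operating characteristics at the defaults
(and asserted by the test suite): type-I error 0.05–0.06 under iid noise
and ≤ 0.05 under AR(0.6) noise at n = 68; mean estimated phi 0.56 for true
0.6; exact recovery (≤ 1e-6) of noiseless linear trends with locality
offsets.

The Shapiro–Wilk normality gate is reported as metadata but the smooth
model is always fitted, so pipeline behaviour never branches on a
data-dependent test. Rank-sum comparisons (e.g. native vs non-native rho
distributions) use the Mann–Whitney U convention with exact enumeration for
n1+n2 ≤ 10 (valid under ties) and the tie-corrected normal approximation
otherwise, optionally after removing 1.5·IQR outliers (linear-interpolation
quartiles) — the outlier convention is ours, chosen as the boxplot default.

## Synthetic survey generator

The generator emulates the monitored design: 6 lakes + 3 rivers, quarterly
campaigns 2000–2017; gillnetting everywhere at a fixed 368 m² with four
campaigns skipped as ordinary field gaps (giving the design's 68 gillnetting
events per locality); seining in lakes from 2003 (60 events), with areas
drawn from N(247.69, 51.52²) truncated to the observed 30.2–367.09 m² range.
The community model:

* a regional pool of 42 native and 26 non-native species; regional mean
  abundance densities lognormal (mu = −3, sigma = 1.2 on the log scale,
  i.e. a median of ~0.05 individuals/m², giving tens of individuals per
  common species per gillnet set) and body masses lognormal (median 50 g,
  sigma = 1), identical across origins so that observation error cancels
  rather than biases the contamination indices;
* initial occupancy 0.75 for natives and 0.25 for non-natives per locality;
* each campaign, every absent non-native colonizes a locality with
  probability `0.02 × 1.08^(years) × 3 in flood years` (2010, 2011, 2015,
  2016); rivers are updated first and lakes can only be colonized by
  non-natives already resident in a river — rivers are the dispersal
  corridor;
* the rarest 10% of resident natives each face a 0.02 per-campaign local
  extinction probability;
* sampling draws negative-binomial counts (dispersion 0.5) around local
  abundance × area, after gear selectivity on body-mass quantile (gillnets
  retain the upper 75%, seines the lower 75%), with mean-one lognormal
  weight noise (sigma = 0.2).

Rates the emulated programme never published (colonization, acceleration,
flood boost, extinction, occupancies, dispersions) were fixed once at
values a field ecologist would call realistic for this system — they
produce a late-series crossover where non-native biodiversity overtakes the
native trend, the qualitative signature the design calls for. All are
config-exposed. Randomness flows from a single seed through per-locality
substreams; identical seed and config give byte-identical output.

What the generator does *not* emulate: hydrology (flood years are exogenous
labels), spatially explicit dispersal, species interactions, seasonal
abundance cycles, within-species body-size change, and mesh-level gear
selectivity curves. Passing recovery tests therefore show the pipeline
correctly measures communities with this covariance structure — not that
real assemblages satisfy it.

A `TrueState` records realized residents per locality and campaign, so
recovery tests can compare estimated CI_r with the true resident
non-native fraction (bias, RMSE, trend-sign agreement). One calibration
subtlety: a "null" community for type-I-error measurement must switch off
*both* colonization and native extinction — with extinctions active the
resident non-native *fraction* genuinely rises as natives are lost, and
detecting that trend is correct behaviour, not a false positive.

## Numerical choices and limitations

* Quantiles everywhere (Q, outlier fences) use linear interpolation between
  order statistics; GCV grids are log-spaced (1e−5–1e9 for the smooth,
  1e−8–1e6 for the random-intercept ridge) with ties broken toward heavier
  smoothing; penalized systems are solved directly (≤ 20 coefficients).
* Degenerate inputs: constant series leave Shapiro–Wilk, rho, and Q
  undefined (flagged, never silently zero); all-tied rank-sum comparisons
  return p = 1 with a warning; fits require ≥ 10 finite observations and a
  non-degenerate time span.
* The AR(1) structure is indexed within locality with campaigns in time
  order (ties kept in row order); whether it should instead nest within
  locality × gear is unresolved in the emulated design — fits are run per
  gear, which sidesteps the ambiguity.
* Group means of CI_a equal (mean CI_b + mean CI_r)/2 exactly, by
  linearity; this is used as an internal consistency check against
  published locality-average tables.
* Limitations: the trend layer's F test is approximate (penalized smooths
  have no exact finite-sample test); phi estimation against a rigid mean
  over-whitens genuinely curved trends, trading a little power for size
  control; Q is undefined for very even assemblages, which the
  campaign-mean skip rule handles but reports.
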