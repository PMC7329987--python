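# Methods

## Data model and conventions

A survey is four tables: plot factors (`ground_state` ∈ {control,
thermokarst}, `polygon_feature` ∈ {top, trough}, `transect_id`, `flooded`),
a plot × species percent-cover matrix (visual estimates, need not sum to
100), per-species per-plot phenophase Julian dates, and hourly 10-cm soil
temperatures. Julian dates are 1-based integer day-of-year; CWM dates are
real-valued. Reference levels are `control` and `top` (stable polar desert
is the baseline against which thermokarst change is measured). A missing
phenophase for a (plot, species) is the absence of the record, never a
sentinel. Plots flagged flooded (troughs submerged all season) are removed
from every table before analysis; the filter is idempotent.

## Thermal metrics

Daily means are arithmetic means of all hourly readings in a Julian day;
partial first/last days use whatever readings exist. TDD sums daily means
strictly above 0 °C — a day at exactly 0 °C contributes nothing. TDD is
interpreted as *relative* forcing over the logged window (Julian 179–200),
not absolute seasonal forcing, because loggers go in after snowmelt.

Cumulative TDD for a phenophase uses cutoff = ⌊CWM date⌋ and **includes the
cutoff day**. Whether the event day itself should count is genuinely open;
we include it on the grounds that the phenophase was expressed on that day,
and flag the exclusive variant as the first thing to toggle when reconciling
against an external benchmark. A cutoff before the first logged day returns
0 with a warning rather than an error: it means the event predates the
record, and the value is a defensible lower bound.

## Community-weighted means

Weights are total-standardized cover (each species / plot sum), computed
once from the full censused cover row and then renormalized per phenophase
over the species that actually carry a record. Species with cover but no
record for a phenophase are dropped from **both** the specific and the fixed
average, so specific − fixed is a pure within-species contrast — composition
enters both identically. Plots with no record at all for a phenophase are
excluded from that phenophase's analyses, which is what produces differing
residual df across phenophases. The alternative (keeping absent species in
the fixed denominator) is not implemented as a switch because it breaks the
exact intraspecific identity; reconciliation against external data should
instead compare plot sets.

Fixed species means are unweighted means over all plots where the species
has the record. Both CWM variants are convex combinations of their inputs
and are bounded by the contributing values; renormalized weights sum to 1
to ~1e−12.

## Type II inference on the unbalanced 2×2

After removing flooded troughs the design is unbalanced (20/20/20/15), so
main effects are tested with type II sums of squares: each term's SS is the
RSS difference between the nested least-squares fits excluding and including
that term, never adjusting a main effect for the interaction that contains
it. With a covariate (ANCOVA), the covariate is the most marginal term and
each factor SS conditions on the covariate. F statistics use the full-model
residual mean square; on balanced data type I, II and III coincide (verified
against statsmodels in the tests, which also serve as the independent
oracle for the nested-RSS arithmetic). Designs with an empty cell are
rejected with a rank-deficiency error rather than silently reduced, and
single-level factors and constant responses are explicit errors.

EMMs are model predictions on the 2×2 reference grid; with a covariate the
grid fixes it at its grand mean over analyzed plots (model scale, i.e. after
any ln transform), so the covariate cancels exactly in every cell contrast.
Main-effect EMMs average cell EMMs with equal weight. All six pairwise cell
contrasts get Tukey–Kramer adjusted p-values from the studentized range with
k = 4 and the full-model residual df; SEs come from the coefficient
covariance, reproducing √(MSE·(1/nᵢ+1/nⱼ)) for plain cell contrasts. For
k = 2 the adjustment is special-cased to the exact two-sided t p-value: the
studentized range at k = 2 reduces to |t|√2 analytically, and the closed
form is both faster and more accurate than numerical integration of the
range distribution.

Transforms: the initial-leaf-growth CWM response takes a square root before
ANOVA/ANCOVA, and cumulative-TDD predictors take a natural log in
regressions and ANCOVAs. Both are config switches (`sqrt_initial_leaf_growth`,
`ln_tdd`) defaulting on; p-values are never adjusted across phenophases or
analyses — only within a Tukey family.

The transect check fits the fixed-effects model with and without a transect
random intercept, both by maximum likelihood (not REML) so the AICs are
comparable; AIC = −2ℓ + 2k with k counting mean plus variance parameters.
At a zero variance estimate the models share a likelihood and ΔAIC = 2 in
favor of the plain model. Singular fits are reported via a flag, not raised.
REML remains available through statsmodels for users who want it, but ML is
the default because cross-family AIC comparison requires it.

## Variance decomposition

The specific-CWM ANOVA's SS is partitioned by fitting the identical type II
model three times: on the specific CWM (total), the fixed CWM (turnover: only
composition varies), and their per-plot difference (intraspecific). The
covariation column is the signed remainder total − turnover − intraspecific,
per term including residuals and the grand total, so additivity is exact by
construction — the difference response is formed *before* fitting, not by SS
arithmetic. Covariation is negative when composition change and
within-species shifts pull community timing in opposite directions. Any
response transform is applied to specific and fixed before differencing. A
response that is constant across plots (fixed CWM on a turnover-free
landscape) carries zero SS in every row rather than erroring.

## Synthetic landscape generator

The generator is first-class, tested code; its defaults are the study
conditions. Design: 4 cells × 20 plots on 5 transects; 5 thermokarst-trough
plots flagged flooded. Species pool of 22 with 5 species restricted to each
ground state and one generalist dominant (80% occupancy, ~60% cover);
occupancy and cover of the others scale with the match between a species'
moisture preference and the ground state's wetness, producing partial
turnover.

Soil temperature: daily-mean ramp 0.8 + 0.5·(d − 179) °C over Julian
179–200, additive state effect −1.1 °C/day (thermokarst) and feature effect
−1.4 °C/day (trough), a persistent per-plot microsite offset (sd 0.8 °C)
representing small-scale soil heterogeneity, a diurnal cosine (amplitude
3 °C) and hourly noise (sd 1.5 °C). These values put the expected state and
feature TDD marginal means near 118/96 and 121/93 °C·day — the observed
contrast between stable and degrading polygon terrain.

Phenology: each species × phenophase has a cumulative-TDD threshold
(site-level bases 8 / 23 / 12 / 26 °C·day for leaf growth, leaf out, flower
bud, open flower; per-species lognormal spread, sd 0.25, and a moisture
term making wetland species later). A species' date in a plot is the first
day the plot's realized cumulative TDD crosses its threshold, plus
intraspecific habitat shifts (default: +1.5 days in thermokarst troughs),
an optional transect intercept, and observation noise (sd 1.5 days, field
re-census every other day), floored to an integer. Crossings after the
window end are censored — no record — which reproduces the differing df
across phenophases. The threshold mechanism builds in the date–TDD
correlation the ANCOVA presumes, making that stage genuinely testable.

Randomness is one seed split into four named substreams (design, species,
thermal, phenology) in fixed order, so adding a table never perturbs
another; bundles are byte-identical under a repeated (config, seed).

Scenarios: `paper_like` is the defaults. The diagnostic scenarios zero
*all* thermal heterogeneity (state and feature effects and the microsite
offset), because any thermal variation propagates through the threshold
mechanism into within-species date variation and would contaminate the
component each scenario is meant to isolate: `turnover_only` additionally
zeroes the habitat shifts and doubles the wetland/dryland threshold
separation so composition change is the dominant systematic signal;
`intraspecific_only` copies one community to every plot (fixed CWM exactly
constant) leaving the configured trough delay as the only signal; `null`
removes turnover structure and all effects so dates are exchangeable across
cells and the interaction test's type-I error can be audited.

What the generator does **not** emulate: spatial autocorrelation beyond a
transect intercept, snowmelt timing as a separate cue, within-plot
micro-moisture gradients, observation error in cover estimates, and
phenophase ordering constraints within a species beyond what the shared
threshold bases impose. Passing tests therefore certify the statistical
machinery and its calibration under these idealized conditions, not the
field validity of any ecological conclusion.

## Problem sizes and numerical choices

Validation runs use full-size landscapes (80 plots): 100 landscapes for the
additivity and scenario-isolation checks, 1000 for the null-calibration
check, 50 random small unbalanced designs for the type II oracle check.
Least squares is `numpy.linalg.lstsq` on explicit dummy-coded design
matrices; SS are clipped at 0 against roundoff; additivity tolerance is
1e−8 relative (observed ~1e−16). Ties in the dominant-species choice break
by total cover. CSVs round-trip exactly (`%.17g` on write,
`float_precision="round_trip"` on read).

## Known limitations

- The ANCOVA conditions on a covariate that is itself derived from the
  response's CWM date (cumulative TDD up to the event), as the source
  analysis does; it is a descriptive adjustment, not a causal one.
- The mixed-model check considers only a random intercept; random slopes or
  spatial covariance structures are out of scope.
- Benchmark reproduction against the deposited field data requires the user
  to supply those CSVs (`thawpheno analyze` + `thawpheno report`); no data
  are bundled.
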