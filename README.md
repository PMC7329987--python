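# thawpheno

Thermokarst — the subsidence of ground over melting ice wedges — reshapes
high-Arctic polygon terrain into elevated *tops* and wet, subsided *troughs*,
and with it the soil climate that plants experience. `thawpheno` is a Python
package for analyzing how this microtopography shifts plant phenology. It is
aimed at plant ecologists and permafrost researchers working with plot-based
surveys: plot factors (ground state × polygon feature on transects), a plot ×
species percent-cover matrix, per-species phenophase dates (initial leaf
growth, first leaf out, first flower bud, first open flower), and hourly soil
temperature loggers.

## What it computes

**Thermal forcing.** Daily mean soil temperatures per plot, seasonal thaw
degree days TDD = Σ<sub>d</sub> T̄<sub>d</sub> · 1(T̄<sub>d</sub> > 0 °C),
and phenophase-specific cumulative TDD up to ⌊date⌋ (cutoff day included).

**Community-weighted means.** With relative abundances
w<sub>s</sub> = cover<sub>s</sub>/Σ cover, each plot × phenophase gets a
*specific* CWM (weighted mean of locally observed dates), a *fixed* CWM
(same weights applied to site-wide species mean dates), and their difference,
the *intraspecific* component.

**Inference.** `FactorialANOVA(response, plots, covariate=...).fit()` gives a
two-way type II ANOVA (or ANCOVA with cumulative TDD as the first covariate)
computed from nested-model RSS differences — the right decomposition for the
unbalanced design that remains after dropping permanently flooded trough
plots. The results object exposes estimated marginal means and all pairwise
cell contrasts with Tukey–Kramer adjusted p-values, plus `summary()`. Simple
regressions on ln cumulative TDD and an ML-based AIC check of a transect
random intercept round out the model set.

**Variance decomposition.** `VarianceDecomposition(specific, fixed, plots)
.fit()` partitions every ANOVA term's SS into species **turnover** (fixed-CWM
fit), **intraspecific** (difference fit), and their signed **covariation**
(remainder), with turnover + intraspecific + covariation = total exact by
construction.

**Synthetic landscapes.** `generate_landscape(scenario("paper_like"), seed)`
emulates the study design end to end — 80 plots in a 2×2 design, 5 flooded
thermokarst troughs, a 22-species pool with partial turnover between ground
states and one widespread dominant, TDD depressed in thermokarst and troughs,
and dates produced by a cumulative-TDD threshold mechanism — so the whole
chain runs with no download. Diagnostic scenarios (`turnover_only`,
`intraspecific_only`, `null`) isolate single drivers for validation.

## Worked example

```python
import thawpheno as tp

bundle, truth = tp.generate_landscape(tp.scenario("paper_like"), seed=1)
tables = tp.run_analysis(bundle)                # filters the 5 flooded plots

print(tables["tdd_emmeans"].to_string(index=False))
```

```
         factor       level     emmean       se
   ground_state     control 119.439285 2.959376
   ground_state thermokarst  97.382689 3.196492
polygon_feature         top 121.477203 2.959376
polygon_feature      trough  95.344771 3.196492
```

Control ground holds ~22 °C·day more thermal forcing than thermokarst, and
tops ~26 °C·day more than troughs, over the 22-day logger window. The colder
troughs delay community flowering:

```python
con = tables["contrasts"].query("phenophase == 'first_open_flower'")
print(con[["contrast", "estimate", "se", "p_adj"]].to_string(index=False))
```

```
                            contrast  estimate       se        p_adj
        control top - control trough -2.732012 0.549802 2.627921e-05
       control top - thermokarst top -3.021829 0.549802 3.392517e-06
    control top - thermokarst trough -6.358804 0.593854 0.000000e+00
    control trough - thermokarst top -0.289817 0.549802 9.522395e-01
 control trough - thermokarst trough -3.626792 0.593854 2.887982e-07
thermokarst top - thermokarst trough -3.336975 0.593854 2.080637e-06
```

Community open flowering in thermokarst troughs lags thermokarst tops by
~3.3 days (Tukey-adjusted p < 1e-5). The decomposition table
(`tables["decomposition"]`) then splits each effect between species turnover
and within-species delays, and `tables["ancova"]` asks whether microtopography
still explains variation once cumulative TDD is controlled for.

The same pipeline runs from the shell on real survey CSVs:

```bash
thawpheno analyze --plots plots.csv --cover cover.csv \
    --phenology phenology.csv --temperature temperature.csv --out results/
thawpheno report --results results/   # side-by-side with the published values
```

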