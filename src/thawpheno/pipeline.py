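"""End-to-end analysis pipeline.

Runs the full chain on a validated bundle: flooded-plot filter, thermal
summaries, CWM construction, the two-way type II ANOVAs with EMM/Tukey
contrasts, cumulative-TDD ANCOVAs, ln-TDD regressions, the transect
random-effect AIC check, the turnover/intraspecific decomposition, and the
single-species (dominant) analyses.  Returns tidy result tables keyed by
analysis name, ready for :func:`thawpheno.datasets.write_results`.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import community, thermal
from .datasets import Bundle, PHENOPHASES, filter_flooded
from .decomposition import VarianceDecomposition
from .inference import FactorialANOVA, compare_random_effect, regress_on_tdd

logger = logging.getLogger("thawpheno")


@dataclasses.dataclass
class AnalysisConfig:
    """Pipeline switches (documented defaults mirror the standard analysis)."""

    sqrt_initial_leaf_growth: bool = True   # sqrt-transform the ILG CWM response
    ln_tdd: bool = True                     # ln-transform cumulative TDD predictors
    emm_adjust: str = "tukey"
    focal_species: str | None = None        # default: most widespread species
    apply_flooded_filter: bool = True


def _response_transform(phase: str, cfg: AnalysisConfig) -> str:
    return "sqrt" if (phase == "initial_leaf_growth" and cfg.sqrt_initial_leaf_growth) else "none"


def run_analysis(bundle: Bundle, cfg: AnalysisConfig | None = None) -> dict[str, pd.DataFrame]:
    cfg = cfg or AnalysisConfig()
    if cfg.apply_flooded_filter:
        before = bundle.n_plots
        bundle = filter_flooded(bundle)
        logger.info("flooded-plot filter: %d -> %d plots", before, bundle.n_plots)

    tables: dict[str, pd.DataFrame] = {}
    have_cover = bundle.cover is not None and len(bundle.cover.columns) > 0

    # ---- CWM ----------------------------------------------------------
    if have_cover:
        cwm = community.cwm_table(bundle)
        tables["cwm"] = cwm
        specific = community.cwm_wide(cwm, "specific")
        fixed = community.cwm_wide(cwm, "fixed")
        logger.info("CWM: %d (plot, phenophase) values", len(specific.stack()))
    else:
        logger.warning("no cover matrix: skipping all abundance-weighted stages")
        cwm = specific = fixed = None

    # ---- thermal ------------------------------------------------------
    tsum = thermal.thermal_summary(bundle, specific)
    tables["thermal_summary"] = tsum.reset_index()
    try:
        tdd_fit = FactorialANOVA(tsum["tdd"], bundle.plots, label="tdd").fit()
        tables["tdd_anova"] = tdd_fit.anova_table.assign(response="tdd")
        emm = tdd_fit.emmeans(cfg.emm_adjust)
        tables["tdd_emmeans"] = emm.main_effects
    except ValueError as exc:
        logger.warning("TDD ANOVA skipped: %s", exc)

    anova_rows, emm_rows, con_rows = [], [], []
    anc_rows, anc_con_rows, reg_rows, aic_rows, dec_rows = [], [], [], [], []

    phases = PHENOPHASES if have_cover else ()
    for phase in phases:
        if phase not in specific.columns:
            logger.warning("%s: no CWM values; skipped", phase)
            continue
        resp = specific[phase].dropna()
        transform = _response_transform(phase, cfg)
        # two-way ANOVA + EMMs
        try:
            fit = FactorialANOVA(resp, bundle.plots, transform=transform, label=phase).fit()
            anova_rows.append(fit.anova_table.assign(phenophase=phase))
            emm = fit.emmeans(cfg.emm_adjust)
            emm_rows.append(emm.cells.assign(phenophase=phase))
            con_rows.append(emm.contrasts.assign(phenophase=phase))
        except ValueError as exc:
            logger.warning("%s ANOVA skipped: %s", phase, exc)
        # ANCOVA with phenophase-specific cumulative TDD
        cov = tsum.get(f"cum_tdd_{phase}")
        if cov is not None:
            try:
                anc = FactorialANOVA(
                    resp,
                    bundle.plots,
                    covariate=cov,
                    transform=transform,
                    ln_covariate=cfg.ln_tdd,
                    label=phase,
                ).fit()
                anc_rows.append(anc.anova_table.assign(phenophase=phase))
                aemm = anc.emmeans(cfg.emm_adjust)
                anc_con_rows.append(
                    aemm.contrasts.assign(
                        phenophase=phase,
                        covariate_mean=float(np.mean(cov.dropna())),
                    )
                )
            except ValueError as exc:
                logger.warning("%s ANCOVA skipped: %s", phase, exc)
            try:
                reg = regress_on_tdd(resp, cov, ln_transform=cfg.ln_tdd, label=phase)
                reg_rows.append(dataclasses.asdict(reg) | {"phenophase": phase})
            except ValueError as exc:
                logger.warning("%s regression skipped: %s", phase, exc)
        # transect random-effect AIC check
        try:
            aic = compare_random_effect(resp, bundle.plots, label=phase, transform=transform)
            aic_rows.append(
                {
                    "phenophase": phase,
                    "aic_linear": aic.aic_linear,
                    "aic_mixed": aic.aic_mixed,
                    "supported": aic.supported,
                    "singular": aic.singular,
                }
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("%s AIC comparison skipped: %s", phase, exc)
        # turnover / intraspecific decomposition
        try:
            dec = VarianceDecomposition(
                resp, fixed[phase].loc[resp.index], bundle.plots,
                transform=transform, phenophase=phase,
            ).fit()
            dec_rows.append(dec.table)
        except ValueError as exc:
            logger.warning("%s decomposition skipped: %s", phase, exc)

    if anova_rows:
        tables["anova"] = pd.concat(anova_rows, ignore_index=True)
        tables["emmeans"] = pd.concat(emm_rows, ignore_index=True)
        tables["contrasts"] = pd.concat(con_rows, ignore_index=True)
    if anc_rows:
        tables["ancova"] = pd.concat(anc_rows, ignore_index=True)
        tables["ancova_contrasts"] = pd.concat(anc_con_rows, ignore_index=True)
    if reg_rows:
        tables["regression"] = pd.DataFrame(reg_rows)
    if aic_rows:
        tables["aic"] = pd.DataFrame(aic_rows)
    if dec_rows:
        tables["decomposition"] = pd.concat(dec_rows, ignore_index=True)

    # ---- single-species (non-weighted) analyses -----------------------
    focal = cfg.focal_species
    if focal is None and have_cover:
        focal = community.dominant_species(bundle)
    if focal is not None:
        sp_anova, sp_con = [], []
        for phase in PHENOPHASES:
            try:
                obs = community.extract_species_phenology(bundle, focal, phase)
            except ValueError as exc:
                logger.warning("focal species analysis skipped: %s", exc)
                break
            if obs.empty:
                continue
            resp = obs.set_index("plot_id")["julian_date"].astype(float)
            try:
                fit = FactorialANOVA(resp, bundle.plots, label=f"{focal}:{phase}").fit()
                sp_anova.append(fit.anova_table.assign(phenophase=phase, species=focal))
                sp_con.append(
                    fit.emmeans(cfg.emm_adjust).contrasts.assign(phenophase=phase, species=focal)
                )
            except ValueError as exc:
                logger.warning("%s %s single-species ANOVA skipped: %s", focal, phase, exc)
        if sp_anova:
            tables["species_anova"] = pd.concat(sp_anova, ignore_index=True)
            tables["species_contrasts"] = pd.concat(sp_con, ignore_index=True)

    return tables
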