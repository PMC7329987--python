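"""Community-weighted mean (CWM) phenophase dates.

Percent cover is converted to relative abundance by total standardization
(each species' cover divided by the plot's summed cover).  For each plot and
phenophase three CWM variants are computed:

``specific``
    abundance-weighted mean of the dates observed in that plot;
``fixed``
    abundance-weighted mean of each species' site-wide mean date, over the
    same species set and weights — it varies only through composition;
``intraspecific``
    specific - fixed, the part attributable to within-species shifts.

Species with cover but no record for a phenophase are dropped from BOTH the
specific and the fixed average for that phenophase, and the remaining weights
are renormalized, so that specific - fixed is a pure within-species contrast.
Plots with no observation at all for a phenophase are excluded from that
phenophase's analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import Bundle, PHENOPHASES

CWM_VARIANTS = ("specific", "fixed", "intraspecific")


def relative_abundance(cover_row: pd.Series) -> pd.Series:
    """Total-standardized weights for one plot: cover / summed cover."""
    total = float(cover_row.sum())
    if total <= 0:
        raise ValueError("all-zero cover row: relative abundance undefined")
    return cover_row / total


def specific_cwm(weights: pd.Series, dates: pd.Series) -> tuple[float, int]:
    """Abundance-weighted mean date over observed species, renormalized.

    Returns ``(value, n_species_used)``; value is NaN when no weighted
    species carries an observation.
    """
    common = weights.index.intersection(dates.dropna().index)
    common = common[weights.loc[common] > 0]
    if len(common) == 0:
        return float("nan"), 0
    w = weights.loc[common]
    w = w / w.sum()
    return float((w * dates.loc[common]).sum()), int(len(common))


def fixed_species_means(phenology: pd.DataFrame, phenophase: str) -> pd.Series:
    """Site-wide unweighted mean date per species for one phenophase."""
    sub = phenology[phenology["phenophase"] == phenophase]
    return sub.groupby("species_id")["julian_date"].mean()


def fixed_cwm(
    weights: pd.Series, fixed_means: pd.Series, observed_species: pd.Index
) -> float:
    """Weighted mean of site-wide species means over the specific-CWM support."""
    common = weights.index.intersection(observed_species)
    common = common[weights.loc[common] > 0]
    if len(common) == 0:
        return float("nan")
    w = weights.loc[common]
    w = w / w.sum()
    return float((w * fixed_means.loc[common]).sum())


def intraspecific_component(specific: float, fixed: float) -> float:
    """Within-species part of the CWM: specific minus fixed."""
    return specific - fixed


def _date_matrix(bundle: Bundle, phenophase: str) -> pd.DataFrame:
    sub = bundle.phenology[bundle.phenology["phenophase"] == phenophase]
    if sub.empty:
        return pd.DataFrame(index=bundle.cover.index, columns=bundle.cover.columns, dtype=float)
    return (
        sub.pivot(index="plot_id", columns="species_id", values="julian_date")
        .reindex(index=bundle.cover.index, columns=bundle.cover.columns)
        .astype(float)
    )


def cwm_table(bundle: Bundle, phenophases: tuple[str, ...] = PHENOPHASES) -> pd.DataFrame:
    """Tidy table of all three CWM variants for every plot and phenophase.

    Columns: plot_id, phenophase, variant, value, n_species_used.  Plots with
    no observation for a phenophase are simply absent for it.
    """
    W = bundle.cover.to_numpy(dtype=float)
    plot_ids = bundle.cover.index.to_numpy()
    records = []
    for phase in phenophases:
        D = _date_matrix(bundle, phase).to_numpy(dtype=float)
        mask = (W > 0) & np.isfinite(D)
        wsum = np.where(mask, W, 0.0).sum(axis=1)
        has_any = wsum > 0
        if not has_any.any():
            continue
        Wn = np.where(mask, W, 0.0)
        Wn = Wn[has_any] / wsum[has_any, None]
        specific = np.nansum(Wn * np.where(mask[has_any], D[has_any], 0.0), axis=1)
        # site-wide species means over all plots carrying a record
        finite = np.isfinite(D)
        counts = finite.sum(axis=0)
        sums = np.where(finite, D, 0.0).sum(axis=0)
        site_means = np.divide(sums, counts, out=np.full(D.shape[1], np.nan), where=counts > 0)
        fixed = (Wn * np.where(mask[has_any], site_means[None, :], 0.0)).sum(axis=1)
        n_used = mask[has_any].sum(axis=1)
        for pid, sp, fx, n in zip(plot_ids[has_any], specific, fixed, n_used):
            records.append((pid, phase, "specific", sp, int(n)))
            records.append((pid, phase, "fixed", fx, int(n)))
            records.append((pid, phase, "intraspecific", sp - fx, int(n)))
    return pd.DataFrame(
        records, columns=["plot_id", "phenophase", "variant", "value", "n_species_used"]
    )


def cwm_wide(cwm: pd.DataFrame, variant: str = "specific") -> pd.DataFrame:
    """Pivot a tidy CWM table to plots x phenophases for one variant."""
    sub = cwm[cwm["variant"] == variant]
    return sub.pivot(index="plot_id", columns="phenophase", values="value")


def extract_species_phenology(
    bundle: Bundle, species_id: str, phenophase: str
) -> pd.DataFrame:
    """Unweighted plot-level dates for one focal species, joined to plot factors.

    Used for the single-species (dominant willow) microtopography contrasts.
    """
    sub = bundle.phenology[
        (bundle.phenology["species_id"] == species_id)
        & (bundle.phenology["phenophase"] == phenophase)
    ]
    if bundle.phenology[bundle.phenology["species_id"] == species_id].empty:
        raise ValueError(f"species {species_id!r} absent from every plot")
    return sub[["plot_id", "julian_date"]].merge(bundle.plots, on="plot_id")


def dominant_species(bundle: Bundle) -> str:
    """Species occupying the most plots (ties broken by total cover)."""
    occ = (bundle.cover > 0).sum(axis=0)
    tot = bundle.cover.sum(axis=0)
    ranked = pd.DataFrame({"occ": occ, "tot": tot}).sort_values(
        ["occ", "tot"], ascending=False
    )
    return str(ranked.index[0])
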