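"""Data model for ice-wedge polygon phenology surveys.

Four tidy tables describe a survey: plot factors (ground state, polygon
feature, transect, flooded flag), a plot x species percent-cover matrix,
per-species per-plot phenophase Julian dates, and hourly 10-cm soil
temperature series.  This module loads and validates them, applies the
flooded-plot filter, and writes analysis result tables back to disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

GROUND_STATES = ("control", "thermokarst")
POLYGON_FEATURES = ("top", "trough")
PHENOPHASES = (
    "initial_leaf_growth",
    "first_leaf_out",
    "first_flower_bud",
    "first_open_flower",
)


class SchemaError(ValueError):
    """A required column is missing or a table cannot be parsed."""


class IntegrityError(ValueError):
    """Cross-table referential integrity or an invariant is violated."""


class EmptyDatasetError(ValueError):
    """An operation left no analyzable plots."""


@dataclasses.dataclass
class Bundle:
    """Validated survey bundle.

    Attributes
    ----------
    plots : DataFrame
        Columns plot_id, ground_state, polygon_feature, transect_id, flooded.
    cover : DataFrame
        Wide percent-cover matrix indexed by plot_id, one column per species.
    phenology : DataFrame
        Columns plot_id, species_id, phenophase, julian_date.
    temperature : DataFrame
        Columns plot_id, julian_day, hour, temp_c.
    """

    plots: pd.DataFrame
    cover: pd.DataFrame | None
    phenology: pd.DataFrame
    temperature: pd.DataFrame

    def copy(self) -> "Bundle":
        return Bundle(
            self.plots.copy(),
            None if self.cover is None else self.cover.copy(),
            self.phenology.copy(),
            self.temperature.copy(),
        )

    @property
    def n_plots(self) -> int:
        return len(self.plots)


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {missing}")


def _normalize_levels(series: pd.Series, allowed: tuple[str, ...], name: str) -> pd.Series:
    """Case-insensitive mapping onto canonical categorical labels."""
    lowered = series.astype(str).str.strip().str.lower()
    bad = sorted(set(lowered) - set(allowed))
    if bad:
        raise IntegrityError(
            f"{name}: unknown level(s) {bad}; allowed levels are {list(allowed)}"
        )
    return lowered


def validate_bundle(bundle: Bundle) -> Bundle:
    """Check all invariants; returns the bundle with canonicalized levels."""
    plots = bundle.plots.copy()
    _require_columns(
        plots, ["plot_id", "ground_state", "polygon_feature", "transect_id", "flooded"], "plots"
    )
    if plots["plot_id"].duplicated().any():
        dupes = plots.loc[plots["plot_id"].duplicated(), "plot_id"].tolist()
        raise IntegrityError(f"plots: duplicate plot_id(s) {dupes}")
    if plots[["ground_state", "polygon_feature"]].isna().any().any():
        raise IntegrityError("plots: ground_state/polygon_feature must be non-missing")
    plots["ground_state"] = _normalize_levels(plots["ground_state"], GROUND_STATES, "ground_state")
    plots["polygon_feature"] = _normalize_levels(
        plots["polygon_feature"], POLYGON_FEATURES, "polygon_feature"
    )
    plots["flooded"] = plots["flooded"].astype(bool)
    plot_ids = set(plots["plot_id"])

    cover = None if bundle.cover is None else bundle.cover.copy()
    if cover is not None and cover.index.name != "plot_id":
        if "plot_id" in cover.columns:
            cover = cover.set_index("plot_id")
        else:
            raise SchemaError("cover: missing column(s) ['plot_id']")
    if cover is not None:
        values = cover.to_numpy(dtype=float)
        if np.isnan(values).any():
            cover = cover.fillna(0.0)
            values = cover.to_numpy(dtype=float)
        if (values < 0).any():
            rows = cover.index[(values < 0).any(axis=1)].tolist()
            raise IntegrityError(f"cover: negative percent cover in plot(s) {rows}")
        if (values.sum(axis=1) <= 0).any():
            rows = cover.index[values.sum(axis=1) <= 0].tolist()
            raise IntegrityError(f"cover: all-zero cover row(s) for plot(s) {rows}")
        orphans = sorted(set(cover.index) - plot_ids)
        if orphans:
            raise IntegrityError(f"cover: plot_id(s) {orphans} not present in plots table")

    pheno = bundle.phenology.copy()
    _require_columns(pheno, ["plot_id", "species_id", "phenophase", "julian_date"], "phenology")
    pheno["phenophase"] = _normalize_levels(pheno["phenophase"], PHENOPHASES, "phenophase")
    pheno["julian_date"] = pheno["julian_date"].astype(int)
    orphans = sorted(set(pheno["plot_id"]) - plot_ids)
    if orphans:
        raise IntegrityError(f"phenology: plot_id(s) {orphans} not present in plots table")
    if pheno.duplicated(["plot_id", "species_id", "phenophase"]).any():
        raise IntegrityError("phenology: duplicate (plot, species, phenophase) record(s)")
    # every phenology record must refer to a species with positive cover in that plot
    if len(pheno) and cover is not None:
        stacked = cover.stack()
        present = set(stacked[stacked > 0].index)
        pairs = set(zip(pheno["plot_id"], pheno["species_id"]))
        bad = sorted(pairs - present)
        if bad:
            raise IntegrityError(
                f"phenology: record(s) for species with zero cover in plot: {bad[:5]}"
            )

    temp = bundle.temperature.copy()
    _require_columns(temp, ["plot_id", "julian_day", "hour", "temp_c"], "temperature")
    orphans = sorted(set(temp["plot_id"]) - plot_ids)
    if orphans:
        raise IntegrityError(f"temperature: plot_id(s) {orphans} not present in plots table")

    return Bundle(plots, cover, pheno, temp)


def load_dataset(
    plots_path: str | Path,
    cover_path: str | Path | None,
    phenology_path: str | Path,
    temperature_path: str | Path,
) -> Bundle:
    """Read the four CSV inputs and return a validated :class:`Bundle`.

    ``cover_path`` may be ``None`` (the deposit may omit the cover matrix);
    downstream abundance-weighted stages then degrade gracefully.
    """
    bundle = Bundle(
        plots=pd.read_csv(plots_path),
        cover=None
        if cover_path is None
        else pd.read_csv(cover_path, float_precision="round_trip"),
        phenology=pd.read_csv(phenology_path),
        temperature=pd.read_csv(temperature_path, float_precision="round_trip"),
    )
    return validate_bundle(bundle)


def filter_flooded(bundle: Bundle) -> Bundle:
    """Drop plots that remained submerged through the season, from every table.

    Idempotent; raises :class:`EmptyDatasetError` if nothing survives.
    """
    keep = bundle.plots.loc[~bundle.plots["flooded"], "plot_id"]
    if keep.empty:
        raise EmptyDatasetError("all plots flooded; nothing left to analyze")
    keep_set = set(keep)
    return Bundle(
        plots=bundle.plots[bundle.plots["plot_id"].isin(keep_set)].reset_index(drop=True),
        cover=None
        if bundle.cover is None
        else bundle.cover.loc[bundle.cover.index.isin(keep_set)],
        phenology=bundle.phenology[bundle.phenology["plot_id"].isin(keep_set)].reset_index(
            drop=True
        ),
        temperature=bundle.temperature[bundle.temperature["plot_id"].isin(keep_set)].reset_index(
            drop=True
        ),
    )


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    metadata: dict | None = None,
) -> list[Path]:
    """Write one tidy CSV per result table plus a run-metadata sidecar.

    Column order is whatever the analysis produced (deterministic); reruns on
    identical inputs yield byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        path = out / f"{name}.csv"
        df = tables[name]
        df.to_csv(path, index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None)
        written.append(path)
    meta = dict(metadata or {})
    meta.setdefault("tables", sorted(tables))
    meta["content_hash"] = hashlib.sha256(
        b"".join(p.read_bytes() for p in written)
    ).hexdigest()
    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    written.append(meta_path)
    return written
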