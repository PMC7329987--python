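"""Seedable synthetic ice-wedge-polygon landscapes.

The generator emulates the statistical structure of a high-Arctic polygon
survey: a 2x2 ground-state x polygon-feature design (20 plots per cell along
five transects, five permanently flooded thermokarst troughs), a ~22-species
pool with partial turnover between ground states and one widespread dominant
(~80% occupancy, ~60% cover), hourly 10-cm soil temperatures whose daily
means are depressed in thermokarst and in troughs, and per-species
phenophase dates produced by a cumulative-TDD threshold mechanism plus
intraspecific habitat shifts, transect effects, and observation noise.

The threshold mechanism (a species enters a phenophase on the first day its
plot's cumulative TDD crosses a species- and phenophase-specific threshold)
builds in the premise that dates track accumulated thermal forcing, so the
regression and ANCOVA stages are meaningfully testable.  Dates are floored
to integer Julian days; a crossing that never happens inside the observation
window is censored (no record), which reproduces the differing residual
degrees of freedom across phenophases seen in real surveys.

Randomness comes from a single seed split into four named substreams
(design, species, thermal, phenology) in that fixed order, so adding a table
never perturbs another.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .datasets import Bundle, GROUND_STATES, PHENOPHASES, POLYGON_FEATURES

_WETNESS = {"control": 0.25, "thermokarst": 0.75}


@dataclasses.dataclass
class SyntheticConfig:
    """Generator parameters; defaults emulate the study conditions."""

    n_per_cell: int = 20
    n_transects: int = 5
    n_flooded_troughs: int = 5
    species_pool_size: int = 22
    n_unique_per_state: int = 5
    dominant_occupancy: float = 0.80
    dominant_mean_cover: float = 60.0
    window: tuple[int, int] = (179, 200)
    # thermal model: daily-mean ramp (degC) plus additive habitat effects
    baseline_intercept: float = 0.8
    baseline_slope: float = 0.5
    state_effect: float = -1.1     # thermokarst minus control, degC/day
    feature_effect: float = -1.4   # trough minus top, degC/day
    hourly_noise_sd: float = 1.5
    diurnal_amplitude: float = 3.0
    plot_daily_sd: float = 0.8   # persistent per-plot microsite offset, degC
    # phenology: cumulative-TDD thresholds (degC-day) per phenophase
    phenophase_thresholds: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "initial_leaf_growth": 8.0,
            "first_leaf_out": 23.0,
            "first_flower_bud": 12.0,
            "first_open_flower": 26.0,
        }
    )
    species_threshold_sd: float = 0.25        # lognormal sigma on the multiplier
    moisture_threshold_effect: float = 0.4    # wetland species cross later
    intraspecific_shift: Mapping[tuple[str, str], float] = dataclasses.field(
        default_factory=lambda: {("thermokarst", "trough"): 1.5}
    )
    observation_noise_sd: float = 1.5         # days
    transect_sd: float = 0.0                  # days, random intercept
    # community composition
    base_occupancy: float = 0.45
    base_cover_mean: float = 8.0
    cover_lognorm_sd: float = 0.8
    turnover_strength: float = 1.0            # 0 => no compositional turnover
    identical_composition: bool = False       # one community copied to all plots

    def validate(self) -> None:
        for name in ("n_per_cell", "n_transects", "species_pool_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.dominant_occupancy <= 1:
            raise ValueError("dominant_occupancy must be in (0, 1]")
        if self.n_flooded_troughs < 0 or self.n_flooded_troughs > self.n_per_cell:
            raise ValueError("n_flooded_troughs must be in [0, n_per_cell]")
        if self.species_pool_size < 2 * self.n_unique_per_state + 1:
            raise ValueError("species pool too small for the unique-species structure")
        for name in ("hourly_noise_sd", "observation_noise_sd", "transect_sd", "plot_daily_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v <= 0 for v in self.phenophase_thresholds.values()):
            raise ValueError("phenophase thresholds must be positive")


def scenario(name: str) -> SyntheticConfig:
    """Named study scenarios.

    ``paper_like``
        defaults: thermokarst and trough TDD depressed, thermokarst troughs
        delayed ~1.5 days within species, composition turnover between states;
    ``turnover_only``
        composition turnover on, but no thermal habitat effects and no
        intraspecific shifts — within-species variation is noise only;
    ``intraspecific_only``
        one community copied to every plot, no thermal effects, the
        intraspecific trough delay as the only systematic signal;
    ``null``
        no thermal effects, no shifts, no turnover structure — dates are
        exchangeable across design cells.
    """
    cfg = SyntheticConfig()
    if name == "paper_like":
        return cfg
    if name == "turnover_only":
        cfg.state_effect = 0.0
        cfg.feature_effect = 0.0
        cfg.plot_daily_sd = 0.0
        cfg.intraspecific_shift = {}
        cfg.moisture_threshold_effect = 0.8  # wetland pool clearly later
        return cfg
    if name == "intraspecific_only":
        cfg.state_effect = 0.0
        cfg.feature_effect = 0.0
        cfg.plot_daily_sd = 0.0
        cfg.turnover_strength = 0.0
        cfg.identical_composition = True
        return cfg
    if name == "null":
        cfg.state_effect = 0.0
        cfg.feature_effect = 0.0
        cfg.intraspecific_shift = {}
        cfg.turnover_strength = 0.0
        return cfg
    raise ValueError(f"unknown scenario {name!r}")


def generate_landscape(config: SyntheticConfig, seed: int) -> tuple[Bundle, dict]:
    """Generate a full survey bundle plus its ground-truth parameters.

    Deterministic given ``(config, seed)``.
    """
    config.validate()
    rng_design, rng_species, rng_thermal, rng_pheno = np.random.default_rng(seed).spawn(4)

    # ---- plots ---------------------------------------------------------
    cells = [(s, f) for s in GROUND_STATES for f in POLYGON_FEATURES]
    n_plots = 4 * config.n_per_cell
    plot_ids = [f"P{i + 1:03d}" for i in range(n_plots)]
    states, features, transects = [], [], []
    for ci, (s, f) in enumerate(cells):
        for j in range(config.n_per_cell):
            states.append(s)
            features.append(f)
            transects.append(f"T{j % config.n_transects + 1}")
    flooded = np.zeros(n_plots, dtype=bool)
    tk_trough = [
        i for i in range(n_plots) if states[i] == "thermokarst" and features[i] == "trough"
    ]
    if config.n_flooded_troughs:
        flooded[rng_design.choice(tk_trough, config.n_flooded_troughs, replace=False)] = True
    plots = pd.DataFrame(
        {
            "plot_id": plot_ids,
            "ground_state": states,
            "polygon_feature": features,
            "transect_id": transects,
            "flooded": flooded,
        }
    )
    state_arr = np.array([s == "thermokarst" for s in states], float)
    feat_arr = np.array([f == "trough" for f in features], float)

    # ---- species pool --------------------------------------------------
    n_sp = config.species_pool_size
    species_ids = [f"S{i + 1:02d}" for i in range(n_sp)]
    nu = config.n_unique_per_state
    pref = np.empty(n_sp)
    pref[0] = 0.5  # dominant generalist
    pref[1 : 1 + nu] = rng_species.uniform(0.05, 0.2, nu)        # unique to control
    pref[1 + nu : 1 + 2 * nu] = rng_species.uniform(0.8, 0.95, nu)  # unique to thermokarst
    pref[1 + 2 * nu :] = rng_species.uniform(0.2, 0.8, n_sp - 1 - 2 * nu)
    thr_base = np.array([config.phenophase_thresholds[p] for p in PHENOPHASES])
    sp_mult = np.exp(rng_species.normal(0.0, config.species_threshold_sd, n_sp)) * (
        1.0 + config.moisture_threshold_effect * (pref - 0.5)
    )
    thresholds = sp_mult[:, None] * thr_base[None, :]  # species x phenophase

    # ---- cover ---------------------------------------------------------
    eff_pref = 0.5 + config.turnover_strength * (pref - 0.5)
    wet = np.array([_WETNESS[s] for s in states])  # per plot
    match = 1.0 - np.abs(eff_pref[None, :] - wet[:, None])  # plots x species
    occ_p = np.clip(2.0 * config.base_occupancy * match, 0.0, 1.0)
    occ_p[:, 0] = config.dominant_occupancy
    # hard habitat restriction for the state-unique species (only with turnover)
    if config.turnover_strength > 0:
        occ_p[state_arr == 1.0, 1 : 1 + nu] = 0.0
        occ_p[state_arr == 0.0, 1 + nu : 1 + 2 * nu] = 0.0
    if config.identical_composition:
        present = np.tile(rng_species.random(n_sp) < occ_p[0], (n_plots, 1))
        base_cov = np.exp(
            np.log(config.base_cover_mean)
            + rng_species.normal(0.0, config.cover_lognorm_sd, n_sp)
        )
        cover_vals = np.tile(base_cov, (n_plots, 1))
        cover_vals[:, 0] = config.dominant_mean_cover
        cover_vals *= present
    else:
        present = rng_species.random((n_plots, n_sp)) < occ_p
        cover_vals = np.exp(
            np.log(np.maximum(config.base_cover_mean * 2.0 * match, 1e-9))
            + rng_species.normal(0.0, config.cover_lognorm_sd, (n_plots, n_sp))
        )
        cover_vals[:, 0] = np.clip(
            rng_species.normal(config.dominant_mean_cover, 10.0, n_plots), 5.0, 100.0
        )
        cover_vals *= present
    empty = cover_vals.sum(axis=1) <= 0
    if empty.any():  # guarantee every plot hosts at least the dominant
        cover_vals[empty, 0] = config.dominant_mean_cover
    cover = pd.DataFrame(cover_vals, index=pd.Index(plot_ids, name="plot_id"), columns=species_ids)

    # ---- hourly soil temperature --------------------------------------
    d0, d1 = config.window
    days = np.arange(d0, d1 + 1)
    n_days = len(days)
    base_daily = config.baseline_intercept + config.baseline_slope * (days - d0)
    plot_offset = rng_thermal.normal(0.0, config.plot_daily_sd, n_plots)
    plot_daily = (
        base_daily[None, :]
        + config.state_effect * state_arr[:, None]
        + config.feature_effect * feat_arr[:, None]
        + plot_offset[:, None]
    )
    hours = np.arange(24)
    diurnal = config.diurnal_amplitude * np.cos(2 * np.pi * (hours - 14) / 24.0)
    hourly = (
        plot_daily[:, :, None]
        + diurnal[None, None, :]
        + rng_thermal.normal(0.0, config.hourly_noise_sd, (n_plots, n_days, 24))
    )
    temperature = pd.DataFrame(
        {
            "plot_id": np.repeat(plot_ids, n_days * 24),
            "julian_day": np.tile(np.repeat(days, 24), n_plots),
            "hour": np.tile(hours, n_plots * n_days),
            "temp_c": hourly.ravel(),
        }
    )

    # ---- phenophase dates via cumulative-TDD threshold crossing --------
    realized_daily = hourly.mean(axis=2)  # includes logger noise
    cum_tdd = np.cumsum(np.maximum(realized_daily, 0.0), axis=1)  # plots x days
    # first day each (plot, species, phenophase) threshold is crossed
    reached = cum_tdd[:, None, None, :] >= thresholds[None, :, :, None]
    ever = reached.any(axis=-1)
    cross_idx = reached.argmax(axis=-1)
    cross_day = days[cross_idx].astype(float)  # plots x species x phases
    shift = np.zeros(n_plots)
    for (s, f), delta in config.intraspecific_shift.items():
        sel = (state_arr == (s == "thermokarst")) & (feat_arr == (f == "trough"))
        shift[sel] += delta
    transect_levels = sorted(set(transects))
    transect_eff = rng_pheno.normal(0.0, config.transect_sd, len(transect_levels))
    t_idx = np.array([transect_levels.index(t) for t in transects])
    noise = rng_pheno.normal(0.0, config.observation_noise_sd, cross_day.shape)
    date = np.floor(
        cross_day + shift[:, None, None] + transect_eff[t_idx][:, None, None] + noise
    )
    observed = (
        (cover_vals > 0)[:, :, None]
        & ever
        & (date <= d1)
    )
    date = np.clip(date, d0, d1)
    p_idx, s_idx, q_idx = np.nonzero(observed)
    phenology = pd.DataFrame(
        {
            "plot_id": np.asarray(plot_ids, dtype=object)[p_idx],
            "species_id": np.asarray(species_ids, dtype=object)[s_idx],
            "phenophase": np.asarray(PHENOPHASES, dtype=object)[q_idx],
            "julian_date": date[p_idx, s_idx, q_idx].astype(int),
        }
    )

    cfg_dict = dataclasses.asdict(config)
    cfg_dict["intraspecific_shift"] = {
        f"{s}:{f}": v for (s, f), v in config.intraspecific_shift.items()
    }
    cfg_dict["phenophase_thresholds"] = dict(config.phenophase_thresholds)
    ground_truth = {
        "seed": seed,
        "config": cfg_dict,
        "species_moisture_pref": dict(zip(species_ids, pref.tolist())),
        "species_thresholds": {
            sp: dict(zip(PHENOPHASES, thresholds[i].tolist())) for i, sp in enumerate(species_ids)
        },
        "expected_tdd_by_cell": {
            f"{s}:{f}": float(
                np.maximum(
                    base_daily
                    + config.state_effect * (s == "thermokarst")
                    + config.feature_effect * (f == "trough"),
                    0.0,
                ).sum()
            )
            for s, f in cells
        },
        "intraspecific_shift": {f"{s}:{f}": v for (s, f), v in config.intraspecific_shift.items()},
    }
    bundle = Bundle(plots=plots, cover=cover, phenology=phenology, temperature=temperature)
    return bundle, ground_truth
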