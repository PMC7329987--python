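"""Shared test utilities: toy 2x2 designs and the independent type II oracle."""

import numpy as np
import pandas as pd

CELLS = [
    ("control", "top"),
    ("control", "trough"),
    ("thermokarst", "top"),
    ("thermokarst", "trough"),
]


def make_design(n_per_cell, y, covariate=None):
    """Plot table + response series for a 2x2 layout with given cell sizes."""
    states, features, pids = [], [], []
    i = 0
    for (s, f), n in zip(CELLS, n_per_cell):
        for _ in range(n):
            pids.append(f"P{i:03d}")
            states.append(s)
            features.append(f)
            i += 1
    plots = pd.DataFrame(
        {
            "plot_id": pids,
            "ground_state": states,
            "polygon_feature": features,
            "transect_id": ["T1"] * i,
            "flooded": False,
        }
    )
    resp = pd.Series(np.asarray(y, float), index=pids)
    cov = None if covariate is None else pd.Series(np.asarray(covariate, float), index=pids)
    return plots, resp, cov


def statsmodels_type2(plots, resp, cov=None):
    """Independent oracle: car-style type II table via statsmodels."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = plots.set_index("plot_id").assign(y=resp)
    formula = "y ~ C(ground_state) * C(polygon_feature)"
    if cov is not None:
        df["c"] = cov
        formula = "y ~ c + C(ground_state) * C(polygon_feature)"
    fit = ols(formula, data=df).fit()
    return sm.stats.anova_lm(fit, typ=2), fit


def brute_force_type2(y, a, b, cov=None):
    """Second independent oracle: nested-model RSS differences via pinv projections."""
    y = np.asarray(y, float)

    def rss(cols):
        X = np.column_stack([np.ones_like(y)] + cols)
        proj = X @ np.linalg.pinv(X)
        r = y - proj @ y
        return float(r @ r)

    c = [] if cov is None else [np.asarray(cov, float)]
    full = rss(c + [a, b, a * b])
    ab = rss(c + [a, b])
    out = {
        "ground_state": rss(c + [b]) - ab,
        "polygon_feature": rss(c + [a]) - ab,
        "interaction": ab - full,
        "residuals": full,
    }
    if cov is not None:
        out["cumulative_tdd"] = rss([a, b, a * b]) - full
    return out
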