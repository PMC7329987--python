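"""Turnover / intraspecific decomposition of CWM sums of squares.

For each phenophase the same two-way type II ANOVA is fitted three times:
on the specific CWM (plot-level observed dates; its SS column is the
"total"), on the fixed CWM (site-wide species means; composition change is
the only source of variation, the "turnover" column), and on their per-plot
difference (the "intraspecific" column).  The covariation column is the
signed remainder, total - turnover - intraspecific, for every term including
residuals and the grand total; it is negative when composition shifts and
within-species shifts pull the community date in opposite directions.

Because the intraspecific response is constructed as specific - fixed per
plot before fitting, the additivity identity holds exactly by construction
of the three fits plus the covariation remainder.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import FactorialANOVA, apply_transform

DECOMP_TERMS = ("ground_state", "polygon_feature", "interaction", "residuals", "total")


class DecompositionResults:
    """Per-term SS partition for one phenophase (date^2 on the analyzed scale)."""

    def __init__(self, table: pd.DataFrame, phenophase: str, transform: str):
        self.table = table
        self.phenophase = phenophase
        self.transform = transform

    def additivity_error(self) -> float:
        """Largest relative violation of turnover + intraspecific + covariation = total."""
        t = self.table
        resid = t["turnover"] + t["intraspecific"] + t["covariation"] - t["total"]
        scale = np.maximum(np.abs(t["total"]), 1.0)
        return float(np.max(np.abs(resid) / scale))

    def summary(self) -> str:
        head = f"Variance decomposition: {self.phenophase}"
        if self.transform != "none":
            head += f" (response transform: {self.transform})"
        return head + "\n" + self.table.to_string(index=False, float_format=lambda v: f"{v:.4g}")


class VarianceDecomposition:
    """Decompose the specific-CWM ANOVA SS into turnover, intraspecific, covariation.

    Parameters
    ----------
    specific, fixed : Series
        Plot-indexed CWM dates for one phenophase; must share a plot set.
    factors : DataFrame
        Plot table with ground_state and polygon_feature.
    transform : {'none', 'sqrt'}
        Applied identically to specific and fixed before differencing, so the
        intraspecific response is their transformed difference.
    """

    def __init__(
        self,
        specific: pd.Series,
        fixed: pd.Series,
        factors: pd.DataFrame,
        transform: str = "none",
        phenophase: str = "",
    ):
        s = pd.Series(specific, dtype=float).dropna()
        f = pd.Series(fixed, dtype=float).dropna()
        if not s.index.sort_values().equals(f.index.sort_values()):
            raise ValueError("specific and fixed CWMs are defined on different plot sets")
        self.specific = apply_transform(s, transform)
        self.fixed = apply_transform(f.loc[s.index], transform)
        self.intraspecific = self.specific - self.fixed
        self.factors = factors
        self.transform = transform
        self.phenophase = phenophase or (specific.name or "phenophase")

    def _ss_column(self, response: pd.Series) -> pd.Series:
        """Type II SS per term, plus residual and grand-total rows.

        A response that is constant across plots (e.g. the fixed CWM on a
        turnover-free landscape) carries zero SS everywhere.
        """
        y = response.to_numpy(dtype=float)
        if np.ptp(y) == 0:
            return pd.Series(0.0, index=list(DECOMP_TERMS))
        res = FactorialANOVA(response, self.factors, transform="none").fit()
        tab = res.anova_table.set_index("term")["ss"]
        out = pd.Series(
            {
                "ground_state": tab["ground_state"],
                "polygon_feature": tab["polygon_feature"],
                "interaction": tab["interaction"],
                "residuals": tab["residuals"],
            }
        )
        out["total"] = float(((y - y.mean()) ** 2).sum())
        return out

    def fit(self) -> DecompositionResults:
        total = self._ss_column(self.specific)
        turnover = self._ss_column(self.fixed)
        intra = self._ss_column(self.intraspecific)
        cov = total - turnover - intra
        table = pd.DataFrame(
            {
                "phenophase": self.phenophase,
                "term": list(DECOMP_TERMS),
                "turnover": turnover.to_numpy(),
                "intraspecific": intra.to_numpy(),
                "covariation": cov.to_numpy(),
                "total": total.to_numpy(),
            }
        )
        return DecompositionResults(table, self.phenophase, self.transform)
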