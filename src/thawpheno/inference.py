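"""Linear-model inference for unbalanced 2x2 microtopography designs.

The central object is :class:`FactorialANOVA`: a two-way model in ground
state (control vs thermokarst) and polygon feature (top vs trough), with an
optional thermal covariate (cumulative TDD, optionally ln-transformed).
``fit()`` returns :class:`ANOVAResults`, which carries the type II
sums-of-squares table, estimated marginal means with Tukey-Kramer-adjusted
pairwise contrasts, and a text summary.

Type II SS are computed from residual-sum-of-squares differences between
nested least-squares fits: each term is adjusted for every other term at or
below its marginality level (the interaction is never included when testing
the main effects it contains).  This is the appropriate decomposition when
cell sample sizes are unequal, as they are here after removing flooded
trough plots.

Also provided: OLS regression of phenophase dates on (ln) cumulative TDD,
and an AIC comparison of the fixed-effects model against the same model with
a transect random intercept (both by maximum likelihood so the AICs are
comparable).
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import GROUND_STATES, POLYGON_FEATURES

TERMS = ("ground_state", "polygon_feature", "interaction")


def apply_transform(values: pd.Series, kind: str) -> pd.Series:
    """Elementwise response/covariate transform: 'none', 'sqrt' or 'ln'.

    Domain violations name the offending plot(s).
    """
    if kind == "none":
        return values
    arr = pd.Series(values, dtype=float)
    if kind == "sqrt":
        bad = arr.index[arr < 0].tolist()
        if bad:
            raise ValueError(f"sqrt transform undefined for negative value(s) at {bad}")
        return np.sqrt(arr)
    if kind == "ln":
        bad = arr.index[arr <= 0].tolist()
        if bad:
            raise ValueError(f"ln transform undefined for non-positive value(s) at {bad}")
        return np.log(arr)
    raise ValueError(f"unknown transform {kind!r}; expected 'none', 'sqrt' or 'ln'")


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


@dataclasses.dataclass
class EmmResult:
    """Estimated marginal means and Tukey-adjusted pairwise contrasts."""

    cells: pd.DataFrame          # ground_state, polygon_feature, emmean, se, df
    contrasts: pd.DataFrame      # contrast, estimate, se, t, df, p_adj
    main_effects: pd.DataFrame   # factor, level, emmean, se
    covariate_value: float | None = None  # evaluation point (model scale)


class ANOVAResults:
    """Fitted two-way (optionally ANCOVA) model.

    Attributes
    ----------
    anova_table : DataFrame
        One row per term (covariate first when present) with type II SS,
        df, F and p, plus a residual row.
    params, cov_params : ndarray
        Full-model coefficients and their covariance.
    """

    def __init__(self, model, params, cov_params, sigma2, df_resid, anova_table):
        self.model = model
        self.params = params
        self.cov_params = cov_params
        self.sigma2 = sigma2
        self.df_resid = int(df_resid)
        self.anova_table = anova_table

    @property
    def label(self) -> str:
        return self.model.label

    def _cell_rows(self, covariate_value: float | None) -> tuple[list, np.ndarray]:
        cells = list(itertools.product(GROUND_STATES, POLYGON_FEATURES))
        rows = []
        for state, feature in cells:
            a = 1.0 if state == GROUND_STATES[1] else 0.0
            b = 1.0 if feature == POLYGON_FEATURES[1] else 0.0
            row = [1.0, a, b, a * b]
            if self.model.has_covariate:
                row.append(covariate_value)
            rows.append(row)
        return cells, np.asarray(rows)

    def emmeans(self, adjust: str = "tukey") -> EmmResult:
        """Cell EMMs, equal-weight main-effect EMMs, and pairwise contrasts.

        With a covariate, cells are evaluated at its grand mean over the
        analyzed plots (on the model scale, i.e. after any ln transform);
        the covariate then cancels exactly in every cell contrast.
        """
        cov_value = None
        if self.model.has_covariate:
            cov_value = float(np.mean(self.model.covariate_values))
        cells, R = self._cell_rows(cov_value)
        emms = R @ self.params
        ses = np.sqrt(np.einsum("ij,jk,ik->i", R, self.cov_params, R))
        cell_df = pd.DataFrame(
            {
                "ground_state": [c[0] for c in cells],
                "polygon_feature": [c[1] for c in cells],
                "emmean": emms,
                "se": ses,
                "df": self.df_resid,
            }
        )
        k = len(cells)
        recs = []
        for i, j in itertools.combinations(range(k), 2):
            d = R[i] - R[j]
            est = float(d @ self.params)
            se = float(np.sqrt(d @ self.cov_params @ d))
            t = est / se
            recs.append(
                (
                    f"{cells[i][0]} {cells[i][1]} - {cells[j][0]} {cells[j][1]}",
                    est,
                    se,
                    t,
                    self.df_resid,
                    _adjusted_p(t, k, self.df_resid, adjust),
                )
            )
        contrasts = pd.DataFrame(
            recs, columns=["contrast", "estimate", "se", "t", "df", "p_adj"]
        )
        main = []
        for factor, levels in (
            ("ground_state", GROUND_STATES),
            ("polygon_feature", POLYGON_FEATURES),
        ):
            for level in levels:
                idx = [
                    i
                    for i, c in enumerate(cells)
                    if (c[0] if factor == "ground_state" else c[1]) == level
                ]
                w = np.zeros(len(cells))
                w[idx] = 1.0 / len(idx)
                row = w @ R
                main.append(
                    (
                        factor,
                        level,
                        float(row @ self.params),
                        float(np.sqrt(row @ self.cov_params @ row)),
                    )
                )
        main_df = pd.DataFrame(main, columns=["factor", "level", "emmean", "se"])
        return EmmResult(cell_df, contrasts, main_df, cov_value)

    def summary(self) -> str:
        lines = [f"Two-way type II ANOVA: {self.label}"]
        if self.model.transform != "none":
            lines.append(f"  response transform: {self.model.transform}")
        if self.model.has_covariate:
            lines.append(
                f"  covariate: cumulative TDD ({'ln' if self.model.ln_covariate else 'raw'} scale)"
            )
        lines.append(self.anova_table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        emm = self.emmeans()
        lines.append("Estimated marginal means (cells):")
        lines.append(emm.cells.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("Tukey-adjusted pairwise contrasts:")
        lines.append(emm.contrasts.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def _adjusted_p(t: float, k: int, df: int, adjust: str) -> float:
    if adjust == "none" or k == 2:
        # k = 2: the studentized range collapses exactly to the two-sided t test
        return float(2.0 * stats.t.sf(abs(t), df))
    if adjust == "tukey":
        return float(np.clip(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df), 0.0, 1.0))
    raise ValueError(f"unknown adjustment {adjust!r}")


class FactorialANOVA:
    """Two-way type II model for one response on the 2x2 design.

    Parameters
    ----------
    response : Series
        Plot-indexed response (a CWM date or a single-species date).
    factors : DataFrame
        Plot table with plot_id, ground_state, polygon_feature.
    covariate : Series, optional
        Plot-indexed cumulative TDD; turns the fit into an ANCOVA with the
        covariate as the first (most marginal) predictor.
    transform : {'none', 'sqrt'}
        Response transform, applied before fitting.
    ln_covariate : bool
        Apply the natural log to the covariate before fitting.
    """

    def __init__(
        self,
        response: pd.Series,
        factors: pd.DataFrame,
        covariate: pd.Series | None = None,
        transform: str = "none",
        ln_covariate: bool = False,
        label: str = "",
    ):
        fac = factors.set_index("plot_id") if "plot_id" in factors.columns else factors
        y = pd.Series(response, dtype=float).dropna()
        idx = y.index.intersection(fac.index)
        if covariate is not None:
            cov = pd.Series(covariate, dtype=float).dropna()
            idx = idx.intersection(cov.index)
        idx = idx.sort_values()
        self.index = idx
        self.label = label or (response.name if response.name else "response")
        self.transform = transform
        self.ln_covariate = ln_covariate
        self.response_values = apply_transform(y.loc[idx], transform).to_numpy()
        self.state = (fac.loc[idx, "ground_state"] == GROUND_STATES[1]).to_numpy(float)
        self.feature = (fac.loc[idx, "polygon_feature"] == POLYGON_FEATURES[1]).to_numpy(float)
        self.has_covariate = covariate is not None
        if self.has_covariate:
            c = cov.loc[idx]
            self.covariate_values = apply_transform(
                c, "ln" if ln_covariate else "none"
            ).to_numpy()
        else:
            self.covariate_values = None
        self._validate()

    def _validate(self) -> None:
        n = len(self.index)
        if n == 0:
            raise ValueError("no plots with both response and factors defined")
        if np.ptp(self.response_values) == 0:
            raise ValueError("constant response: nothing to model")
        for name, v in (("ground_state", self.state), ("polygon_feature", self.feature)):
            if np.ptp(v) == 0:
                raise ValueError(f"factor {name} has a single level on the analyzed plots")
        if self.has_covariate and np.ptp(self.covariate_values) == 0:
            raise ValueError("covariate is constant across analyzed plots")
        # every represented cell must carry data for the interaction to be estimable
        cells = set(zip(self.state, self.feature))
        if len(cells) < 4:
            raise ValueError(
                "rank deficiency: empty design cell(s); the interaction is inestimable"
            )

    def _design(self, with_covariate: bool, terms: set[str]) -> np.ndarray:
        cols = [np.ones_like(self.state)]
        if with_covariate:
            cols.append(self.covariate_values)
        if "A" in terms:
            cols.append(self.state)
        if "B" in terms:
            cols.append(self.feature)
        if "AB" in terms:
            cols.append(self.state * self.feature)
        return np.column_stack(cols)

    def fit(self) -> ANOVAResults:
        y = self.response_values
        n = len(y)
        hc = self.has_covariate
        X_full = self._design(hc, {"A", "B", "AB"})
        p = X_full.shape[1]
        if np.linalg.matrix_rank(X_full) < p:
            raise ValueError("rank-deficient design: interaction inestimable")
        rss_full = _rss(X_full, y)
        df_resid = n - p
        sigma2 = rss_full / df_resid
        # type II nested-model RSS differences
        rss_ab = _rss(self._design(hc, {"A", "B"}), y)
        ss = {
            "ground_state": _rss(self._design(hc, {"B"}), y) - rss_ab,
            "polygon_feature": _rss(self._design(hc, {"A"}), y) - rss_ab,
            "interaction": rss_ab - rss_full,
        }
        order = list(TERMS)
        if hc:
            ss["cumulative_tdd"] = _rss(self._design(False, {"A", "B", "AB"}), y) - rss_full
            order = ["cumulative_tdd"] + order
        rows = []
        for term in order:
            ssq = max(ss[term], 0.0)
            F = (ssq / 1.0) / sigma2
            rows.append((term, ssq, 1, F, float(stats.f.sf(F, 1, df_resid))))
        rows.append(("residuals", rss_full, df_resid, np.nan, np.nan))
        table = pd.DataFrame(rows, columns=["term", "ss", "df", "F", "p"])
        beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
        cov = sigma2 * np.linalg.inv(X_full.T @ X_full)
        # reorder params to (intercept, A, B, AB[, covariate]) for the EMM grid
        if hc:
            perm = [0, 2, 3, 4, 1]
            beta = beta[perm]
            cov = cov[np.ix_(perm, perm)]
        return ANOVAResults(self, beta, cov, sigma2, df_resid, table)


@dataclasses.dataclass
class RegressionResult:
    """OLS of a phenophase date on (ln) cumulative TDD."""

    label: str
    slope: float
    intercept: float
    r_squared: float
    df: int
    p_value: float
    ln_covariate: bool

    def summary(self) -> str:
        pred = "ln(cumulative TDD)" if self.ln_covariate else "cumulative TDD"
        return (
            f"{self.label} ~ {pred}: slope={self.slope:.4g}, R^2={self.r_squared:.3f}, "
            f"df={self.df}, p={self.p_value:.3g}"
        )


def regress_on_tdd(
    response: pd.Series,
    covariate: pd.Series,
    ln_transform: bool = True,
    label: str = "",
) -> RegressionResult:
    """Simple regression of a plot-level date on its cumulative TDD."""
    import statsmodels.api as sm

    y = pd.Series(response, dtype=float).dropna()
    c = pd.Series(covariate, dtype=float).dropna()
    idx = y.index.intersection(c.index)
    if len(idx) < 3:
        raise ValueError("need at least 3 plots for regression")
    x = apply_transform(c.loc[idx], "ln" if ln_transform else "none")
    if np.ptp(x.to_numpy()) == 0:
        raise ValueError("covariate has zero variance")
    res = sm.OLS(y.loc[idx].to_numpy(), sm.add_constant(x.to_numpy())).fit()
    return RegressionResult(
        label=label or (response.name or "response"),
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        df=int(res.df_resid),
        p_value=float(res.pvalues[1]),
        ln_covariate=ln_transform,
    )


@dataclasses.dataclass
class AicComparison:
    """ML-based AIC comparison: plain linear model vs transect random intercept."""

    label: str
    aic_linear: float
    aic_mixed: float
    singular: bool

    @property
    def supported(self) -> str:
        return "linear" if self.aic_linear <= self.aic_mixed else "mixed"


def compare_random_effect(
    response: pd.Series,
    factors: pd.DataFrame,
    label: str = "",
    transform: str = "none",
) -> AicComparison:
    """Is a transect random intercept supported on top of the 2x2 fixed effects?

    Both models are fitted by maximum likelihood (not REML) so their AICs are
    on the same footing; AIC = -2 logL + 2k with k counting mean parameters
    plus variance parameters (one for the plain model, two for the mixed).
    A variance component estimated at (numerically) zero is reported via the
    ``singular`` flag, not raised.
    """
    import statsmodels.api as sm

    fac = factors.set_index("plot_id") if "plot_id" in factors.columns else factors
    y = pd.Series(response, dtype=float).dropna()
    idx = y.index.intersection(fac.index).sort_values()
    if fac.loc[idx, "transect_id"].nunique() < 2:
        raise ValueError("need at least 2 transects for the random-effect comparison")
    yv = apply_transform(y.loc[idx], transform).to_numpy()
    a = (fac.loc[idx, "ground_state"] == GROUND_STATES[1]).to_numpy(float)
    b = (fac.loc[idx, "polygon_feature"] == POLYGON_FEATURES[1]).to_numpy(float)
    X = np.column_stack([np.ones_like(a), a, b, a * b])
    ols = sm.OLS(yv, X).fit()
    k_lin = X.shape[1] + 1
    aic_lin = -2.0 * float(ols.llf) + 2.0 * k_lin
    groups = fac.loc[idx, "transect_id"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mm = sm.MixedLM(yv, X, groups=groups)
        try:
            mixed = mm.fit(reml=False)
        except np.linalg.LinAlgError:
            mixed = mm.fit(reml=False, method="powell")
    k_mix = X.shape[1] + 2
    aic_mix = -2.0 * float(mixed.llf) + 2.0 * k_mix
    singular = bool(float(np.squeeze(mixed.cov_re)) < 1e-8 * max(mixed.scale, 1e-300))
    return AicComparison(
        label=label or (response.name or "response"),
        aic_linear=aic_lin,
        aic_mixed=aic_mix,
        singular=singular,
    )
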