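"""Plot-level habitat statistics and canopy-structure -> microclimate models.

Sample-point summaries are aggregated to plots (mean/min/max of the
per-sample ROI means); treeless grassland plots receive the structural
defaults LAI = 0, FCover = 0, NDVI_up = -1.  Habitats are compared with
pairwise two-sided Wilcoxon rank-sum tests under Bonferroni adjustment.
Single-predictor relationships between ground metrics (NDVI_down,
Thermal_ground) and canopy structure (FCover, LAI, NDVI_up) are fitted
both as ordinary linear models and as penalized-spline smooths; the
model with the higher adjusted R-squared is selected, with ties going to
the simpler linear model.  Air-temperature effects enter through the
interaction model  Thermal_ground ~ structure * T_air,  whose intercept
and structure slope can be evaluated at any chosen T_air.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.smooth_basis import BSplines

__all__ = [
    "ModelFit",
    "InteractionFit",
    "aggregate_to_plot",
    "assign_treeless_defaults",
    "pairwise_wilcoxon",
    "fit_lm",
    "fit_gam",
    "select_model",
    "fit_interaction",
    "evaluate_at_tair",
    "predict_change",
    "TREELESS_DEFAULTS",
]

TREELESS_DEFAULTS = {"lai": 0.0, "fcover": 0.0, "ndvi_up": -1.0}

#: adjusted-R2 difference below which two fits count as "the same"
#: (reporting is to two decimals, so differences under half a unit in the
#: second decimal are not distinguishable)
R2_TIE = 0.005


@dataclass
class ModelFit:
    """A fitted single-predictor relationship (LM or penalized smooth)."""

    kind: str                     # "LM" or "GAM"
    response: str
    predictor: str
    intercept: float
    coefficient: float            # LM slope; GAM: effective df of the smooth
    adjusted_r2: float
    p_values: dict = field(default_factory=dict)
    n: int = 0
    conf_int: dict = field(default_factory=dict)   # 95% CIs per parameter
    _predict: object = None       # callable, used by GAM prediction

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "LM":
            return self.intercept + self.coefficient * x
        if self._predict is None:
            raise ValueError("smooth fit carries no prediction function")
        return self._predict(x)

    def summary(self) -> str:
        head = f"{self.response} ~ {self.predictor}  [{self.kind}, n={self.n}]"
        if self.kind == "LM":
            body = (f"  intercept {self.intercept:.4g}  coefficient "
                    f"{self.coefficient:.4g}")
        else:
            body = (f"  intercept {self.intercept:.4g}  smooth edf "
                    f"{self.coefficient:.2f}")
        return f"{head}\n{body}\n  adjusted R2 {self.adjusted_r2:.3f}"


@dataclass
class InteractionFit:
    """OLS fit of  y ~ 1 + x + T_air + x:T_air  (four coefficients)."""

    b0: float
    b_struct: float
    b_T: float
    b_interact: float
    adjusted_r2: float
    p_values: dict = field(default_factory=dict)
    n: int = 0
    struct_name: str = "FCover"
    conf_int: dict = field(default_factory=dict)   # 95% CIs per parameter

    def evaluate_at_tair(self, t_air: float) -> tuple[float, float]:
        return evaluate_at_tair(self, t_air)

    def summary(self) -> str:
        return (
            f"Thermal_ground ~ {self.struct_name} * T_air  [n={self.n}]\n"
            f"  intercept   {self.b0:.6f}\n"
            f"  {self.struct_name:<11} {self.b_struct:.6f}\n"
            f"  T_air       {self.b_T:.6f}\n"
            f"  interaction {self.b_interact:.6f}\n"
            f"  adjusted R2 {self.adjusted_r2:.3f}"
        )


def aggregate_to_plot(samples: pd.DataFrame, statistic: str = "mean") -> pd.DataFrame:
    """Aggregate accepted sample-point summaries to one value per plot/metric.

    ``samples`` needs columns plot_id, metric, mean and optionally
    excluded (bool).  The plot value is the chosen statistic (mean, min
    or max) of the per-sample ROI means; excluded samples are skipped and
    a plot with no accepted samples gets a missing value for that metric.
    """
    if statistic not in ("mean", "min", "max"):
        raise ValueError(f"unsupported statistic {statistic!r}")
    df = samples.copy()
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    wide = (
        df.groupby(["plot_id", "metric"])["mean"]
        .agg(statistic)
        .unstack("metric")
    )
    # plots present in the input but with every sample excluded -> all-NaN row
    all_plots = pd.Index(samples["plot_id"].unique(), name="plot_id")
    return wide.reindex(all_plots)


def assign_treeless_defaults(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the no-trees defaults to grassland plots.

    Grassland plots carry no canopy, so LAI and FCover are set to 0 and
    NDVI_up to -1.  Measured canopy values on a grassland row trigger a
    warning but are still overwritten.
    """
    out = records.copy()
    grass = out["habitat"] == "grassland"
    for col, default in TREELESS_DEFAULTS.items():
        if col not in out.columns:
            out[col] = np.nan
        measured = grass & out[col].notna() & (out[col] != default)
        if measured.any():
            warnings.warn(
                f"grassland plots {out.loc[measured, 'plot_id'].tolist() if 'plot_id' in out else measured.sum()} "
                f"carry measured {col}; treeless default applied",
                stacklevel=2,
            )
        out.loc[grass, col] = default
    return out


def _rank_sum_p(x, y) -> float:
    """Two-sided rank-sum p-value: exact when combined n <= 12 without
    ties, normal approximation with tie and continuity correction
    otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def pairwise_wilcoxon(groups: dict, adjustment: str = "bonferroni") -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests with Bonferroni adjustment.

    ``groups`` maps label -> 1-d samples.  Returns a symmetric DataFrame
    of adjusted p-values, NaN on the diagonal.  Adjusted p = min(1,
    raw p x number of pairs).
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValueError(f"unsupported adjustment {adjustment!r}")
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(np.asarray(vals)) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    n_pairs = len(labels) * (len(labels) - 1) // 2
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            p = _rank_sum_p(groups[a], groups[b])
            if adjustment == "bonferroni":
                p = min(1.0, p * n_pairs)
            mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def fit_lm(y, x, response: str = "y", predictor: str = "x") -> ModelFit:
    """Ordinary least squares y ~ 1 + x with adjusted R-squared and
    two-sided t-test p-values."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return ModelFit(
        kind="LM",
        response=response,
        predictor=predictor,
        intercept=float(res.params[0]),
        coefficient=float(res.params[1]),
        adjusted_r2=float(res.rsquared_adj),
        p_values={"intercept": float(res.pvalues[0]),
                  "coefficient": float(res.pvalues[1])},
        n=n,
        conf_int={
            "intercept": tuple(map(float, res.conf_int()[0])),
            "coefficient": tuple(map(float, res.conf_int()[1])),
        },
    )


def _gam_design(x, df, degree):
    bs = BSplines(np.asarray(x, dtype=float).reshape(-1, 1),
                  df=[df], degree=[degree])
    basis = bs.basis
    k = basis.shape[1] + 1
    pen = np.zeros((k, k))
    pen[1:, 1:] = bs.penalty_matrices[0]
    return bs, pen


def fit_gam(y, x, response: str = "y", predictor: str = "x",
            df: int = 10, degree: int = 3) -> ModelFit:
    """One-dimensional penalized regression spline (basis dimension 10).

    The smoothing weight is chosen by generalized cross-validation,
    GCV(a) = n RSS(a) / (n - edf(a))^2, over a log-spaced grid; near-ties
    resolve to the smoother fit.  Reports the effective degrees of
    freedom of the smooth term (edf ~ 1 means essentially linear) and the
    adjusted R-squared 1 - (RSS / (n - edf_total)) / (TSS / (n - 1)).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    n = len(y)
    if n < 8:
        raise ValueError("need at least 8 observations for the spline basis")
    bs, pen = _gam_design(x, df, degree)
    X = np.column_stack([np.ones(n), bs.basis])
    XtX = X.T @ X
    Xty = X.T @ y
    tss = float(((y - y.mean()) ** 2).sum())
    best = None  # (gcv, alpha, beta, edf, rss)
    atol = 1e-10 * max(tss / n, 1e-12)
    for alpha in 10.0 ** np.arange(-6.0, 10.5, 0.5):
        # pseudo-inverse: the demeaned spline basis is rank-deficient by
        # construction, and heavy penalties make the system near-singular
        Minv = np.linalg.pinv(XtX + alpha * pen)
        beta = Minv @ Xty
        edf = float(np.trace(Minv @ XtX))
        rss = float(((y - X @ beta) ** 2).sum())
        gcv = n * rss / (n - edf) ** 2
        # iterate alphas ascending; on a near-tie keep the smoother fit
        if best is None or gcv < best[0] - atol:
            best = (gcv, alpha, beta, edf, rss)
        elif gcv <= best[0] + atol:
            best = (gcv, alpha, beta, edf, rss)
    _, alpha, beta, edf_total, rss = best
    edf_smooth = edf_total - 1.0
    adj_r2 = (1.0 - (rss / (n - edf_total)) / (tss / (n - 1))) if tss > 0 else 0.0

    def _predict(xnew, _bs=bs, _beta=beta):
        xnew = np.asarray(xnew, dtype=float).reshape(-1, 1)
        basis = _bs.transform(xnew)
        return _beta[0] + basis @ _beta[1:]

    # approximate significance of the smooth term: F-test against the
    # intercept-only model on effective degrees of freedom
    if tss > rss and n - edf_total > 0 and edf_smooth > 0:
        f = ((tss - rss) / edf_smooth) / (rss / (n - edf_total)) if rss > 0 else np.inf
        p_smooth = float(stats.f.sf(f, edf_smooth, max(n - edf_total, 1e-6)))
    else:
        p_smooth = 1.0
    return ModelFit(
        kind="GAM",
        response=response,
        predictor=predictor,
        intercept=float(beta[0]),
        coefficient=edf_smooth,
        adjusted_r2=float(adj_r2),
        p_values={"smooth": p_smooth},
        n=n,
        _predict=_predict,
    )


def select_model(lm: ModelFit, gam: ModelFit, tie: float = R2_TIE) -> ModelFit:
    """Pick the fit with the higher adjusted R-squared; ties (|difference|
    < 0.005, i.e. indistinguishable at two-decimal reporting) go to the
    simpler linear model."""
    if (lm.response, lm.predictor) != (gam.response, gam.predictor):
        raise ValueError("fits describe different variables")
    if abs(lm.adjusted_r2 - gam.adjusted_r2) < tie:
        return lm
    return lm if lm.adjusted_r2 > gam.adjusted_r2 else gam


def fit_interaction(y, x_struct, t_air, struct_name: str = "FCover") -> InteractionFit:
    """OLS with terms {1, x, T_air, x * T_air}."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x_struct, dtype=float)
    t = np.asarray(t_air, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x) & np.isfinite(t)
    y, x, t = y[ok], x[ok], t[ok]
    n = len(y)
    if n < 6:
        raise ValueError("need at least 6 observations")
    X = np.column_stack([np.ones(n), x, t, x * t])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("degenerate design: predictors are collinear")
    res = sm.OLS(y, X).fit()
    return InteractionFit(
        b0=float(res.params[0]),
        b_struct=float(res.params[1]),
        b_T=float(res.params[2]),
        b_interact=float(res.params[3]),
        adjusted_r2=float(res.rsquared_adj),
        p_values={k: float(v) for k, v in zip(
            ("intercept", "struct", "t_air", "interaction"), res.pvalues)},
        n=n,
        struct_name=struct_name,
        conf_int={k: tuple(map(float, ci)) for k, ci in zip(
            ("intercept", "struct", "t_air", "interaction"), res.conf_int())},
    )


def evaluate_at_tair(fit: InteractionFit, t_air: float) -> tuple[float, float]:
    """Intercept and structure slope of the interaction model at a chosen
    air temperature: intercept = b0 + b_T * T, slope = b_struct +
    b_interact * T."""
    intercept = fit.b0 + fit.b_T * t_air
    slope = fit.b_struct + fit.b_interact * t_air
    return float(intercept), float(slope)


def predict_change(fit: ModelFit, delta_x: float) -> float:
    """Response change for a predictor change of ``delta_x`` under a
    linear fit (coefficient x delta).  A smooth fit has no single slope."""
    if fit.kind != "LM":
        raise ValueError("marginal change is only defined for a linear fit")
    return float(fit.coefficient * delta_x)
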