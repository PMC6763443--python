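"""Mortality driver models: standardized logistic odds and binned-rate regression.

The covariates (tree height, canopy cover, maximum VPD, temperature and
precipitation anomalies, slope, soil available water capacity) are
transformed (log for skewed height and slope), optionally converted to
percent anomalies against historical normals, and z-standardized so
coefficients are directly comparable across drivers. Collinearity is
screened with variance inflation factors (flagging VIF >= 2). Mortality
likelihood is modeled with a binary-outcome logistic regression fit by
iteratively reweighted least squares; mortality *rate* is modeled by
weighted multiple linear regression over a table of narrow covariate bins,
with each bin's rate computed as dead/total divided by the observation lag.
Effects are reported both per standard deviation and per conventional
physical increment (e.g. an odds ratio per 10 m of height).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: covariate columns in canonical order
DRIVER_COLUMNS = ("height", "cover_pct", "vpd_max", "dt_pct", "dppt_pct",
                  "slope_pct", "soil_awc")

DEFAULT_TRANSFORMS = {"height": "log", "slope_pct": "log1p"}

#: conventional physical increments for reporting effect sizes
DEFAULT_INCREMENTS = {"height": 10.0, "vpd_max": 0.4, "dt_pct": 2.9,
                      "dppt_pct": 4.0, "soil_awc": 6.2, "cover_pct": 17.0}

DEFAULT_BIN_WIDTHS = {"height": 5.0, "vpd_max": 0.1, "dt_pct": 2.0,
                      "dppt_pct": 2.0, "soil_awc": 5.0, "cover_pct": 10.0,
                      "slope_pct": 5.0}


@dataclass
class CovariateMatrix:
    """Standardized design matrix plus the metadata to undo it.

    ``meta`` has one row per column: transform tag, mean and SD of the
    transformed variable (the standardization constants), and the mean on
    the natural scale (used for local linearization of log-scale effects).
    """

    X: pd.DataFrame
    meta: pd.DataFrame

    def back_transform(self, column: str, z):
        """Map a standardized value back to the covariate's natural scale."""
        m = self.meta.loc[column]
        t = m["mean"] + m["sd"] * np.asarray(z, dtype=float)
        if m["transform"] == "log":
            return np.exp(t)
        if m["transform"] == "log1p":
            return np.expm1(t)
        return t


def prepare_covariates(records: pd.DataFrame, columns=None, transforms=None,
                       normals: dict | None = None) -> CovariateMatrix:
    """Transform, anomaly-convert, and z-standardize the driver covariates.

    `normals` optionally maps a column (raw temperature / precipitation) to
    its historical normal; such columns are replaced by percent deviation
    (100 * (x - normal) / normal) before standardization. A zero-variance
    column is an error naming the column.
    """
    columns = list(columns) if columns is not None else \
        [c for c in DRIVER_COLUMNS if c in records.columns]
    transforms = dict(DEFAULT_TRANSFORMS if transforms is None else transforms)
    X = {}
    meta = []
    for col in columns:
        x = records[col].to_numpy(dtype=float)
        if not np.isfinite(x).all():
            raise ValueError(f"column {col!r} has non-finite values")
        if normals and col in normals:
            x = 100.0 * (x - normals[col]) / normals[col]
        nat_mean = float(np.mean(x))
        tag = transforms.get(col, "identity")
        if tag == "log":
            if (x <= 0).any():
                raise ValueError(f"log transform of non-positive values in {col!r}")
            t = np.log(x)
        elif tag == "log1p":
            if (x < 0).any():
                raise ValueError(f"log1p transform of negative values in {col!r}")
            t = np.log1p(x)
        elif tag == "identity":
            t = x
        else:
            raise ValueError(f"unknown transform {tag!r}")
        mu, sd = float(t.mean()), float(t.std(ddof=0))
        if sd == 0.0:
            raise ValueError(f"column {col!r} has zero variance")
        X[col] = (t - mu) / sd
        meta.append({"column": col, "transform": tag, "mean": mu, "sd": sd,
                     "natural_mean": nat_mean})
    return CovariateMatrix(X=pd.DataFrame(X),
                           meta=pd.DataFrame(meta).set_index("column"))


def compute_vif(X: pd.DataFrame, flag_at: float = 2.0) -> pd.DataFrame:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j) from regressing
    column j on the remaining columns (with intercept). Perfectly collinear
    columns report infinite VIF. Flags VIF >= `flag_at`."""
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than columns")
    rows = []
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]).to_numpy())
        fit = sm.OLS(X[col].to_numpy(), others).fit()
        r2 = min(fit.rsquared, 1.0)
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"column": col, "vif": vif, "flagged": bool(vif >= flag_at)})
    return pd.DataFrame(rows).set_index("column")


@dataclass
class ModelFit:
    """Fitted-model summary shared by the logistic and rate models."""

    params: pd.Series
    bse: pd.Series
    llf: float
    n: int
    converged: bool
    n_iter: int
    loglik_path: list = field(default_factory=list)
    grad_norm: float = np.nan
    baseline_rate: float = np.nan
    kind: str = "logistic"

    @property
    def conf_int(self) -> pd.DataFrame:
        lo = self.params - 1.96 * self.bse
        hi = self.params + 1.96 * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})


def fit_logistic(X: pd.DataFrame, y, max_iter: int = 50,
                 tol: float = 1e-8) -> ModelFit:
    """Binary logistic regression by iteratively reweighted least squares.

    An intercept is always included. Convergence is declared when the
    largest coefficient change falls below `tol`; standard errors come from
    the inverse observed information at the optimum. Quasi-complete
    separation (a coefficient diverging) raises, naming the worst variable.
    The per-iteration log-likelihood path and the final gradient norm are
    retained so monotonicity of the optimization can be asserted.
    """
    X = pd.DataFrame(X)
    yv = np.asarray(y, dtype=float)
    if set(np.unique(yv)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if yv.min() == yv.max():
        raise ValueError("y must contain both classes")
    names = ["intercept"] + list(X.columns)
    A = np.column_stack([np.ones(len(yv)), X.to_numpy(dtype=float)])
    beta = np.zeros(A.shape[1])
    pbar = yv.mean()
    beta[0] = np.log(pbar / (1 - pbar))
    loglik_path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = A @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        loglik_path.append(float(np.sum(yv * np.log(mu) + (1 - yv) * np.log(1 - mu))))
        w = mu * (1.0 - mu)
        z = eta + (yv - mu) / w
        Aw = A * w[:, None]
        try:
            new_beta = np.linalg.solve(A.T @ Aw, Aw.T @ z)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(f"singular information matrix: {e}")
        step = np.abs(new_beta - beta).max()
        beta = new_beta
        if np.abs(beta).max() > 30:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise RuntimeError(
                f"logistic fit diverging (complete separation?); worst "
                f"coefficient: {worst!r}")
        if step < tol:
            converged = True
            break
    if not converged:
        worst = names[int(np.argmax(np.abs(beta)))]
        raise RuntimeError(
            f"logistic fit did not converge in {max_iter} iterations "
            f"(complete separation?); worst coefficient: {worst!r}")
    eta = A @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    llf = float(np.sum(yv * np.log(mu) + (1 - yv) * np.log(1 - mu)))
    loglik_path.append(llf)
    grad = A.T @ (yv - mu)
    w = mu * (1.0 - mu)
    info = A.T @ (A * w[:, None])
    cov = np.linalg.inv(info)
    bse = np.sqrt(np.diag(cov))
    return ModelFit(params=pd.Series(beta, index=names),
                    bse=pd.Series(bse, index=names),
                    llf=llf, n=len(yv), converged=converged, n_iter=it,
                    loglik_path=loglik_path, grad_norm=float(np.linalg.norm(grad)),
                    baseline_rate=float(yv.mean()), kind="logistic")


def _per_unit_scale(meta_row, increment: float) -> float:
    """Standardized-coefficient multiplier for a `increment`-sized change on
    the covariate's natural scale.

    Identity transform: increment / sd. Log transforms: local linearization
    at the natural-scale mean, d(log x) ~ dx / x_bar, so the multiplier is
    increment / (sd * x_bar) (x_bar + 1 for log1p)."""
    sd = meta_row["sd"]
    if meta_row["transform"] == "log":
        return increment / (sd * meta_row["natural_mean"])
    if meta_row["transform"] == "log1p":
        return increment / (sd * (1.0 + meta_row["natural_mean"]))
    return increment / sd


def odds_ratio_report(fit: ModelFit, matrix: CovariateMatrix,
                      increments: dict | None = None) -> pd.DataFrame:
    """Odds ratios per SD and per physical increment, with 95% CIs.

    For log-transformed covariates the per-increment odds ratio uses a
    local linearization at the covariate's mean, and is flagged as such
    (the effect of, say, +10 m is then only locally constant). The report
    also notes whether the odds ratio can be read as an approximate
    relative risk (baseline mortality < 3%).
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    increments = dict(DEFAULT_INCREMENTS if increments is None else increments)
    rows = []
    rr_ok = fit.baseline_rate < 0.03
    for col in matrix.X.columns:
        if col not in fit.params.index:
            continue
        b = fit.params[col]
        se = fit.bse[col]
        row = {"variable": col,
               "or_per_sd": np.exp(b),
               "or_per_sd_lo": np.exp(b - 1.96 * se),
               "or_per_sd_hi": np.exp(b + 1.96 * se),
               "direction": "risk-increasing" if b > 0 else
                            ("risk-decreasing" if b < 0 else "null"),
               "rr_approx_valid": rr_ok}
        inc = increments.get(col)
        if inc is not None:
            if inc == 0:
                raise ValueError(f"zero increment for {col!r}")
            mrow = matrix.meta.loc[col]
            scale = _per_unit_scale(mrow, inc)
            row.update({
                "increment": inc,
                "or_per_increment": np.exp(b * scale),
                "or_per_increment_lo": np.exp((b - 1.96 * se) * scale),
                "or_per_increment_hi": np.exp((b + 1.96 * se) * scale),
                "increment_linearized": mrow["transform"] != "identity",
            })
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def fit_reduced_vpd(records: pd.DataFrame, columns=None, transforms=None,
                    increments: dict | None = None, y_col: str = "dead"):
    """Reduced logistic model: VPD retained, temperature and precipitation
    anomalies dropped (they are nearly collinear with VPD). Returns
    (ModelFit, odds-ratio report, CovariateMatrix)."""
    cols = list(columns) if columns is not None else \
        [c for c in DRIVER_COLUMNS if c in records.columns]
    cols = [c for c in cols if c not in ("dt_pct", "dppt_pct")]
    matrix = prepare_covariates(records, columns=cols, transforms=transforms)
    fit = fit_logistic(matrix.X, records[y_col].to_numpy(dtype=float))
    report = odds_ratio_report(fit, matrix, increments)
    return fit, report, matrix


def binned_rates(records: pd.DataFrame, bin_widths: dict | None = None,
                 lag_years: float = 2.0, n_min: int = 25,
                 y_col: str = "dead") -> pd.DataFrame:
    """Mortality-rate table over narrow covariate bins.

    Each record is assigned to the unique combination of bins of all
    covariates; per combination rate = dead / total / lag_years * 100
    (% yr^-1, capped at 100/lag by construction). Combinations with fewer
    than `n_min` trees are excluded and counted in the log. Bin labels are
    bin centers.
    """
    if len(records) == 0:
        raise ValueError("no records to bin")
    widths = dict(DEFAULT_BIN_WIDTHS if bin_widths is None else bin_widths)
    widths = {k: w for k, w in widths.items() if k in records.columns}
    if not widths:
        raise ValueError("no binnable covariates present")
    for k, w in widths.items():
        if w <= 0:
            raise ValueError(f"non-positive bin width for {k!r}")
    centers = {}
    for k, w in widths.items():
        centers[k] = (np.floor(records[k].to_numpy(dtype=float) / w) + 0.5) * w
    df = pd.DataFrame(centers)
    df["_dead"] = records[y_col].to_numpy(dtype=float)
    grouped = df.groupby(list(widths), as_index=False).agg(
        n=("_dead", "size"), n_dead=("_dead", "sum"))
    n_small = int((grouped["n"] < n_min).sum())
    if n_small:
        logger.info("excluded %d bin combinations with n < %d", n_small, n_min)
    grouped = grouped[grouped["n"] >= n_min].reset_index(drop=True)
    grouped["n_dead"] = grouped["n_dead"].astype(int)
    grouped["rate_pct_yr"] = grouped["n_dead"] / grouped["n"] / lag_years * 100.0
    grouped.attrs["n_excluded_small"] = n_small
    grouped.attrs["lag_years"] = lag_years
    return grouped


def fit_rate_model(rate_table: pd.DataFrame, predictors=None,
                   transforms=None, increments: dict | None = None,
                   weight_col: str = "n"):
    """Weighted multiple linear regression of binned mortality rate on the
    standardized bin-center covariates, weighting rows by tree count.

    Returns (ModelFit, per-increment rate-change report, CovariateMatrix).
    Rate changes per physical increment are in % yr^-1 (linear model, so the
    conversion is exact for identity transforms and locally linearized for
    log transforms).
    """
    predictors = list(predictors) if predictors is not None else \
        [c for c in DRIVER_COLUMNS if c in rate_table.columns]
    if len(rate_table) < len(predictors) + 2:
        raise ValueError("need at least predictors + 2 rows")
    matrix = prepare_covariates(rate_table, columns=predictors, transforms=transforms)
    y = rate_table["rate_pct_yr"].to_numpy(dtype=float)
    w = rate_table[weight_col].to_numpy(dtype=float)
    A = sm.add_constant(matrix.X.to_numpy())
    res = sm.WLS(y, A, weights=w).fit()
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("rank-deficient design in rate model")
    names = ["intercept"] + list(matrix.X.columns)
    fit = ModelFit(params=pd.Series(res.params, index=names),
                   bse=pd.Series(res.bse, index=names),
                   llf=float(res.llf), n=len(y), converged=True, n_iter=1,
                   kind="rate-wls")
    increments = dict(DEFAULT_INCREMENTS if increments is None else increments)
    rows = []
    for col in matrix.X.columns:
        b = fit.params[col]
        se = fit.bse[col]
        row = {"variable": col, "rate_change_per_sd": b,
               "rate_per_sd_lo": b - 1.96 * se, "rate_per_sd_hi": b + 1.96 * se}
        inc = increments.get(col)
        if inc is not None:
            scale = _per_unit_scale(matrix.meta.loc[col], inc)
            row.update({"increment": inc,
                        "rate_change_per_increment": b * scale,
                        "rate_per_increment_lo": (b - 1.96 * se) * scale,
                        "rate_per_increment_hi": (b + 1.96 * se) * scale})
        rows.append(row)
    report = pd.DataFrame(rows).set_index("variable")
    return fit, report, matrix
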