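"""Multilevel modelling of log-transformed tissue proportions.

Each composition table contains several samples per heart, so proportions
are analysed with a linear mixed model on the log scale:

    log(value) = cell mean (location × region) [+ covariates] + heart + ε,

with a random intercept per heart capturing the clustered structure.  The
model is fit by REML (statsmodels ``MixedLM``).  Back-transformed cell
predictions are geometric means with Wald 95% CIs (``exp(est ± 1.96·SE)``),
and between-cell comparisons are geometric-mean ratios
``exp(est_a − est_b)`` with Wald CIs and two-sided p-values.  No
small-sample degrees-of-freedom correction and no multiplicity adjustment
are applied; see docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "ModelFit",
    "RatioEstimate",
    "fit_multilevel",
    "predict_geometric_means",
    "contrast_ratio",
    "covariate_tests",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def cell_name(location: str, region: str) -> str:
    return f"{location}|{region}"


@dataclass
class ModelFit:
    """Fitted mixed model for one tissue component.

    ``fixed_effects`` maps cell/covariate names to log-scale (estimate, SE);
    ``vcov`` is the fixed-effect covariance in the order of ``names``.
    """

    component: str
    names: list[str]
    cells: list[str]
    covariate_names: list[str]
    estimates: np.ndarray
    vcov: np.ndarray
    heart_var: float
    resid_var: float
    n_obs: int
    n_hearts: int
    estimation: str = "REML"
    covariate_means: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    @property
    def fixed_effects(self) -> dict[str, tuple[float, float]]:
        se = np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))
        return {n: (float(e), float(s)) for n, e, s in zip(self.names, self.estimates, se)}

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"{name!r} is not a term of this fit; terms: {self.names}")


def _encode_covariates(
    df: pd.DataFrame, covariates: list[str]
) -> tuple[np.ndarray, dict[str, float]]:
    """Numeric covariate matrix, centred so cell means stay interpretable
    as predictions at sample-average covariates.  Sex is coded F=1."""
    cols, means = [], {}
    for cov in covariates:
        if cov == "sex":
            vals = (
                df["sex"].astype(str).str.upper().map({"F": 1.0, "M": 0.0})
            )
            if vals.isna().any():
                vals = pd.to_numeric(df["sex"], errors="coerce")
            x = vals.to_numpy(dtype=float)
        else:
            x = pd.to_numeric(df[cov], errors="coerce").to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"covariate {cov!r} has missing/non-numeric values")
        mu = float(x.mean())
        means[cov] = mu
        cols.append(x - mu)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, means


def _handle_zeros(
    values: np.ndarray, component: str, policy: str
) -> np.ndarray:
    """Zero proportions break the log transform.  ``halfmin`` replaces them
    with half the smallest positive observed value for the component (with
    a warning); ``fail`` raises instead."""
    zero = values <= 0
    if not zero.any():
        return values
    if policy == "fail":
        idx = np.flatnonzero(zero)
        raise ValueError(
            f"non-positive {component} values at rows {idx.tolist()} "
            "(zero_policy='fail')"
        )
    if policy != "halfmin":
        raise ValueError("zero_policy must be 'halfmin' or 'fail'")
    pos = values[values > 0]
    if pos.size == 0:
        raise ValueError(f"all {component} values are non-positive")
    repl = 0.5 * float(pos.min())
    warnings.warn(
        f"replaced {int(zero.sum())} non-positive {component} value(s) with "
        f"half the smallest positive value ({repl:g})",
        UserWarning,
        stacklevel=3,
    )
    out = values.copy()
    out[zero] = repl
    return out


def fit_multilevel(
    table: pd.DataFrame,
    component: str,
    covariates: list[str] | None = None,
    reml: bool = True,
    zero_policy: str = "halfmin",
) -> ModelFit:
    """Fit the random-intercept model on log(value_pct) for one component.

    Fixed effects are cell means for every (location, region) cell present,
    plus optional centred covariates (sex, age, bmi); the random intercept
    groups rows by ``heart_id``.

    Raises
    ------
    ValueError
        On non-positive values under ``zero_policy='fail'``, fewer than two
        hearts, or a rank-deficient design (e.g. a constant covariate).
    """
    covariates = list(covariates or [])
    df = table[table["component"] == component].copy()
    if df.empty:
        raise ValueError(f"no rows for component {component!r}")
    n_hearts = df["heart_id"].nunique()
    if n_hearts < 2:
        raise ValueError("need at least 2 hearts for a multilevel fit")
    values = df["value_pct"].to_numpy(dtype=float)
    values = _handle_zeros(values, component, zero_policy)
    y = np.log(values)

    cells = sorted(
        {cell_name(l, r) for l, r in zip(df["location"], df["region"])}
    )
    cell_of_row = [cell_name(l, r) for l, r in zip(df["location"], df["region"])]
    cell_idx = {c: j for j, c in enumerate(cells)}
    Xc = np.zeros((len(df), len(cells)))
    Xc[np.arange(len(df)), [cell_idx[c] for c in cell_of_row]] = 1.0
    Xv, cov_means = _encode_covariates(df, covariates)
    X = np.column_stack([Xc, Xv]) if covariates else Xc
    names = cells + covariates

    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = [
            cov
            for cov, col in zip(covariates, Xv.T)
            if np.allclose(col, col[0])
        ]
        detail = f"constant covariate(s): {bad}" if bad else "collinear design"
        raise ValueError(f"rank-deficient fixed-effect design ({detail})")

    groups = df["heart_id"].to_numpy()
    k = X.shape[1]

    # Degenerate limit: (near-)zero residual variation makes the mixed-model
    # likelihood singular; the exact solution is then the OLS projection with
    # zero variance components, which we return rather than mask the
    # singularity behind an optimizer failure.
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid_ols = y - X @ beta_ols
    if float(np.max(np.abs(resid_ols))) < 1e-10:
        return ModelFit(
            component=component,
            names=names,
            cells=cells,
            covariate_names=covariates,
            estimates=beta_ols,
            vcov=np.zeros((k, k)),
            heart_var=0.0,
            resid_var=0.0,
            n_obs=len(df),
            n_hearts=int(n_hearts),
            estimation="degenerate-zero-variance",
            covariate_means=cov_means,
            converged=True,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        res = None
        last_err: Exception | None = None
        for method in ("lbfgs", "cg", "powell"):
            try:
                res = model.fit(reml=reml, method=method)
                break
            except (np.linalg.LinAlgError, ValueError) as err:
                last_err = err
        if res is None:
            raise RuntimeError(
                f"mixed-model fit failed for component {component!r}"
            ) from last_err
    vcov = np.asarray(res.cov_params())[:k, :k]
    heart_var = float(np.asarray(res.cov_re)[0, 0])
    return ModelFit(
        component=component,
        names=names,
        cells=cells,
        covariate_names=covariates,
        estimates=np.asarray(res.fe_params, dtype=float),
        vcov=vcov,
        heart_var=heart_var,
        resid_var=float(res.scale),
        n_obs=len(df),
        n_hearts=int(n_hearts),
        estimation="REML" if reml else "ML",
        covariate_means=cov_means,
        converged=bool(getattr(res, "converged", True)),
    )


def predict_geometric_means(fit: ModelFit) -> pd.DataFrame:
    """Back-transformed cell predictions.

    geometric_mean = exp(cell estimate); 95% CI = exp(estimate ± 1.96·SE).
    With covariates in the fit, predictions are at sample-average covariate
    values (covariates are centred at fit time).
    """
    fe = fit.fixed_effects
    rows = []
    for cell in fit.cells:
        est, se = fe[cell]
        loc, region = cell.split("|", 1)
        rows.append(
            {
                "component": fit.component,
                "location": loc,
                "region": region,
                "geometric_mean": float(np.exp(est)),
                "ci_low": float(np.exp(est - Z95 * se)),
                "ci_high": float(np.exp(est + Z95 * se)),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RatioEstimate:
    """Geometric-mean ratio between two cells with Wald CI and p-value."""

    numerator: str
    denominator: str
    ratio: float
    ci_low: float
    ci_high: float
    p_value: float


def contrast_ratio(fit: ModelFit, cell_a: str, cell_b: str) -> RatioEstimate:
    """Geometric-mean ratio of ``cell_a`` over ``cell_b``.

    ratio = exp(est_a − est_b); the SE of the log-difference comes from the
    fixed-effect covariance; CI = exp(diff ± 1.96·SE); two-sided Wald
    p-value.  ``cell_a == cell_b`` is the allowed degenerate identity
    (ratio exactly 1, p = 1).
    """
    if cell_a == cell_b:
        return RatioEstimate(cell_a, cell_b, 1.0, 1.0, 1.0, 1.0)
    ia, ib = fit.index_of(cell_a), fit.index_of(cell_b)
    diff = float(fit.estimates[ia] - fit.estimates[ib])
    var = float(fit.vcov[ia, ia] + fit.vcov[ib, ib] - 2.0 * fit.vcov[ia, ib])
    se = float(np.sqrt(max(var, 0.0)))
    if se > 0:
        z = diff / se
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        p = 0.0 if diff != 0 else 1.0
    return RatioEstimate(
        numerator=cell_a,
        denominator=cell_b,
        ratio=float(np.exp(diff)),
        ci_low=float(np.exp(diff - Z95 * se)),
        ci_high=float(np.exp(diff + Z95 * se)),
        p_value=p,
    )


def covariate_tests(fit: ModelFit) -> pd.DataFrame:
    """Wald test per covariate on the log scale (estimate, SE, p-value)."""
    if not fit.covariate_names:
        raise ValueError("fit contains no covariates")
    fe = fit.fixed_effects
    rows = []
    for cov in fit.covariate_names:
        est, se = fe[cov]
        z = est / se if se > 0 else np.inf * np.sign(est)
        rows.append(
            {
                "covariate": cov,
                "estimate": est,
                "se": se,
                "p_value": float(2.0 * sps.norm.sf(abs(z))),
            }
        )
    return pd.DataFrame(rows)
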