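"""Allometric model family and fitting engine.

The central model is the log-power form

    ln(y) = a * ln(x)^b + c

with ``y`` body mass (g) and ``x`` a linear skeletal measurement (mm). For a
fixed exponent ``b`` this is linear in ``(a, c)`` and is fitted by ordinary
least squares on the transformed design; ``b`` can also be estimated freely by
non-linear least squares. Fractional exponents in {1/3, 1/2, 2/3, 3/4}
correspond to the candidate scaling regimes considered when comparing models;
quadratic and cubic polynomials in ln(x) are the conventional alternative
parameterization of non-linear allometry.

Natural logarithms are used throughout and the base is deliberately not
configurable: silently mixing bases is a classic source of coefficient
mismatches in the allometry literature.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "ModelTerm",
    "AllometricModelSpec",
    "FittedModel",
    "NLSFit",
    "GroupAllometryTest",
    "RankDeficientError",
    "transform_predictor",
    "fit_model",
    "fit_free_exponent",
    "compare_models",
    "test_group_allometry",
    "POWER_LADDER",
]

_POLY_DEGREE = {"quadratic": 2, "cubic": 3}


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; message names the collinear terms."""


@dataclass(frozen=True)
class ModelTerm:
    """One transformed predictor.

    ``transform`` is either a float power ``p`` (the column is ``ln(x)^p``;
    ``p = 1`` is the plain log-linear term) or one of ``'quadratic'`` /
    ``'cubic'`` (polynomial columns ``ln x, (ln x)^2, ...``).
    """

    predictor: str
    transform: float | str = 1.0

    def label(self) -> str:
        if isinstance(self.transform, str):
            return f"{self.predictor}:{self.transform}"
        if self.transform == 1.0:
            return f"ln_{self.predictor}"
        return f"ln_{self.predictor}^{_fmt_power(self.transform)}"


def _fmt_power(p: float) -> str:
    for num, den in ((1, 3), (1, 2), (2, 3), (3, 4)):
        if math.isclose(p, num / den):
            return f"{num}/{den}"
    return f"{p:g}"


@dataclass(frozen=True)
class AllometricModelSpec:
    """Model definition: response, transformed terms, additive covariates.

    Covariates are either plain column names (used as-is; the usual case is a
    0/1 dummy such as ``rabbit_like`` or ``captive``) or ``(name, 'ln')``
    pairs for continuous covariates entered on the log scale (e.g. brain
    mass).
    """

    response: str = "body_mass"
    terms: tuple[ModelTerm, ...] = (ModelTerm("ocw", 2 / 3),)
    covariates: tuple = ()
    name: str = ""

    def label(self) -> str:
        if self.name:
            return self.name
        parts = [t.label() for t in self.terms]
        parts += [c if isinstance(c, str) else f"ln_{c[0]}" for c in self.covariates]
        return f"ln_{self.response} ~ " + " + ".join(parts)

    @staticmethod
    def power(p: float, predictor: str = "ocw", response: str = "body_mass",
              covariates: Sequence = (), name: str = "") -> "AllometricModelSpec":
        return AllometricModelSpec(
            response=response,
            terms=(ModelTerm(predictor, p),),
            covariates=tuple(covariates),
            name=name,
        )

    @staticmethod
    def polynomial(kind: str, predictor: str = "ocw", response: str = "body_mass",
                   name: str = "") -> "AllometricModelSpec":
        return AllometricModelSpec(
            response=response, terms=(ModelTerm(predictor, kind),), name=name
        )


#: The standard comparison ladder: linear, fractional powers, polynomials.
POWER_LADDER: tuple[AllometricModelSpec, ...] = (
    AllometricModelSpec.power(1.0, name="linear"),
    AllometricModelSpec.power(1 / 3, name="1/3 power"),
    AllometricModelSpec.power(1 / 2, name="1/2 power"),
    AllometricModelSpec.power(2 / 3, name="2/3 power"),
    AllometricModelSpec.power(3 / 4, name="3/4 power"),
    AllometricModelSpec.polynomial("quadratic", name="quadratic"),
    AllometricModelSpec.polynomial("cubic", name="cubic"),
)


def transform_predictor(x, transform: float | str = 1.0) -> np.ndarray:
    """Apply a log-power or log-polynomial transform to a positive measurement.

    Returns a 1-D array ``ln(x)^p`` for power transforms, or an ``(n, degree)``
    array of polynomial columns for ``'quadratic'`` / ``'cubic'``. Fractional
    powers require ``x > 1`` so that ``ln x`` is positive (a negative log has
    no real fractional power).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("predictor values must be strictly positive")
    lx = np.log(x)
    if isinstance(transform, str):
        degree = _POLY_DEGREE.get(transform)
        if degree is None:
            raise ValueError(f"unknown transform {transform!r}")
        return np.column_stack([lx ** d for d in range(1, degree + 1)])
    p = float(transform)
    if p == 1.0:
        return lx
    if not float(p).is_integer() and np.any(x <= 1):
        raise ValueError(
            "fractional log-power transforms require x > 1 (ln x must be "
            "positive before taking a fractional power)"
        )
    return lx ** p


def _design(
    data: pd.DataFrame, spec: AllometricModelSpec, check: bool = True
) -> tuple[np.ndarray, pd.DataFrame]:
    """Build (ln-response, design frame with named columns incl. intercept)."""
    y_raw = np.asarray(data[spec.response], dtype=float)
    if np.any(y_raw <= 0):
        raise ValueError(f"response {spec.response!r} must be strictly positive")
    y = np.log(y_raw)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(data))}
    for term in spec.terms:
        block = transform_predictor(data[term.predictor], term.transform)
        if block.ndim == 1:
            cols[term.label()] = block
        else:
            base = f"ln_{term.predictor}"
            for d in range(block.shape[1]):
                cols[base if d == 0 else f"{base}^{d + 1}"] = block[:, d]
    for cov in spec.covariates:
        if isinstance(cov, str):
            cols[cov] = np.asarray(data[cov], dtype=float)
        else:
            name, tf = cov
            if tf != "ln":
                raise ValueError(f"unknown covariate transform {tf!r}")
            vals = np.asarray(data[name], dtype=float)
            if np.any(vals <= 0):
                raise ValueError(f"covariate {name!r} must be positive for ln")
            cols[f"ln_{name}"] = np.log(vals)
    X = pd.DataFrame(cols, index=data.index)
    if not check:  # prediction rows: no variance/rank requirements
        return y, X
    degenerate = [c for c in X.columns if c != "intercept" and np.ptp(X[c].values) == 0]
    if degenerate:
        raise ValueError(f"predictors with zero variance after transform: {degenerate}")
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        corr = np.corrcoef(X.values.T[1:]) if X.shape[1] > 2 else None
        raise RankDeficientError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"check collinearity among {list(X.columns[1:])}"
            + (f"; correlation matrix:\n{np.round(corr, 3)}" if corr is not None else "")
        )
    return y, X


def _gaussian_loglik(rss: float, n: int) -> float:
    # ML log-likelihood of a Gaussian linear model with profiled variance
    return -0.5 * n * (math.log(2 * math.pi) + math.log(rss / n) + 1.0)


@dataclass
class FittedModel:
    """An OLS fit of a transformed-predictor linear model on the ln scale."""

    spec: AllometricModelSpec
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame  # columns 'lower', 'upper'
    resid: np.ndarray
    fitted: np.ndarray  # ln scale
    observed: np.ndarray  # ln scale
    n: int
    df_resid: int
    s2: float  # residual mean square, RSS / df_resid
    see: float  # standard error of estimate on ln scale, sqrt(s2)
    r2_adj: float
    loglik: float
    aic: float
    bic: float
    x_range: dict[str, tuple[float, float]]  # raw predictor training range
    _X: pd.DataFrame = field(repr=False, default=None)
    _XtX_inv: np.ndarray = field(repr=False, default=None)
    _sm_results: object = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return len(self.params)

    def design_row(self, data_row: pd.DataFrame) -> np.ndarray:
        """Design vector(s) for new observations (same columns as training)."""
        _, X = _design(_with_dummy_response(data_row, self.spec), self.spec, check=False)
        return X[self.params.index].values

    def to_dict(self) -> dict:
        return {
            "model": self.spec.label(),
            "coefficients": self.params.to_dict(),
            "standard_errors": self.bse.to_dict(),
            "conf_int": {
                k: [float(self.conf_int.loc[k, "lower"]), float(self.conf_int.loc[k, "upper"])]
                for k in self.params.index
            },
            "n": self.n,
            "df_resid": self.df_resid,
            "s2": self.s2,
            "see": self.see,
            "r2_adj": self.r2_adj,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "x_range": {k: list(v) for k, v in self.x_range.items()},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _with_dummy_response(data: pd.DataFrame, spec: AllometricModelSpec) -> pd.DataFrame:
    if spec.response in data.columns:
        return data
    data = data.copy()
    data[spec.response] = 1.0  # placeholder; only the design columns are used
    return data


def fit_model(data: pd.DataFrame, spec: AllometricModelSpec) -> FittedModel:
    """Fit a fixed-exponent (or polynomial) allometric model by OLS.

    Log-likelihood, AIC and BIC follow the Gaussian-ML convention with the
    error variance counted as an estimated parameter (parameter count
    ``k + 1``), the convention used by R's ``lm``/``AIC`` and hence by most of
    the comparative literature.
    """
    y, X = _design(data, spec)
    n, k = X.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} observations to fit {k} coefficients")
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    loglik = _gaussian_loglik(rss, n)
    npar = k + 1
    ci = res.conf_int(alpha=0.05)
    ci.columns = ["lower", "upper"]
    x_range = {
        t.predictor: (float(data[t.predictor].min()), float(data[t.predictor].max()))
        for t in spec.terms
    }
    return FittedModel(
        spec=spec,
        params=res.params,
        bse=res.bse,
        conf_int=ci,
        resid=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        observed=y,
        n=n,
        df_resid=int(res.df_resid),
        s2=rss / res.df_resid,
        see=math.sqrt(rss / res.df_resid),
        r2_adj=float(res.rsquared_adj),
        loglik=loglik,
        aic=-2 * loglik + 2 * npar,
        bic=-2 * loglik + math.log(n) * npar,
        x_range=x_range,
        _X=X,
        _XtX_inv=np.linalg.inv(X.values.T @ X.values),
        _sm_results=res,
    )


@dataclass
class NLSFit:
    """Free-exponent fit of ln(y) = a * ln(x)^b + c by non-linear least squares."""

    a: float
    b: float
    c: float
    se: dict[str, float]
    conf_int: dict[str, tuple[float, float]]  # asymptotic (Wald) 95% intervals
    resid: np.ndarray
    fitted: np.ndarray
    n: int
    df_resid: int
    s2: float
    see: float
    r2_adj: float
    loglik: float
    aic: float
    bic: float
    converged: bool
    predictor: str = "ocw"
    response: str = "body_mass"

    @property
    def params(self) -> dict[str, float]:
        return {"a": self.a, "b": self.b, "c": self.c}


class NLSConvergenceError(RuntimeError):
    def __init__(self, message: str, best: NLSFit | None = None):
        super().__init__(message)
        self.best = best


def fit_free_exponent(
    data: pd.DataFrame,
    predictor: str = "ocw",
    response: str = "body_mass",
    init: tuple[float, float, float] | None = None,
    fix_exponent: float | None = None,
) -> NLSFit:
    """Estimate (a, b, c) of ln(y) = a * ln(x)^b + c by least squares.

    Initialization defaults to the 2/3-power OLS solution for (a, c) with
    b0 = 2/3; on non-convergence, bounded restarts are attempted from
    b0 in {1/3, 1/2, 3/4, 1}. Confidence intervals are asymptotic Wald
    intervals from the (J'J)^-1 curvature at the optimum with the
    t-distribution on n - 3 degrees of freedom. ``fix_exponent`` pins b,
    reducing the problem to the corresponding fixed-exponent OLS.
    """
    x = np.asarray(data[predictor], dtype=float)
    y_raw = np.asarray(data[response], dtype=float)
    if np.any(x <= 1):
        raise ValueError("free-exponent fitting requires predictor values > 1")
    if np.any(y_raw <= 0):
        raise ValueError("response must be strictly positive")
    lx = np.log(x)
    y = np.log(y_raw)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 observations for a 3-parameter fit")
    if np.ptp(lx) == 0:
        raise ValueError("predictor has zero variance")

    def inner_ols(b: float) -> tuple[float, float, float]:
        t = lx ** b
        X = np.column_stack([t, np.ones(n)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        return float(beta[0]), float(beta[1]), rss

    if fix_exponent is not None:
        a, c, rss = inner_ols(fix_exponent)
        b_hat = float(fix_exponent)
        free = ["a", "c"]
        theta = np.array([a, b_hat, c])
        success = True
    else:
        def residual_fn(theta):
            a, b, c = theta
            return a * lx ** b + c - y

        if init is None:
            a0, c0, _ = inner_ols(2 / 3)
            init = (a0, 2 / 3, c0)
        starts = [init]
        for b0 in (1 / 3, 1 / 2, 3 / 4, 1.0):
            a0, c0, _ = inner_ols(b0)
            starts.append((a0, b0, c0))
        best = None
        success = False
        for start in starts:
            sol = scipy.optimize.least_squares(
                residual_fn, np.asarray(start, dtype=float),
                bounds=([-np.inf, 1e-6, -np.inf], [np.inf, 5.0, np.inf]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            if best is None or sol.cost < best.cost:
                best = sol
            if sol.success:
                success = True
                if sol is best:
                    break
        theta = best.x
        a, b_hat, c = (float(v) for v in theta)
        rss = float(2 * best.cost)
        free = ["a", "b", "c"]

    t_col = lx ** b_hat
    fitted = a * t_col + c
    resid = y - fitted
    df_resid = n - (3 if fix_exponent is None else 2)
    s2 = rss / df_resid
    # Jacobian of the mean function wrt the free parameters at the optimum
    jac_cols = {"a": t_col, "b": a * t_col * np.log(lx), "c": np.ones(n)}
    J = np.column_stack([jac_cols[p] for p in free])
    cov = s2 * np.linalg.inv(J.T @ J)
    tcrit = scipy.stats.t.ppf(0.975, df_resid)
    se = {p: float(np.sqrt(cov[i, i])) for i, p in enumerate(free)}
    est = {"a": a, "b": b_hat, "c": c}
    ci = {
        p: (est[p] - tcrit * se[p], est[p] + tcrit * se[p]) for p in free
    }
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1 - rss / tss
    k_mean = len(free)
    r2_adj = 1 - (1 - r2) * (n - 1) / df_resid
    loglik = _gaussian_loglik(rss, n)
    npar = k_mean + 1
    fit = NLSFit(
        a=a, b=b_hat, c=c, se=se, conf_int=ci,
        resid=resid, fitted=fitted, n=n, df_resid=df_resid,
        s2=s2, see=math.sqrt(s2), r2_adj=r2_adj,
        loglik=loglik, aic=-2 * loglik + 2 * npar,
        bic=-2 * loglik + math.log(n) * npar,
        converged=bool(success), predictor=predictor, response=response,
    )
    if fix_exponent is None and not success:
        raise NLSConvergenceError(
            "non-linear least squares did not converge from any start; "
            "best-so-far fit attached", best=fit,
        )
    return fit


def compare_models(
    data: pd.DataFrame,
    specs: Iterable[AllometricModelSpec],
) -> pd.DataFrame:
    """Fit a list of model specs on the same observations and tabulate
    AIC / BIC / logLik / df / r2_adj plus back-transformed accuracy columns
    (%PE, CF, %PEcf, %SEE). Fit failures annotate the row instead of aborting
    the table.
    """
    from . import accuracy  # local import; accuracy is downstream of fitting

    rows = []
    for spec in specs:
        label = spec.label()
        try:
            fit = fit_model(data, spec)
        except Exception as exc:
            rows.append({"model": label, "error": str(exc)})
            continue
        cf = accuracy.correction_factors(fit)
        rep = accuracy.accuracy_report(fit, cf)
        rows.append(
            {
                "model": label,
                "aic": fit.aic,
                "bic": fit.bic,
                "loglik": fit.loglik,
                "df": fit.df_resid,
                "r2_adj": fit.r2_adj,
                "pct_pe": rep.mean_abs_pe,
                "cf": cf.mean_cf,
                "pct_pe_cf": rep.mean_abs_pe_cf,
                "pct_see": rep.pct_see,
                "error": "",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupAllometryTest:
    """Result of a two-group slope or intercept comparison."""

    grouping: str
    term: str  # 'slope' or 'intercept'
    t: float
    p: float
    coefficient: float  # interaction (slope) or group main effect (intercept)
    group_coefficients: pd.DataFrame  # per-group slope and intercept
    n_groups: tuple[int, int]


def test_group_allometry(
    data: pd.DataFrame,
    grouping: float | str,
    term: str = "slope",
    spec: AllometricModelSpec | None = None,
) -> GroupAllometryTest:
    """Test whether two groups share a slope or an intercept.

    ``grouping`` is either a mass threshold in grams (groups are observations
    above / at-or-below the threshold on the response) or the name of a 0/1
    flag column. The spec must have a single power term. For ``term='slope'``
    the model adds a group main effect plus a group-by-predictor interaction
    and reports the interaction t and p; for ``term='intercept'`` only the
    main effect is added and its t and p are reported.
    """
    if spec is None:
        spec = AllometricModelSpec.power(2 / 3)
    if len(spec.terms) != 1 or isinstance(spec.terms[0].transform, str):
        raise ValueError("group tests require a single power term")
    if term not in ("slope", "intercept"):
        raise ValueError("term must be 'slope' or 'intercept'")

    if isinstance(grouping, str):
        flag = np.asarray(data[grouping], dtype=float)
        desc = grouping
    else:
        flag = (np.asarray(data[spec.response], dtype=float) > float(grouping)).astype(float)
        desc = f"{spec.response} > {grouping:g} g"
    n1 = int(flag.sum())
    n0 = int(len(flag) - n1)
    if n0 < 3 or n1 < 3:
        side = "flagged/above-threshold" if n1 < 3 else "reference/below-threshold"
        raise ValueError(
            f"both groups need >= 3 observations; the {side} group has "
            f"{min(n0, n1)}"
        )

    y, X = _design(data, spec)
    xcol = X.columns[1]
    work = X.copy()
    work["group"] = flag
    if term == "slope":
        work["group_x"] = flag * X[xcol].values
    res = sm.OLS(y, work).fit()
    target = "group_x" if term == "slope" else "group"
    # per-group effective coefficients
    slope0 = float(res.params[xcol])
    int0 = float(res.params["intercept"])
    slope1 = slope0 + (float(res.params["group_x"]) if term == "slope" else 0.0)
    int1 = int0 + float(res.params["group"])
    groups = pd.DataFrame(
        {"slope": [slope0, slope1], "intercept": [int0, int1]},
        index=["group0", "group1"],
    )
    return GroupAllometryTest(
        grouping=desc,
        term=term,
        t=float(res.tvalues[target]),
        p=float(res.pvalues[target]),
        coefficient=float(res.params[target]),
        group_coefficients=groups,
        n_groups=(n0, n1),
    )
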