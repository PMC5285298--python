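"""Panel estimators: pooled OLS / linear probability models, probits,
two-level random-intercept models, the stacked-IMR two-step selection
estimator, and first differences with an exogenous price shock.

Model specifications are declarative (:class:`ModelSpec`), naming an outcome,
covariates, an optional random-intercept level (doctor or practice), year
dummies and a row filter. Ordinary fits are delegated to statsmodels (OLS,
Probit, MixedLM with full maximum likelihood); the selection correction, the
first-difference estimator and the inverse Mills ratio are implemented here.

Conventions: age enters as a quadratic, centred at 45 for conditioning, with
coefficients reported back on the original scale; linear probability fits are
never clipped but report the share of fitted values outside [0, 1]; standard
errors are conventional by default with practice clustering available.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from scipy.special import log_ndtr
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "ModelSpec",
    "FitResult",
    "SelectionResult",
    "CollinearityError",
    "SeparationError",
    "EstimationConvergenceError",
    "ols_fit",
    "probit_fit",
    "inverse_mills",
    "random_intercept_fit",
    "heckman_selection_fit",
    "first_difference_fit",
    "first_difference_by_quintile",
    "exclusion_restriction_check",
]

AGE_CENTER = 45.0


class CollinearityError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


class SeparationError(RuntimeError):
    """A binary-outcome fit is perfectly separated (no silent divergence)."""


class EstimationConvergenceError(RuntimeError):
    """An iterative fit failed to converge."""


@dataclass
class ModelSpec:
    """Declarative model specification.

    ``group_level`` is ``"doctor"``, ``"practice"`` or ``None`` (pooled);
    ``filter_query`` a pandas query string applied before fitting;
    ``cluster`` an optional column for clustered standard errors.
    """

    outcome: str
    covariates: list[str]
    group_level: str | None = None
    year_dummies: bool = False
    filter_query: str | None = None
    cluster: str | None = None

    def __post_init__(self) -> None:
        if self.group_level not in (None, "doctor", "practice"):
            raise ValueError("group_level must be None, 'doctor' or 'practice'")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, payload: str) -> "ModelSpec":
        return cls(**json.loads(payload))


@dataclass
class FitResult:
    """Coefficients and inference for one fitted model."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n_obs: int
    loglike: float | None = None
    sigma_u2: float | None = None
    sigma_e2: float | None = None
    n_groups: int | None = None
    extra: dict = field(default_factory=dict)

    def coef(self, name: str) -> float:
        return float(self.params[name])

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table with significance stars (* 10%, ** 5%, *** 1%)."""
        stars = pd.cut(
            self.pvalues, [-np.inf, 0.01, 0.05, 0.10, np.inf], labels=["***", "**", "*", ""]
        ).astype(str)
        return pd.DataFrame({"coef": self.params, "se": self.bse, "p": self.pvalues, "sig": stars})


@dataclass
class SelectionResult:
    """Artifacts of the two-step selection estimator."""

    first_stages: dict[int, FitResult]
    imr: pd.Series
    second_stage: FitResult
    skipped_years: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Design-matrix construction
# ---------------------------------------------------------------------------

def _group_column(level: str | None) -> str | None:
    return {None: None, "doctor": "doctor_id", "practice": "practice_id"}[level]


def build_design(
    panel: pd.DataFrame, spec: ModelSpec, extra_covariates: list[str] | None = None
) -> tuple[pd.Series, pd.DataFrame, pd.Series | None, pd.DataFrame]:
    """Outcome vector, design matrix (with constant), groups and the used rows.

    ``age`` in the covariate list expands to a centred quadratic
    (``age - 45`` and its square); year dummies omit the first year. Rows with
    missing values in any used column are dropped.
    """
    df = panel.query(spec.filter_query) if spec.filter_query else panel
    covs = list(spec.covariates) + list(extra_covariates or [])
    needed = [spec.outcome] + [c for c in covs if c != "age"]
    if "age" in covs:
        needed.append("age")
    if spec.year_dummies:
        needed.append("year")
    gcol = _group_column(spec.group_level)
    if gcol:
        needed.append(gcol)
    if spec.cluster:
        needed.append(spec.cluster)
    df = df.dropna(subset=[c for c in dict.fromkeys(needed)])
    if len(df) <= len(covs) + 2:
        raise ValueError(
            f"filter leaves {len(df)} rows for {len(covs)} covariates; too few to fit"
        )

    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    for c in covs:
        if c == "age":
            ac = df["age"].astype(float) - AGE_CENTER
            X["age_c"] = ac
            X["age_c_sq"] = ac**2
        else:
            X[c] = df[c].astype(float)
    if spec.year_dummies:
        dummies = pd.get_dummies(df["year"].astype(int), prefix="year", drop_first=True)
        for c in dummies.columns:
            X[c] = dummies[c].astype(float)
    y = df[spec.outcome].astype(float)
    groups = df[gcol] if gcol else None
    return y, X, groups, df


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, _, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
        offending = sorted(X.columns[piv[rank:]])
        raise CollinearityError(f"design matrix is rank deficient; offending columns: {offending}")


def _uncenter_age(params: pd.Series, bse: pd.Series, cov: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Report the age quadratic on the original scale.

    With b1, b2 on (age - c) and (age - c)^2, the original-scale coefficients
    are age: b1 - 2 c b2 and age^2: b2, with the delta-method standard error.
    """
    if "age_c" not in params.index:
        return params, bse
    b1, b2 = params["age_c"], params["age_c_sq"]
    v1 = cov.loc["age_c", "age_c"]
    v2 = cov.loc["age_c_sq", "age_c_sq"]
    c12 = cov.loc["age_c", "age_c_sq"]
    a_coef = b1 - 2.0 * AGE_CENTER * b2
    a_var = v1 + 4.0 * AGE_CENTER**2 * v2 - 4.0 * AGE_CENTER * c12
    params = params.rename({"age_c": "age", "age_c_sq": "age_sq"}).copy()
    bse = bse.rename({"age_c": "age", "age_c_sq": "age_sq"}).copy()
    params["age"] = a_coef
    bse["age"] = np.sqrt(max(a_var, 0.0))
    return params, bse


# ---------------------------------------------------------------------------
# Core fits
# ---------------------------------------------------------------------------

def ols_fit(
    spec: ModelSpec, panel: pd.DataFrame, extra_covariates: list[str] | None = None
) -> FitResult:
    """Pooled least squares (also the linear probability model).

    Conventional standard errors by default; set ``spec.cluster`` to a column
    name (typically ``practice_id``) for cluster-robust ones. Binary outcomes
    are not clipped; the share of fitted values outside [0, 1] is reported in
    ``extra['lpm_out_of_range_share']``.
    """
    y, X, _, df = build_design(panel, spec, extra_covariates)
    _check_rank(X)
    model = sm.OLS(y.to_numpy(), X)
    if spec.cluster:
        res = model.fit(cov_type="cluster", cov_kwds={"groups": df[spec.cluster]})
    else:
        res = model.fit()
    params, bse = _uncenter_age(res.params, res.bse, res.cov_params())
    pvals = res.pvalues.rename(dict(zip(res.params.index, params.index)))
    extra = {}
    if set(np.unique(y)) <= {0.0, 1.0}:
        fitted = res.fittedvalues
        extra["lpm_out_of_range_share"] = float(((fitted < 0) | (fitted > 1)).mean())
    return FitResult(
        params=params, bse=bse, pvalues=pvals, n_obs=int(res.nobs), loglike=float(res.llf),
        extra=extra,
    )


def probit_fit(
    spec: ModelSpec, panel: pd.DataFrame, extra_covariates: list[str] | None = None
) -> FitResult:
    """Maximum-likelihood probit by Newton-Raphson.

    Raises :class:`SeparationError` on perfect separation or divergence and
    :class:`EstimationConvergenceError` if the optimiser stalls; both classes
    of failure are surfaced, never silent.
    """
    y, X, _, df = build_design(panel, spec, extra_covariates)
    classes = set(np.unique(y))
    if not classes <= {0.0, 1.0}:
        raise ValueError(f"probit outcome must be binary 0/1, got values {sorted(classes)[:5]}")
    if len(classes) < 2:
        raise ValueError("probit outcome takes a single value; both classes required")
    _check_rank(X)
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Probit(y.to_numpy(), X).fit(method="newton", maxiter=100, disp=0)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(str(exc)) from exc
    if np.any(~np.isfinite(res.params)) or np.max(np.abs(res.params)) > 1e3:
        raise SeparationError("probit likelihood diverged; outcome is (quasi-)separated")
    if not res.mle_retvals.get("converged", False):
        raise EstimationConvergenceError("probit Newton-Raphson did not converge")
    params, bse = _uncenter_age(res.params, res.bse, res.cov_params())
    pvals = res.pvalues.rename(dict(zip(res.params.index, params.index)))
    return FitResult(
        params=params, bse=bse, pvalues=pvals, n_obs=int(res.nobs), loglike=float(res.llf),
        extra={"converged": bool(res.mle_retvals.get("converged", False)),
               "linear_index": pd.Series(np.asarray(X @ res.params), index=X.index)},
    )


def inverse_mills(index):
    """Inverse Mills ratio phi(x)/Phi(x) of the standard normal.

    Strictly positive and strictly decreasing; evaluated as
    exp(log phi - log Phi) so that deep negative indices (where both density
    and distribution function underflow) remain accurate.
    Accepts scalars or arrays.
    """
    x = np.asarray(index, dtype=float)
    out = np.exp(-0.5 * x * x - 0.5 * np.log(2.0 * np.pi) - log_ndtr(x))
    return float(out) if np.isscalar(index) else out


def random_intercept_fit(
    spec: ModelSpec, panel: pd.DataFrame, extra_covariates: list[str] | None = None
) -> FitResult:
    """Two-level linear model with a single random intercept, full ML.

    Fixed effects plus variance components (sigma_u^2 between groups,
    sigma_e^2 residual); the grouping level is ``spec.group_level``.
    """
    if spec.group_level is None:
        raise ValueError("random_intercept_fit requires a group level")
    y, X, groups, _ = build_design(panel, spec, extra_covariates)
    if groups.nunique() < 2:
        raise ValueError("need at least two groups for a random intercept")
    _check_rank(X)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary sigma_u ~ 0 warnings are expected
        for method in ("bfgs", "powell", "lbfgs"):
            model = sm.MixedLM(y.to_numpy(), X, groups=groups.to_numpy())
            candidate = model.fit(reml=False, method=method)
            # a boundary fit can report convergence with an infinite likelihood
            if candidate.converged and np.isfinite(candidate.llf):
                res = candidate
                break
    if res is None:
        raise EstimationConvergenceError("random-intercept ML did not converge")
    fe = res.fe_params
    cov = res.cov_params().loc[fe.index, fe.index]
    params, bse = _uncenter_age(fe, res.bse_fe, cov)
    pvals = res.pvalues[fe.index].rename(dict(zip(fe.index, params.index)))
    return FitResult(
        params=params,
        bse=bse,
        pvalues=pvals,
        n_obs=int(res.nobs),
        loglike=float(res.llf),
        sigma_u2=float(res.cov_re.iloc[0, 0]),
        sigma_e2=float(res.scale),
        n_groups=int(groups.nunique()),
    )


# ---------------------------------------------------------------------------
# Selection (stacked-IMR two-step)
# ---------------------------------------------------------------------------

def heckman_selection_fit(
    stay_spec: ModelSpec,
    outcome_spec: ModelSpec,
    panel: pd.DataFrame,
    exclusion_var: str = "years_to_retirement",
) -> SelectionResult:
    """Two-step selection estimator with year-by-year first stages.

    Stage one fits a probit of staying in the market separately for each year;
    the exclusion variable (years to statutory retirement) must appear in the
    stay equation and must not appear in the outcome equation. From each
    year's fit the inverse Mills ratio is computed at the linear index, the
    yearly series are stacked, and the stacked IMR joins the surviving
    (stayer) rows as an additional covariate of the second-stage model — a
    random-intercept model when ``outcome_spec.group_level`` is set, pooled
    OLS otherwise. Years in which the stay outcome takes a single value are
    flagged and excluded with a warning.
    """
    if exclusion_var not in stay_spec.covariates:
        raise ValueError(f"stay equation must contain the exclusion variable {exclusion_var!r}")
    if exclusion_var in outcome_spec.covariates:
        raise ValueError(f"outcome equation must not contain {exclusion_var!r}")

    first_stages: dict[int, FitResult] = {}
    skipped: list[int] = []
    imr_parts: list[pd.Series] = []
    stay_col = stay_spec.outcome
    for year, chunk in panel.groupby("year"):
        if chunk[stay_col].nunique() < 2:
            warnings.warn(f"year {year}: stay outcome single-valued; skipped", stacklevel=2)
            skipped.append(int(year))
            continue
        fs = probit_fit(stay_spec, chunk)
        index = fs.extra.pop("linear_index")
        lam = pd.Series(inverse_mills(index.to_numpy()), index=index.index)
        stayers = chunk.index[chunk[stay_col] == 1]
        imr_parts.append(lam.loc[lam.index.intersection(stayers)])
        first_stages[int(year)] = fs
    if not first_stages:
        raise ValueError("no year had both stay classes; selection model unidentified")
    imr = pd.concat(imr_parts).sort_index()

    surviving = panel.loc[panel.index.intersection(imr.index)].copy()
    surviving["imr"] = imr
    if outcome_spec.group_level is None:
        second = ols_fit(outcome_spec, surviving, extra_covariates=["imr"])
    else:
        second = random_intercept_fit(outcome_spec, surviving, extra_covariates=["imr"])
    return SelectionResult(
        first_stages=first_stages, imr=imr, second_stage=second, skipped_years=skipped
    )


# ---------------------------------------------------------------------------
# First differences
# ---------------------------------------------------------------------------

def first_difference_fit(
    spec: ModelSpec,
    panel: pd.DataFrame,
    shock_var: str | None = None,
    years: tuple[int, int] = (2005, 2006),
    level_vars: list[str] | None = None,
) -> FitResult:
    """OLS on within-doctor differences across two consecutive years.

    Doctor-constant unobservables difference out. Covariates whose difference
    is constant across doctors (time-invariant ones such as gender, and age,
    whose difference is identically one) are dropped with a warning; the
    shock variable and any ``level_vars`` enter in levels of the difference
    equation (their later-year values).
    """
    y0, y1 = years
    level_vars = list(level_vars or [])
    if shock_var is not None:
        level_vars = [shock_var] + level_vars
    sub = panel[panel["year"].isin(years)]
    if spec.filter_query:
        sub = sub.query(spec.filter_query)
    wide_cols = [spec.outcome] + [c for c in spec.covariates if c not in level_vars]
    both = sub.groupby("doctor_id")["year"].nunique() == 2
    keep_ids = both.index[both]
    sub = sub[sub["doctor_id"].isin(keep_ids)]
    a = sub[sub.year == y0].set_index("doctor_id")
    b = sub[sub.year == y1].set_index("doctor_id")
    a, b = a.align(b, join="inner", axis=0)

    dy = (b[spec.outcome] - a[spec.outcome]).astype(float)
    X = pd.DataFrame(index=dy.index)
    X["const"] = 1.0
    dropped = []
    for c in wide_cols[1:]:
        d = (b[c] - a[c]).astype(float)
        if np.nanstd(d.to_numpy()) < 1e-12:
            dropped.append(c)
            continue
        X[f"d_{c}"] = d
    for c in level_vars:
        X[c] = b[c].astype(float)
    if dropped:
        warnings.warn(
            f"covariates constant after differencing dropped: {dropped}", stacklevel=2
        )
    rows = pd.concat([dy.rename("dy"), X], axis=1).dropna()
    if len(rows) <= X.shape[1] + 1:
        raise ValueError("too few complete doctor pairs for first differences")
    _check_rank(rows[X.columns])
    res = sm.OLS(rows["dy"].to_numpy(), rows[X.columns]).fit()
    return FitResult(
        params=res.params, bse=res.bse, pvalues=res.pvalues,
        n_obs=int(res.nobs), loglike=float(res.llf),
        extra={"dropped": dropped, "years": years},
    )


def first_difference_by_quintile(
    spec: ModelSpec,
    panel: pd.DataFrame,
    shock_var: str | None = None,
    years: tuple[int, int] = (2005, 2006),
    perf_var: str = "prop_qof_points",
    perf_year: int = 2004,
) -> dict[str, FitResult]:
    """First differences fit separately for bottom/top practice-performance quintiles.

    Quintiles of practice performance in ``perf_year`` (ties assigned to the
    lower quintile); the panel's ``imr`` column, where present, joins the
    difference equation in levels as the selection control.
    """
    perf = (
        panel.loc[panel["year"] == perf_year]
        .groupby("practice_id")[perf_var]
        .mean()
    )
    pct = perf.rank(method="min", pct=True)
    quintile = np.minimum(np.ceil(pct * 5).astype(int), 5)
    out: dict[str, FitResult] = {}
    levels = ["imr"] if ("imr" in panel.columns and panel["imr"].notna().any()) else []
    for label, q in (("bottom", 1), ("top", 5)):
        ids = quintile.index[quintile == q]
        sub = panel[panel["practice_id"].isin(ids)]
        out[label] = first_difference_fit(
            spec, sub, shock_var=shock_var, years=years, level_vars=levels
        )
    return out


def exclusion_restriction_check(
    panel: pd.DataFrame,
    mobility_spec: ModelSpec,
    exclusion_var: str = "years_to_retirement",
) -> FitResult:
    """Refit the mobility equation with the exclusion variable included.

    Under a valid exclusion restriction, years to statutory retirement shifts
    exit but not between-practice mobility, so its coefficient here should be
    statistically indistinguishable from zero. A constant exclusion variable
    is dropped with a warning (coefficient reported as NaN).
    """
    sub = panel.query(mobility_spec.filter_query) if mobility_spec.filter_query else panel
    if sub[exclusion_var].nunique() <= 1:
        warnings.warn(f"{exclusion_var} is constant; dropped from the check", stacklevel=2)
        base = (
            ols_fit(mobility_spec, panel)
            if mobility_spec.group_level is None
            else random_intercept_fit(mobility_spec, panel)
        )
        base.extra.update({"exclusion_coef": np.nan, "exclusion_pvalue": np.nan,
                           "exclusion_dropped": True})
        return base
    if mobility_spec.group_level is None:
        res = ols_fit(mobility_spec, panel, extra_covariates=[exclusion_var])
    else:
        res = random_intercept_fit(mobility_spec, panel, extra_covariates=[exclusion_var])
    res.extra.update(
        {
            "exclusion_coef": res.coef(exclusion_var),
            "exclusion_pvalue": float(res.pvalues[exclusion_var]),
            "exclusion_dropped": False,
        }
    )
    return res
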