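"""Orchestration: theory sweeps, panel synthesis, the estimation suite and
qualitative-implication reporting.

`run_theory_sweep` evaluates the closed-form equilibrium, region membership,
competition outcomes and the numeric-oracle agreement over a parameter grid.
`run_empirical_suite` generates the census panel, fits the default model suite
(quality, partnership, mobility with selection correction, market entry, FTE,
first differences with the price shock, quintile splits) and checks the three
testable implications of the theory:

1. efficient doctors are more likely to hold a partnership;
2. the introduction of the quality payment raises between-practice mobility;
3. a higher quality price lowers the entry of new salaried doctors.

All randomness flows from one seed; every artifact embeds the seed and a
configuration hash so that a run is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import market_model as mm
from .estimation import (
    FitResult,
    ModelSpec,
    SelectionResult,
    exclusion_restriction_check,
    first_difference_by_quintile,
    first_difference_fit,
    heckman_selection_fit,
    ols_fit,
    random_intercept_fit,
)
from .synthetic_panel import DGPConfig, generate_population, simulate_panel

__all__ = [
    "ExperimentConfig",
    "RecoveryReport",
    "default_model_specs",
    "default_sweep_grid",
    "run_theory_sweep",
    "run_empirical_suite",
    "recovery_report",
    "config_hash",
]

logger = logging.getLogger("gpmobility")

_PRACTICE_COVS = [
    "distance_to_best",
    "total_population",
    "lisi",
    "practice_years",
    "practice_size",
    "prop_f65_74",
    "prop_f75",
    "prop_m65_74",
    "prop_m75",
]


@dataclass
class ExperimentConfig:
    """One reproducible experiment: a data-generating configuration, a model
    suite, a theory-sweep grid, an output directory and a seed."""

    dgp: DGPConfig = field(default_factory=DGPConfig)
    sweep_grid: list[dict] | None = None
    outdir: str | None = None
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        # one seed governs everything downstream
        self.dgp = dataclasses.replace(self.dgp, seed=int(self.seed) + 100)


@dataclass
class RecoveryReport:
    """Truth-vs-estimate table plus the implication sign checks.

    ``parameters`` has one row per recovered parameter (truth, mean estimate,
    mean SE, 95% coverage across reps — NaN for a single rep);
    ``implications`` one row per testable implication, citing the operation
    that produced the check.
    """

    parameters: pd.DataFrame
    implications: pd.DataFrame

    @property
    def all_pass(self) -> bool:
        return bool(self.implications["passed"].all())


def config_hash(config: ExperimentConfig) -> str:
    payload = {
        "dgp": {k: (v if not isinstance(v, dict) else {str(a): b for a, b in v.items()})
                for k, v in dataclasses.asdict(config.dgp).items()},
        "seed": config.seed,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Theory sweep
# ---------------------------------------------------------------------------

def default_sweep_grid() -> list[dict]:
    grid = []
    for p, g, pi, m in itertools.product(
        (0.0, 0.5, 1.0, 125.0 / 76.0, 3.0), (0.3, 0.5, 0.8), (0.1, 0.3, 0.6), (0.05, 0.5)
    ):
        grid.append(dict(m=m, p=p, pi=pi, gamma_v=g, t=0.1, b1=1.0, b2=0.8))
    return grid


def run_theory_sweep(
    grid: list[dict] | None = None, out_csv: str | Path | None = None, seed: int = 0
) -> pd.DataFrame:
    """Equilibrium outcomes, region flags and oracle agreement over a grid.

    Each row carries the parameter draw, salaried and partnership equilibria
    for both types, region membership, competition outcomes where feasible,
    the stage-1 partnership indicator and the maximum absolute disagreement
    between the closed forms and the numeric best-response oracle. Rows whose
    parameters violate the model's domain are flagged invalid, not fatal.
    """
    if grid is None:
        grid = default_sweep_grid()
    if not grid:
        raise ValueError("empty sweep grid")
    rows = []
    for point in grid:
        row = dict(point)
        try:
            params = mm.ModelParams(**point)
        except ValueError as exc:
            row.update(valid=False, error=str(exc))
            rows.append(row)
            continue
        row["valid"] = True
        agree = 0.0
        for contract in (mm.Contract.NEW_SALARIED, mm.Contract.LOCAL_PARTNERSHIP):
            for z in (mm.DoctorType.V, mm.DoctorType.NV):
                closed = mm.equilibrium_outcomes(params, contract, z)
                oracle = mm.numeric_oracle(params, contract, z)
                agree = max(
                    agree,
                    abs(closed.effort - oracle.effort),
                    abs(closed.investment - oracle.investment),
                    abs(closed.practice_profit - oracle.practice_profit),
                    abs(closed.doctor_utility - oracle.doctor_utility),
                )
                key = f"{'sal' if contract == mm.Contract.NEW_SALARIED else 'part'}_{z.value}"
                row[f"effort_{key}"] = closed.effort
                row[f"profit_{key}"] = closed.practice_profit
        row["investment"] = params.p
        rep = mm.region_membership(params, params.gamma_v)
        row.update(
            in_s1=rep.in_s1, in_s2=rep.in_s2, in_s=rep.in_s, in_s_hat=rep.in_s_hat,
            m_bar=rep.m_bar, p_bar=rep.p_bar,
        )
        choice = mm.stage1_contract_choice(params, ("v", "nv"))
        row["partnership_chosen"] = int(
            choice.practice1.contract != mm.Contract.NEW_SALARIED
            or choice.practice2.contract != mm.Contract.NEW_SALARIED
        )
        if rep.in_s_hat:
            comp = mm.competition_outcomes(params)
            row.update(
                w_bar_1=comp.w_bar_1, w_bar_2=comp.w_bar_2,
                profit_contested=comp.profit_contested,
                profit_advantage=comp.profit_advantage,
            )
        row["oracle_agreement"] = agree
        rows.append(row)
    df = pd.DataFrame(rows)
    if out_csv is not None:
        _write_csv(df, out_csv, seed=seed, note="theory sweep")
    return df


# ---------------------------------------------------------------------------
# Default model suite
# ---------------------------------------------------------------------------

def default_model_specs() -> dict[str, ModelSpec]:
    """The estimation suite mirroring the study's table layout.

    quality_singlehanded: pooled OLS of practice QOF performance on doctor and
    practice characteristics in single-handed practices (age as the efficiency
    proxy); partnership / mobility / new_doctors: linear probability models
    with a practice random intercept and year dummies; fte and quality:
    random-intercept models for the price-rise years.
    """
    doctor_covs = ["age", "female", "fte_lag", "income"]
    return {
        "quality_singlehanded": ModelSpec(
            outcome="prop_qof_points",
            # practice_size is 1 by construction in this sample
            covariates=["age", "female", "income"]
            + [c for c in _PRACTICE_COVS if c != "practice_size"],
            filter_query="practice_size == 1 and year in (2004, 2005)",
        ),
        "partnership": ModelSpec(
            outcome="is_partner",
            covariates=["is_efficient"] + doctor_covs + _PRACTICE_COVS,
            group_level="practice",
            year_dummies=True,
        ),
        "mobility": ModelSpec(
            outcome="moved",
            covariates=doctor_covs + _PRACTICE_COVS,
            group_level="practice",
            year_dummies=True,
            filter_query="is_new == 0",
        ),
        "new_doctors": ModelSpec(
            outcome="is_new",
            covariates=["age", "female"] + _PRACTICE_COVS,
            group_level="practice",
            year_dummies=True,
        ),
        "fte": ModelSpec(
            outcome="fte",
            covariates=["age", "female", "income"] + _PRACTICE_COVS,
            group_level="practice",
            year_dummies=True,
            filter_query="year >= 2004",
        ),
        "quality": ModelSpec(
            outcome="prop_qof_points",
            covariates=["age", "female", "income"] + _PRACTICE_COVS,
            group_level="practice",
            year_dummies=True,
            filter_query="year >= 2004",
        ),
        "stay": ModelSpec(
            outcome="stayed",
            covariates=["age", "female", "years_to_retirement"],
        ),
    }


def run_empirical_suite(config: ExperimentConfig) -> dict:
    """Generate the panel, fit the suite, check implications, write artifacts.

    Returns a bundle with the panel, fit results, the selection result, the
    first-difference fits, the implication table and reproducibility metadata.
    Individual estimator failures are recorded in ``bundle['errors']`` and do
    not abort the run.
    """
    chash = config_hash(config)
    logger.info("running empirical suite (seed=%s, config=%s)", config.seed, chash)
    population = generate_population(config.dgp)
    panel = simulate_panel(config.dgp, population)
    panel["stayed"] = 1 - panel["exited"]

    specs = default_model_specs()
    fits: dict[str, FitResult] = {}
    errors: dict[str, str] = {}
    for name in ("quality_singlehanded", "partnership", "new_doctors", "fte", "quality"):
        try:
            spec = specs[name]
            fits[name] = (
                ols_fit(spec, panel) if spec.group_level is None
                else random_intercept_fit(spec, panel)
            )
        except Exception as exc:  # recorded, run continues
            errors[name] = f"{type(exc).__name__}: {exc}"
            logger.warning("fit %s failed: %s", name, exc)

    selection: SelectionResult | None = None
    try:
        selection = heckman_selection_fit(specs["stay"], specs["mobility"], panel)
        fits["mobility"] = selection.second_stage
        # propagate the stacked IMR into the panel for the quintile splits
        panel.loc[selection.imr.index, "imr"] = selection.imr
    except Exception as exc:
        errors["mobility"] = f"{type(exc).__name__}: {exc}"
        logger.warning("selection fit failed: %s", exc)

    exclusion = None
    try:
        exclusion = exclusion_restriction_check(panel, specs["mobility"])
    except Exception as exc:
        errors["exclusion_check"] = f"{type(exc).__name__}: {exc}"
        logger.warning("exclusion-restriction check failed: %s", exc)

    fd_results: dict[str, FitResult] = {}
    try:
        fd_spec = ModelSpec(outcome="fte", covariates=["fte_lag", "income", "practice_size"])
        fd_results["fte_shock"] = first_difference_fit(fd_spec, panel, shock_var="price_shock")
        for label, res in first_difference_by_quintile(
            ModelSpec(outcome="moved", covariates=["income", "practice_size"],
                      filter_query="is_new == 0"),
            panel, shock_var="price_shock",
        ).items():
            fd_results[f"mobility_fd_{label}_quintile"] = res
    except Exception as exc:
        errors["first_difference"] = f"{type(exc).__name__}: {exc}"
        logger.warning("first differences failed: %s", exc)

    implications = _implication_table(fits)
    bundle = {
        "panel": panel,
        "population": population,
        "fits": fits,
        "selection": selection,
        "exclusion_check": exclusion,
        "first_differences": fd_results,
        "implications": implications,
        "errors": errors,
        "seed": config.seed,
        "config_hash": chash,
    }
    if config.outdir:
        _write_bundle(bundle, config)
    return bundle


def _year_coefs(fit: FitResult, years: list[int]) -> list[float]:
    return [fit.coef(f"year_{y}") for y in years if f"year_{y}" in fit.params.index]


def _implication_table(fits: dict[str, FitResult]) -> pd.DataFrame:
    rows = []
    if "partnership" in fits:
        coef = fits["partnership"].coef("is_efficient")
        rows.append(
            {
                "implication": "efficient doctors more likely to hold a partnership",
                "operation": "random_intercept_fit[partnership].coef(is_efficient)",
                "value": coef,
                "passed": coef > 0,
            }
        )
    if "mobility" in fits:
        shift = _year_coefs(fits["mobility"], [2004, 2005, 2006, 2007])
        val = float(np.mean(shift)) if shift else np.nan
        rows.append(
            {
                "implication": "introduction of the quality payment raised mobility",
                "operation": "heckman_selection_fit[mobility].year_dummies(2004+) vs 2003",
                "value": val,
                "passed": bool(shift) and val > 0,
            }
        )
    if "new_doctors" in fits:
        post = _year_coefs(fits["new_doctors"], [2005, 2006, 2007])
        base = fits["new_doctors"].coef("year_2004") if "year_2004" in fits["new_doctors"].params.index else np.nan
        val = float(np.mean(post) - base) if post else np.nan
        rows.append(
            {
                "implication": "price rise lowered entry of new salaried doctors",
                "operation": "random_intercept_fit[new_doctors].year_dummies(2005+) vs 2004",
                "value": val,
                "passed": bool(post) and val < 0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Recovery report
# ---------------------------------------------------------------------------

def recovery_report(
    truth: dict[str, float],
    estimates: list[dict[str, tuple[float, float]]],
    implications: pd.DataFrame | None = None,
) -> RecoveryReport:
    """Truth vs estimates across replications.

    ``estimates`` holds one dict per replication mapping parameter name to
    (estimate, standard error); every replication must report every truth
    parameter. With two or more replications the report includes the fraction
    of nominal-95% intervals covering the truth; with a single replication the
    intervals are reported and coverage is omitted (NaN).
    """
    if not estimates:
        raise ValueError("no estimates supplied")
    for i, rep in enumerate(estimates):
        missing = set(truth) - set(rep)
        if missing:
            raise ValueError(f"replication {i} missing parameters {sorted(missing)}")
    rows = []
    for name, true_val in truth.items():
        est = np.array([rep[name][0] for rep in estimates])
        se = np.array([rep[name][1] for rep in estimates])
        covered = np.abs(est - true_val) <= 1.96 * se
        rows.append(
            {
                "parameter": name,
                "truth": true_val,
                "mean_estimate": float(est.mean()),
                "mean_se": float(se.mean()),
                "coverage": float(covered.mean()) if len(estimates) > 1 else np.nan,
                "n_reps": len(estimates),
            }
        )
    params = pd.DataFrame(rows)
    if implications is None:
        implications = pd.DataFrame(columns=["implication", "operation", "value", "passed"])
    return RecoveryReport(parameters=params, implications=implications)


# ---------------------------------------------------------------------------
# Artifact writing
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: str | Path, seed: int, note: str, chash: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# gpmobility {note}; seed={seed}; config_hash={chash}\n")
        df.to_csv(fh, index=False)


def _fit_to_json(fit: FitResult) -> dict:
    return {
        "params": fit.params.to_dict(),
        "bse": fit.bse.to_dict(),
        "pvalues": fit.pvalues.to_dict(),
        "n_obs": fit.n_obs,
        "loglike": fit.loglike,
        "sigma_u2": fit.sigma_u2,
        "sigma_e2": fit.sigma_e2,
        "n_groups": fit.n_groups,
        "extra": {k: v for k, v in fit.extra.items() if np.isscalar(v) or v is None
                  or isinstance(v, (list, str, bool))},
    }


def _write_bundle(bundle: dict, config: ExperimentConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = bundle["config_hash"]
    seed = bundle["seed"]
    _write_csv(bundle["panel"], outdir / "panel.csv", seed, "synthetic panel", chash)
    _write_csv(bundle["implications"], outdir / "implications.csv", seed, "implication checks", chash)
    results = {
        "seed": seed,
        "config_hash": chash,
        "fits": {name: _fit_to_json(fit) for name, fit in bundle["fits"].items()},
        "first_differences": {name: _fit_to_json(fit) for name, fit in bundle["first_differences"].items()},
        "errors": bundle["errors"],
        "implications": bundle["implications"].to_dict(orient="records"),
    }
    (outdir / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True, default=float))
    for name, fit in {**bundle["fits"], **bundle["first_differences"]}.items():
        _write_csv(fit.to_frame().reset_index(names="term"), outdir / f"table_{name}.csv",
                   seed, f"coefficients: {name}", chash)
    logger.info("artifacts written to %s", outdir)
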