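"""Seeded generator of a doctor-by-practice census panel (2003-2007).

Emulates the statistical structure of the English GP workforce censuses used
to study pay-for-performance: doctors nested in practices, yearly entry/exit
and between-practice moves, partner vs salaried status, full-time-equivalence
(FTE) workload, practice QOF achievement, deprivation (LISI), geodesic
distances between practices, and the 2005->2006 price shock on CVD indicators.

Outcomes are produced by the structural contract-choice model plus stated
noise, selection and heterogeneity:

* exit from the market follows a latent index rising as retirement approaches
  (the exclusion variable of the selection model);
* between-practice mobility, conditional on staying, is triggered when a rival
  practice's poaching condition from the theory holds (parameters in the
  competition-feasibility region, a favourable amenity differential, and a
  relocation-cost draw below the feasibility bound), with an error correlated
  ``rho`` with the exit error so that naive mobility regressions suffer
  selection bias;
* partnership promotion follows the stage-1 contract choice plus a logistic
  taste shock -- with no quality payment (p = 0) partnership events are zero
  and inefficient doctors are never promoted;
* FTE is a bounded affine transform of structural effort plus a doctor random
  intercept and noise; practice QOF achievement a bounded transform of
  investment plus mean doctor effort plus a practice random intercept;
* vacancies left by exits are filled with a probability decreasing in the
  quality price (partnership lock-in crowds out new salaried entrants).

The module also provides small benchmark generators with known truth for the
estimator-recovery studies (random-intercept, selection/IMR, first-difference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import atan, atan2, cos, sin, sqrt, tan, radians

import numpy as np
import pandas as pd

from . import market_model as mm
from . import qof_payment as qp

__all__ = [
    "PracticeProfile",
    "DoctorProfile",
    "DGPConfig",
    "Population",
    "vincenty_distance",
    "distance_to_best_practice",
    "income_recode",
    "generate_population",
    "simulate_panel",
    "simulate_selection_benchmark",
    "simulate_random_intercept_benchmark",
    "simulate_fd_benchmark",
    "INCOME_BAND_EDGES",
]

MILES_PER_METRE = 1.0 / 1609.344

# WGS-84 reference ellipsoid
_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_WGS84_B = _WGS84_A * (1.0 - _WGS84_F)


# ---------------------------------------------------------------------------
# Geodesy
# ---------------------------------------------------------------------------

def vincenty_distance(
    lat1: float,
    lon1: float,
    lat2: float,
    lon2: float,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> float:
    """Vincenty inverse geodesic distance on the WGS-84 ellipsoid, in miles.

    Iterative solution of the inverse problem for an oblate spheroid;
    symmetric in its arguments and zero iff the points coincide. On the rare
    non-convergent (near-antipodal) pairs a great-circle fallback is returned
    with a warning.
    """
    if lat1 == lat2 and lon1 == lon2:
        return 0.0
    phi1, phi2 = radians(lat1), radians(lat2)
    L = radians(lon2 - lon1)
    U1, U2 = atan((1.0 - _WGS84_F) * tan(phi1)), atan((1.0 - _WGS84_F) * tan(phi2))
    sinU1, cosU1 = sin(U1), cos(U1)
    sinU2, cosU2 = sin(U2), cos(U2)

    lam = L
    for _ in range(max_iter):
        sin_lam, cos_lam = sin(lam), cos(lam)
        sin_sigma = sqrt(
            (cosU2 * sin_lam) ** 2 + (cosU1 * sinU2 - sinU1 * cosU2 * cos_lam) ** 2
        )
        if sin_sigma == 0.0:
            return 0.0  # coincident after reduction
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha * sin_alpha
        if cos2_alpha == 0.0:
            cos_2sigma_m = 0.0  # equatorial line
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha
        C = _WGS84_F / 16.0 * cos2_alpha * (4.0 + _WGS84_F * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = L + (1.0 - C) * _WGS84_F * sin_alpha * (
            sigma
            + C * sin_sigma * (cos_2sigma_m + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < tol:
            break
    else:
        warnings.warn(
            "Vincenty iteration did not converge (near-antipodal points); "
            "returning great-circle fallback",
            RuntimeWarning,
            stacklevel=2,
        )
        return _haversine_miles(lat1, lon1, lat2, lon2)

    u2 = cos2_alpha * (_WGS84_A**2 - _WGS84_B**2) / _WGS84_B**2
    A = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    delta_sigma = B * sin_sigma * (
        cos_2sigma_m
        + B
        / 4.0
        * (
            cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2)
            - B
            / 6.0
            * cos_2sigma_m
            * (-3.0 + 4.0 * sin_sigma**2)
            * (-3.0 + 4.0 * cos_2sigma_m**2)
        )
    )
    s = _WGS84_B * A * (sigma - delta_sigma)
    return s * MILES_PER_METRE


def _haversine_miles(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    r = 6371008.8  # mean Earth radius, metres
    p1, p2 = radians(lat1), radians(lat2)
    dp, dl = radians(lat2 - lat1), radians(lon2 - lon1)
    h = sin(dp / 2.0) ** 2 + cos(p1) * cos(p2) * sin(dl / 2.0) ** 2
    return 2.0 * r * atan2(sqrt(h), sqrt(1.0 - h)) * MILES_PER_METRE


def distance_to_best_practice(
    practice_id: str,
    practices: pd.DataFrame,
    qof_scores: dict[str, float],
    n_neighbors: int = 10,
    furthest_variant: bool = False,
) -> float:
    """Distance (miles) from one practice to the best of its nearest neighbours.

    Among the ``n_neighbors`` nearest other practices (fewer if the market is
    smaller), returns the distance to the one with the highest QOF score, ties
    broken towards the nearer practice. With ``furthest_variant=True`` returns
    instead the distance to the furthest of those neighbours (an alternative
    reading of the census variable). ``practices`` needs columns
    ``practice_id``, ``latitude``, ``longitude``.

    Raises ValueError for a singleton market.
    """
    others = practices[practices["practice_id"] != practice_id]
    if len(others) == 0:
        raise ValueError("distance to best practice is undefined in a singleton market")
    me = practices.loc[practices["practice_id"] == practice_id].iloc[0]
    dists = np.array(
        [
            vincenty_distance(me.latitude, me.longitude, row.latitude, row.longitude)
            for row in others.itertuples()
        ]
    )
    order = np.argsort(dists, kind="stable")[: min(n_neighbors, len(others))]
    if furthest_variant:
        return float(dists[order[-1]])
    ids = others["practice_id"].to_numpy()[order]
    d = dists[order]
    scores = np.array([qof_scores[i] for i in ids])
    # highest score wins; among equal scores the nearer practice (stable sort
    # by distance already orders candidates by proximity)
    best = np.lexsort((d, -scores))[0]
    return float(d[best])


# ---------------------------------------------------------------------------
# Income recoding
# ---------------------------------------------------------------------------

#: Band edges in pounds: band k (1..7) is [edges[k-1], edges[k]); band 8 is the
#: open top band, treated as one band-width wide for midpoint recoding.
INCOME_BAND_EDGES = tuple(25_000.0 * k for k in range(8))  # 0 .. 175,000


def income_recode(band: int) -> float:
    """Continuous income (pounds) as the midpoint of a survey income band.

    The survey records income in eight bands of width 25,000 pounds starting
    at zero; the open-ended top band is assigned the midpoint it would have at
    the same width (187,500).
    """
    if not (isinstance(band, (int, np.integer)) and 1 <= band <= 8):
        raise ValueError(f"income band must be an integer in 1..8, got {band!r}")
    return 25_000.0 * (band - 1) + 12_500.0


def _income_band(income: np.ndarray) -> np.ndarray:
    """Inverse of the recoding: pounds -> band 1..8 (top band open)."""
    return np.clip(np.floor(income / 25_000.0).astype(int) + 1, 1, 8)


# ---------------------------------------------------------------------------
# Configuration and population
# ---------------------------------------------------------------------------

def _default_p_by_year() -> dict[int, float]:
    # Quality price path in model units: no scheme in 2003, introduction in
    # 2004 (normalised to 1 = 76 pounds/point), price rise to 125/76 in 2005.
    return {2003: 0.0, 2004: 1.0, 2005: 125.0 / 76.0, 2006: 125.0 / 76.0, 2007: 125.0 / 76.0}


@dataclass
class DGPConfig:
    """Study conditions of the synthetic census.

    Sizes and marginals follow the census the generator emulates (500
    practices with on average five doctors each, observed 2003-2007); noise
    scales, the selection correlation and the structural primitives are the
    generator's own assumptions, documented in the methods note.
    """

    n_practices: int = 500
    doctors_per_practice: float = 5.0
    years: tuple[int, ...] = (2003, 2004, 2005, 2006, 2007)
    p_by_year: dict[int, float] = field(default_factory=_default_p_by_year)
    pi_efficient: float = 0.15
    gamma_v: float = 0.5
    m: float = 0.05
    # latent heterogeneity and noise
    sigma_a: float = 4.0          # doctor intercept in FTE points
    sigma_d: float = 2.0          # practice intercept in QOF percentage points
    sigma_eps: float = 8.0        # FTE residual
    sigma_q: float = 1.5          # practice QOF residual
    rho: float = 0.3              # corr(exit error, mobility error)
    # behavioural links
    retirement_age: int = 65
    baseline_partner_share: float = 0.82
    fte_base: float = 91.0        # FTE of a full-time salaried inefficient doctor at p=0
    fte_slope: float = 5.0        # FTE points per unit of structural effort
    qof_base: float = 80.0
    qof_slope: float = 4.5
    amenity_base: float = 1.0
    amenity_lisi: float = 0.03    # deprivation lowers amenities
    t_per_mile: float = 0.05      # relocation cost per mile of distance
    exit_base: float = 0.0
    exit_slope: float = 0.08      # exit hazard rises as retirement approaches
    mobility_base: float = -1.9
    mobility_feasible_gain: float = 1.4
    promote_scale: float = 0.5
    entry_base: float = 1.5
    entry_p_slope: float = 1.0
    seed: int = 20030901

    def __post_init__(self) -> None:
        if self.n_practices <= 0 or self.doctors_per_practice <= 0:
            raise ValueError("counts must be positive")
        for name in ("sigma_a", "sigma_d", "sigma_eps", "sigma_q"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (-1.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (-1, 1)")
        missing = [y for y in self.years if y not in self.p_by_year]
        if missing:
            raise ValueError(f"p_by_year missing years {missing}")


@dataclass(frozen=True)
class PracticeProfile:
    practice_id: str
    latitude: float
    longitude: float
    lisi: float
    total_population: float
    opening_year: int
    prop_f65_74: float
    prop_f75: float
    prop_m65_74: float
    prop_m75: float
    n_partner_slots: int
    amenity: float
    contract: str  # GMS or PMS


@dataclass(frozen=True)
class DoctorProfile:
    doctor_id: str
    birth_year: int
    gender: str
    doctor_type: str  # "v" or "nv"
    gamma: float
    doctor_effect: float
    practice_id: str
    is_partner: bool


@dataclass
class Population:
    """Baseline state: practice and doctor tables plus precomputed geography."""

    practices: pd.DataFrame
    doctors: pd.DataFrame
    neighbor_idx: np.ndarray      # (n_practices, k) nearest-neighbour indices
    neighbor_dist: np.ndarray     # matching Vincenty distances in miles
    config: DGPConfig


def generate_population(config: DGPConfig) -> Population:
    """Draw the baseline practices and doctors (census year 2003), seeded.

    Practice locations are uniform on a bounded region (~3x3 degrees);
    deprivation, list size and age-sex mix come from bounded distributions
    with census-like means. Doctors are efficient with probability
    ``pi_efficient`` and carry normal latent intercepts.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_practices
    first_year = config.years[0]

    lat = rng.uniform(51.0, 54.0, n)
    lon = rng.uniform(-3.0, 0.0, n)
    # Gamma deprivation index: right-skewed like the real LISI
    shape = (11.23 / 7.41) ** 2
    lisi = np.clip(rng.gamma(shape, 11.23 / shape, n), 0.0, 90.0)
    total_pop = np.clip(rng.normal(8.77, 4.51, n), 0.5, 37.6)
    practice_years0 = np.clip(rng.normal(28.9, 6.3, n), 0.0, 33.0)
    props = {
        "prop_f65_74": np.clip(rng.normal(4.23, 1.26, n), 0.0, 33.3),
        "prop_f75": np.clip(rng.normal(4.62, 1.73, n), 0.0, 16.1),
        "prop_m65_74": np.clip(rng.normal(3.91, 1.17, n), 0.0, 33.3),
        "prop_m75": np.clip(rng.normal(2.89, 1.19, n), 0.0, 33.3),
    }
    practices = pd.DataFrame(
        {
            "practice_id": [f"P{k:04d}" for k in range(n)],
            "latitude": lat,
            "longitude": lon,
            "lisi": lisi,
            "total_population": total_pop,
            "opening_year": (first_year - practice_years0).round().astype(int),
            **props,
            "amenity": config.amenity_base - config.amenity_lisi * lisi,
            "contract": np.where(rng.random(n) < 0.7, "GMS", "PMS"),
            "practice_effect": rng.normal(0.0, config.sigma_d, n),
        }
    )

    # nearest neighbours: great-circle preselection, Vincenty on the shortlist
    k = min(10, n - 1)
    lat_r, lon_r = np.radians(lat), np.radians(lon)
    dphi = lat_r[:, None] - lat_r[None, :]
    dlam = lon_r[:, None] - lon_r[None, :]
    h = np.sin(dphi / 2.0) ** 2 + np.cos(lat_r)[:, None] * np.cos(lat_r)[None, :] * np.sin(dlam / 2.0) ** 2
    gc = 2.0 * 6371008.8 * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))) * MILES_PER_METRE
    np.fill_diagonal(gc, np.inf)
    neighbor_idx = np.argsort(gc, axis=1, kind="stable")[:, :k]
    neighbor_dist = np.empty_like(neighbor_idx, dtype=float)
    for i in range(n):
        for jpos, j in enumerate(neighbor_idx[i]):
            neighbor_dist[i, jpos] = vincenty_distance(lat[i], lon[i], lat[j], lon[j])

    n_docs = rng.poisson(max(config.doctors_per_practice - 1.0, 0.0), n) + 1
    practice_idx = np.repeat(np.arange(n), n_docs)
    total = practice_idx.size
    age0 = np.clip(rng.normal(45.18, 9.74, total), 25.0, 70.0).round().astype(int)
    doctors = pd.DataFrame(
        {
            "doctor_id": np.arange(total),
            "practice_idx": practice_idx,
            "birth_year": first_year - age0,
            "female": (rng.random(total) < 0.42).astype(int),
            "is_efficient": (rng.random(total) < config.pi_efficient).astype(int),
            "doctor_effect": rng.normal(0.0, config.sigma_a, total),
            "is_partner": (rng.random(total) < config.baseline_partner_share).astype(int),
            # statutory retirement varies across doctors (cohort- and
            # scheme-specific pension rules), so years-to-retirement is not a
            # deterministic function of age
            "retirement_age": config.retirement_age + rng.integers(-3, 4, total),
            "entry_year": first_year,
        }
    )
    return Population(
        practices=practices,
        doctors=doctors,
        neighbor_idx=neighbor_idx,
        neighbor_dist=neighbor_dist,
        config=config,
    )


# ---------------------------------------------------------------------------
# Panel simulation
# ---------------------------------------------------------------------------

def _structural_efforts(config: DGPConfig, p: float) -> dict[tuple[int, int], float]:
    """Effort by (is_efficient, is_partner) at quality price p."""
    out = {}
    for eff in (0, 1):
        g = config.gamma_v if eff else 1.0
        out[(eff, 0)] = 1.0 / g
        out[(eff, 1)] = (2.0 + p) / (2.0 * g)
    return out


def _partnership_advantage(config: DGPConfig, p: float) -> float:
    """Pi_v^M - max(0, Pi^N) for the efficient type at price p (0 if p invalid)."""
    params = mm.ModelParams(
        m=config.m, p=p, pi=config.pi_efficient, gamma_v=config.gamma_v, t=0.01
    )
    profit_m = (params.gamma_v * (2.0 * config.m + p * p) + p * (p + 2.0)) / (4.0 * params.gamma_v)
    profit_n = config.m + p * p / 2.0 + p * (
        config.gamma_v + config.pi_efficient - config.gamma_v * config.pi_efficient
    ) / config.gamma_v
    return profit_m - max(0.0, profit_n)


def simulate_panel(config: DGPConfig, population: Population | None = None) -> pd.DataFrame:
    """Simulate the doctor-year panel under the structural data-generating process.

    Returns a tidy frame, one row per doctor-year, with outcome columns
    (``is_partner``, ``moved``, ``is_new``, ``exited``, ``fte``,
    ``prop_qof_points``) and covariate columns dated t-1 for incumbents and
    contemporaneous for entrants (``age``, ``female``, ``fte_lag``,
    ``income``, ``income_band``, ``distance_to_best``, ``total_population``,
    ``lisi``, ``practice_years``, ``practice_size``, the four age-sex
    proportions, ``years_to_retirement``, ``price_shock`` on 2006 rows,
    ``is_efficient``) plus an ``imr`` placeholder filled by the selection
    estimator. ``DataFrame.attrs`` carries diagnostics (partnership event
    count, empirical exit/mobility error correlation, seed).
    """
    if population is None:
        population = generate_population(config)
    rng = np.random.default_rng(config.seed + 1)
    practices = population.practices
    emit_years = set(config.years)
    pr_amenity = practices["amenity"].to_numpy()
    pr_effect = practices["practice_effect"].to_numpy()
    n_pr = len(practices)
    # one internal burn-in year before the observation window so that the first
    # emitted year has well-defined lags, mobility and entry; its quality price
    # defaults to the first observed year's (0 for a pre-scheme start)
    burn_year = config.years[0] - 1
    years = [burn_year, *config.years]
    p_schedule = dict(config.p_by_year)
    p_schedule.setdefault(burn_year, p_schedule[config.years[0]])

    # mutable doctor state
    docs = population.doctors.copy()
    state = {
        "doctor_id": docs["doctor_id"].to_numpy().copy(),
        "practice_idx": docs["practice_idx"].to_numpy().copy(),
        "birth_year": docs["birth_year"].to_numpy().copy(),
        "female": docs["female"].to_numpy().copy(),
        "is_efficient": docs["is_efficient"].to_numpy().copy(),
        "doctor_effect": docs["doctor_effect"].to_numpy().copy(),
        "is_partner": docs["is_partner"].to_numpy().copy(),
        "retirement_age": docs["retirement_age"].to_numpy().copy(),
        "entry_year": np.full(len(docs), burn_year),  # incumbents predate the window
    }
    next_doctor_id = int(state["doctor_id"].max()) + 1

    rows: list[pd.DataFrame] = []
    prev_year_frame: pd.DataFrame | None = None
    qof_by_practice_prev: np.ndarray | None = None
    dist_best_prev: np.ndarray | None = None
    pending_vacancies = np.zeros(n_pr, dtype=int)
    n_partnership_events = 0
    err_u_all: list[np.ndarray] = []
    err_v_all: list[np.ndarray] = []

    params_s_cache: dict[float, mm.RegionReport] = {}

    def region_ok(p: float) -> tuple[bool, float]:
        """in-S membership for the efficient type and the poaching bound on t."""
        if p <= 0.0:
            return False, 0.0
        if p not in params_s_cache:
            params_s_cache[p] = mm.region_membership(
                mm.ModelParams(m=config.m, p=p, pi=config.pi_efficient, gamma_v=config.gamma_v, t=0.01),
                config.gamma_v,
            )
        rep = params_s_cache[p]
        delta_pm = p * (p + 2.0) * (1.0 - config.gamma_v) / (4.0 * config.gamma_v)
        return rep.in_s, delta_pm

    shock_pct_by_practice = _price_shocks_by_practice(config, rng_seed=config.seed + 7)

    for year in years:
        p_t = p_schedule[year]
        nd = state["doctor_id"].size
        age = year - state["birth_year"]
        is_new = (state["entry_year"] == year).astype(int)
        old = is_new == 0
        # covariate timing: lagged (t-1) for incumbents, contemporaneous for entrants
        age_cov = np.where(old, age - 1, age)
        ytr = state["retirement_age"] - age_cov

        # --- exit ---
        u = rng.standard_normal(nd)
        exit_latent = config.exit_base - config.exit_slope * np.clip(ytr, 0.0, None) + u
        exited = (exit_latent > 0.0).astype(int)

        # --- mobility (stayers, incumbents only) ---
        v_err = config.rho * u + sqrt(1.0 - config.rho**2) * rng.standard_normal(nd)
        in_s, t_bound = region_ok(p_t)
        rival_pos = rng.integers(0, population.neighbor_idx.shape[1], nd)
        cur = state["practice_idx"]
        rival_idx = population.neighbor_idx[cur, rival_pos]
        rival_dist = population.neighbor_dist[cur, rival_pos]
        t_draw = config.t_per_mile * rival_dist
        delta_b = pr_amenity[rival_idx] - pr_amenity[cur]
        feasible = (
            in_s
            & (state["is_efficient"] == 1)
            & (t_draw < t_bound)
            & (t_draw > 0.0)
            & (delta_b > 0.0)
        )
        mob_latent = config.mobility_base + config.mobility_feasible_gain * feasible + v_err
        can_move = (exited == 0) & old & (year != years[0])
        moved = ((mob_latent > 0.0) & can_move).astype(int)
        if year in emit_years:
            err_u_all.append(u[can_move])
            err_v_all.append(v_err[can_move])

        # poached efficient movers relocate into a contested partnership
        poached = (moved == 1) & feasible
        state["practice_idx"] = np.where(moved == 1, rival_idx, cur)
        became_partner_by_move = poached & (state["is_partner"] == 0)
        state["is_partner"] = np.where(poached, 1, state["is_partner"])

        # --- partnership promotion (stage-1 choice + logistic taste shock) ---
        adv = _partnership_advantage(config, p_t)
        salaried = (state["is_partner"] == 0) & (exited == 0) & (moved == 0)
        if adv > 0.0 and in_s:
            promote_prob = 1.0 / (1.0 + np.exp(-adv / config.promote_scale))
            promoted = salaried & (state["is_efficient"] == 1) & (rng.random(nd) < promote_prob)
        else:
            promoted = np.zeros(nd, dtype=bool)
        state["is_partner"] = np.where(promoted, 1, state["is_partner"])
        if year in emit_years:
            n_partnership_events += int(promoted.sum() + became_partner_by_move.sum())

        # --- FTE from structural effort ---
        efforts = _structural_efforts(config, p_t)
        e = np.empty(nd)
        for (eff, part), val in efforts.items():
            mask = (state["is_efficient"] == eff) & (state["is_partner"] == part)
            e[mask] = val
        fte = np.clip(
            config.fte_base
            + config.fte_slope * (e - 1.0)
            + state["doctor_effect"]
            + rng.normal(0.0, config.sigma_eps, nd),
            11.0,
            100.0,
        )

        # --- practice quality ---
        counts = np.bincount(state["practice_idx"], minlength=n_pr)
        sum_e = np.bincount(state["practice_idx"], weights=e, minlength=n_pr)
        mean_e = np.divide(sum_e, counts, out=np.zeros(n_pr), where=counts > 0)
        qof_by_practice = np.clip(
            config.qof_base
            + config.qof_slope * (p_t + mean_e)
            + pr_effect
            + rng.normal(0.0, config.sigma_q, n_pr),
            0.0,
            100.0,
        )
        dist_best = _distance_to_best_vec(
            population.neighbor_idx, population.neighbor_dist, qof_by_practice
        )

        # --- income (band + midpoint recode) ---
        latent_income = (
            35_000.0
            + 500.0 * fte
            + 25_000.0 * state["is_partner"]
            + rng.normal(0.0, 8_000.0, nd)
        )
        band = _income_band(np.clip(latent_income, 0.0, None))
        income = np.array([income_recode(int(b)) for b in band])

        # --- assemble rows; practice covariates from the t-1 practice for
        # incumbents (the origin practice for movers), contemporaneous for entrants
        if prev_year_frame is not None:
            prev_pidx = prev_year_frame.set_index("doctor_id")["practice_idx_now"]
            cov_pidx = np.where(
                old,
                prev_pidx.reindex(state["doctor_id"]).to_numpy(),
                state["practice_idx"],
            ).astype(int)
        else:
            cov_pidx = state["practice_idx"]
        cov_counts_src = counts if prev_year_frame is None else prev_counts
        cov_qof_src = qof_by_practice if qof_by_practice_prev is None else qof_by_practice_prev
        cov_dist_src = dist_best if dist_best_prev is None else dist_best_prev
        lag_year = year if prev_year_frame is None else year - 1

        frame = pd.DataFrame(
            {
                "doctor_id": state["doctor_id"],
                "practice_id": practices["practice_id"].to_numpy()[state["practice_idx"]],
                "year": year,
                # outcomes
                "is_partner": state["is_partner"],
                "moved": moved,
                "is_new": is_new,
                "exited": exited,
                "fte": fte,
                "prop_qof_points": qof_by_practice[state["practice_idx"]],
                # covariates (t-1 for incumbents, contemporaneous for entrants)
                "age": age_cov,
                "female": state["female"],
                "fte_lag": np.nan,  # filled from the previous frame below
                "income_band": band,
                "income": income,
                "distance_to_best": np.where(
                    old & (prev_year_frame is not None),
                    cov_dist_src[cov_pidx],
                    dist_best[cov_pidx],
                ),
                "total_population": practices["total_population"].to_numpy()[cov_pidx],
                "lisi": practices["lisi"].to_numpy()[cov_pidx],
                "practice_years": lag_year - practices["opening_year"].to_numpy()[cov_pidx],
                "practice_size": cov_counts_src[cov_pidx],
                "prop_f65_74": practices["prop_f65_74"].to_numpy()[cov_pidx],
                "prop_f75": practices["prop_f75"].to_numpy()[cov_pidx],
                "prop_m65_74": practices["prop_m65_74"].to_numpy()[cov_pidx],
                "prop_m75": practices["prop_m75"].to_numpy()[cov_pidx],
                "years_to_retirement": ytr,
                "is_efficient": state["is_efficient"],
                "price_shock": shock_pct_by_practice[cov_pidx] if year == 2006 else np.nan,
                "imr": np.nan,
                "practice_idx_now": state["practice_idx"],
            }
        )
        if prev_year_frame is not None:
            prev_fte = prev_year_frame.set_index("doctor_id")["fte"]
            frame["fte_lag"] = np.where(
                old, prev_fte.reindex(state["doctor_id"]).to_numpy(), fte
            )
        else:
            frame["fte_lag"] = fte
        if year in emit_years:
            rows.append(frame)

        # --- entries for next year: exits leave vacancies, filled with
        # probability decreasing in the quality price
        vac = np.bincount(state["practice_idx"][exited == 1], minlength=n_pr)
        pending_vacancies = vac
        prev_year_frame = frame
        prev_counts = counts
        qof_by_practice_prev = qof_by_practice
        dist_best_prev = dist_best

        if year != years[-1]:
            next_year = years[years.index(year) + 1]
            p_next = config.p_by_year[next_year]
            fill_prob = 1.0 / (1.0 + np.exp(-(config.entry_base - config.entry_p_slope * p_next)))
            filled = rng.random(int(pending_vacancies.sum())) < fill_prob
            vac_practice = np.repeat(np.arange(n_pr), pending_vacancies)[filled]
            n_new = vac_practice.size
            # drop exiters, append entrants
            keep = exited == 0
            for key in state:
                state[key] = state[key][keep]
            new_age = np.clip(rng.normal(32.0, 4.0, n_new), 25.0, 45.0).round().astype(int)
            additions = {
                "doctor_id": np.arange(next_doctor_id, next_doctor_id + n_new),
                "practice_idx": vac_practice,
                "birth_year": next_year - new_age,
                "female": (rng.random(n_new) < 0.42).astype(int),
                "is_efficient": (rng.random(n_new) < config.pi_efficient).astype(int),
                "doctor_effect": rng.normal(0.0, config.sigma_a, n_new),
                "is_partner": np.zeros(n_new, dtype=int),
                "retirement_age": config.retirement_age + rng.integers(-3, 4, n_new),
                "entry_year": np.full(n_new, next_year),
            }
            next_doctor_id += n_new
            for key in state:
                state[key] = np.concatenate([state[key], additions[key]])

    panel = pd.concat(rows, ignore_index=True).drop(columns=["practice_idx_now"])
    panel = panel.sort_values(["doctor_id", "year"], kind="stable").reset_index(drop=True)
    u_cat, v_cat = np.concatenate(err_u_all), np.concatenate(err_v_all)
    panel.attrs["partnership_events"] = n_partnership_events
    panel.attrs["error_corr"] = (
        float(np.corrcoef(u_cat, v_cat)[0, 1]) if u_cat.size > 2 else np.nan
    )
    panel.attrs["seed"] = config.seed
    return panel


def _distance_to_best_vec(
    neighbor_idx: np.ndarray, neighbor_dist: np.ndarray, scores: np.ndarray
) -> np.ndarray:
    """Distance to the highest-scoring of each practice's nearest neighbours.

    Ties broken towards the nearer neighbour (columns are distance-ordered).
    """
    s = scores[neighbor_idx]
    best_col = np.argmax(s, axis=1)  # first max = nearest among ties
    return neighbor_dist[np.arange(neighbor_idx.shape[0]), best_col]


def _price_shocks_by_practice(config: DGPConfig, rng_seed: int) -> np.ndarray:
    """Percent-of-revenue price shocks from the 2005->2006 threshold change.

    Synthesises 2005 achievement records per practice (tied to a common
    quality level plus indicator noise) and runs them through the payment
    engine under both years' schemes.
    """
    rng = np.random.default_rng(rng_seed)
    reg05, reg06 = qp.default_registry(2005), qp.default_registry(2006)
    n = config.n_practices
    shocks = np.empty(n)
    quality = np.clip(rng.normal(95.0, 4.0, n), 60.0, 100.0)
    n_ind = len(reg05)
    ach = np.clip(
        0.45 + 0.0040 * quality[:, None] + rng.normal(0.0, 0.08, (n, n_ind)),
        0.05,
        1.0,
    )
    # vectorised revenue under both schemes
    pts05 = np.empty((n, n_ind))
    pts06 = np.empty((n, n_ind))
    cvd_cols = []
    for j, ind in enumerate(reg05.indicators):
        pts05[:, j] = qp.points_earned(ach[:, j], ind)
        pts06[:, j] = qp.points_earned(ach[:, j], reg06[ind.id])
        if ind.id in qp.CVD_SUBSET:
            cvd_cols.append(j)
    rev05_total = pts05.sum(axis=1) * reg05.price_per_point
    sub05 = pts05[:, cvd_cols].sum(axis=1) * reg05.price_per_point
    sub06 = pts06[:, cvd_cols].sum(axis=1) * reg06.price_per_point
    with np.errstate(invalid="ignore"):
        shocks = np.where(rev05_total > 0, 100.0 * (sub06 - sub05) / rev05_total, 0.0)
    return shocks


# ---------------------------------------------------------------------------
# Benchmark generators with known truth (estimator-recovery studies)
# ---------------------------------------------------------------------------

def simulate_random_intercept_benchmark(
    n_groups: int = 500,
    group_size: int = 8,
    beta: tuple[float, float] = (1.0, 1.5),
    sigma_u: float = 2.0,
    sigma_e: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-level linear DGP: y = b0 + b1 x + u_group + e."""
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), group_size)
    x = rng.standard_normal(g.size)
    u = rng.normal(0.0, sigma_u, n_groups)
    y = beta[0] + beta[1] * x + u[g] + rng.normal(0.0, sigma_e, g.size)
    return pd.DataFrame({"y": y, "x": x, "group": g})


def simulate_selection_benchmark(
    n_per_year: int = 600,
    n_years: int = 3,
    rho: float = 0.5,
    beta: tuple[float, float] = (0.5, 1.0),
    gamma: tuple[float, float, float] = (0.5, 1.0, 0.8),
    seed: int = 0,
) -> pd.DataFrame:
    """Selection DGP for the stacked-IMR two-step estimator.

    Stay equation (probit): stay* = g0 + g1 x + g2 z + u, stay = 1(stay* > 0),
    with ``z`` the exclusion variable (years to retirement, scaled). Outcome,
    observed for stayers only: y = b0 + b1 x + e with corr(u, e) = rho. The
    noise correlation makes the naive regression of y on x biased; the truth
    ``beta`` is known for bias studies.
    """
    rng = np.random.default_rng(seed)
    n = n_per_year * n_years
    year = np.repeat(np.arange(2003, 2003 + n_years), n_per_year)
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    u = rng.standard_normal(n)
    e = rho * u + sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    stay_star = gamma[0] + gamma[1] * x + gamma[2] * z + u
    stay = (stay_star > 0.0).astype(int)
    y = beta[0] + beta[1] * x + e
    y = np.where(stay == 1, y, np.nan)
    return pd.DataFrame(
        {
            "doctor_id": np.arange(n),
            "practice_id": rng.integers(0, 40, n),
            "year": year,
            "stay": stay,
            "y": y,
            "x": x,
            "years_to_retirement": z,
        }
    )


def simulate_fd_benchmark(
    n: int = 1000,
    beta: float = 1.0,
    alpha_x_corr: float = 0.8,
    sigma_e: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-period panel with doctor fixed effects correlated with the regressor.

    y_it = beta x_it + alpha_i + e_it, where alpha_i correlates with the
    doctor's average x: pooled OLS is biased, first differences are not.
    """
    rng = np.random.default_rng(seed)
    x_base = rng.standard_normal(n)
    alpha = alpha_x_corr * x_base + sqrt(1.0 - alpha_x_corr**2) * rng.standard_normal(n)
    rows = []
    for tpos, year in enumerate((2005, 2006)):
        x = x_base + rng.standard_normal(n)
        y = beta * x + alpha + rng.normal(0.0, sigma_e, n)
        rows.append(
            pd.DataFrame(
                {
                    "doctor_id": np.arange(n),
                    "year": year,
                    "y": y,
                    "x": x,
                    "female": rng.integers(0, 2, n) if tpos == 0 else np.nan,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    # time-invariant covariate: copy period-1 values into period 2
    fem = df.loc[df.year == 2005, ["doctor_id", "female"]].set_index("doctor_id")["female"]
    df["female"] = fem.reindex(df["doctor_id"]).to_numpy()
    return df
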