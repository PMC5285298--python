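"""Two-practice contract-choice game under a pay-for-performance scheme.

Two practices, each run by a profit-oriented manager, serve a local market and
need exactly one doctor. Doctors come in two efficiency types: *v* (efficient,
effort-cost parameter ``gamma_v``) and *nv* (inefficient, cost normalised to 1).
A practice can hire a new salaried doctor of unknown type from the labour
market, or offer a partnership (equal profit share) to a local doctor whose
type is known. Practice revenue is a capitation payment ``m`` plus a
quality-related payment ``p`` per unit of quality; quality is the sum of the
doctor's effort and the practice's investment. With an asymmetric allocation of
types (efficient doctor local to practice 1, inefficient to practice 2) and a
relocation cost ``t``, the two practices may compete for the efficient doctor.

This module provides the closed-form stage-2 equilibria, the parameter regions
in which partnership offers are profitable, the wage competition over the
efficient doctor, the stage-1 contract choice, comparative statics by central
finite differences, and a numeric best-response oracle that verifies every
closed form independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Callable

import numpy as np

__all__ = [
    "Contract",
    "DoctorType",
    "ModelParams",
    "ContractOutcome",
    "RegionReport",
    "CompetitionOutcome",
    "Stage1Choice",
    "RegionError",
    "ConvergenceError",
    "BoundaryWarning",
    "equilibrium_outcomes",
    "region_membership",
    "competition_outcomes",
    "stage1_contract_choice",
    "comparative_static_sign",
    "numeric_oracle",
    "sample_s_hat_params",
]


class Contract(str, Enum):
    """Contract configurations a practice can end up with."""

    NEW_SALARIED = "new_salaried"
    LOCAL_PARTNERSHIP = "local_partnership"
    CONTESTED_PARTNERSHIP = "contested_partnership"


class DoctorType(str, Enum):
    """Doctor efficiency types; ``UNKNOWN`` is a new hire of unrealised type."""

    V = "v"
    NV = "nv"
    UNKNOWN = "unknown"


class RegionError(ValueError):
    """Raised when an operation requires parameters inside a region they are not in."""


class ConvergenceError(RuntimeError):
    """Raised when the numeric best-response oracle fails to reach a fixed point."""


class BoundaryWarning(UserWarning):
    """Emitted when a comparative static is requested on a region boundary."""


@dataclass(frozen=True)
class ModelParams:
    """Structural primitives of the two-practice game.

    Parameters
    ----------
    m : capitation payment (money, >= 0).
    p : price per unit of quality under the pay-for-performance scheme
        (money/quality, >= 0).
    pi : probability that a new doctor drawn from the labour market is of the
        efficient type, in [0, 1].
    gamma_v : effort-cost parameter of the efficient type, in (0, 1].
    gamma_nv : effort-cost parameter of the inefficient type; normalised to 1.
    t : relocation cost (money, >= 0).
    b1, b2 : amenity benefits of the two practice locations (money, >= 0).
    w_outside : outside-option utility of a new doctor; fixed at 0 in the
        baseline model.
    """

    m: float = 1.0
    p: float = 1.0
    pi: float = 0.5
    gamma_v: float = 0.5
    gamma_nv: float = 1.0
    t: float = 0.1
    b1: float = 0.0
    b2: float = 0.0
    w_outside: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma_v <= self.gamma_nv):
            raise ValueError(f"require 0 < gamma_v <= gamma_nv, got {self.gamma_v}, {self.gamma_nv}")
        if self.gamma_nv != 1.0:
            raise ValueError("gamma_nv is normalised to 1")
        if not (0.0 <= self.pi <= 1.0):
            raise ValueError(f"pi must lie in [0, 1], got {self.pi}")
        for name in ("m", "p", "t", "b1", "b2"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")

    def gamma(self, doctor_type: DoctorType | str) -> float:
        """Effort-cost parameter of a known doctor type."""
        doctor_type = DoctorType(doctor_type)
        if doctor_type == DoctorType.V:
            return self.gamma_v
        if doctor_type == DoctorType.NV:
            return self.gamma_nv
        raise ValueError("unknown doctor type has no single cost parameter")

    def amenity(self, location: int) -> float:
        if location not in (1, 2):
            raise ValueError("location must be 1 or 2")
        return self.b1 if location == 1 else self.b2


@dataclass(frozen=True)
class ContractOutcome:
    """Stage-2 equilibrium for one practice under one contract configuration.

    ``quality = investment + effort`` holds exactly. Wages equal the doctor's
    outside option (0) unless set by wage competition.
    """

    contract: Contract
    doctor_type: DoctorType
    effort: float
    investment: float
    quality: float
    wage: float
    doctor_utility: float
    practice_profit: float


@dataclass(frozen=True)
class RegionReport:
    """Membership of the partnership-profitability parameter regions.

    ``in_s1``/``in_s2`` are the two printed sub-regions (split at the
    ``pi_cutoff`` on the share of efficient new doctors), ``in_s`` their union,
    and ``in_s_hat`` additionally requires relocation costs small enough that
    poaching the efficient doctor is feasible.
    """

    in_s1: bool
    in_s2: bool
    in_s: bool
    in_s_hat: bool
    m_bar: float
    p_bar: float
    pi_cutoff: float


@dataclass(frozen=True)
class CompetitionOutcome:
    """Wage competition over the efficient doctor (asymmetric allocation).

    ``w_bar_2`` is the highest salary the rival (practice 2) can offer while
    still preferring to poach over hiring a new doctor; ``w_bar_1`` is the
    retention wage practice 1 must concede; ``profit_contested`` the resulting
    profit of practice 1, whose advantage over a new salaried hire is exactly
    ``b1 - b2 + t``.
    """

    w_bar_2: float
    w_bar_1: float
    profit_contested: float
    profit_advantage: float


@dataclass(frozen=True)
class Stage1Choice:
    """Stage-1 contract choice of both practices."""

    practice1: ContractOutcome
    practice2: ContractOutcome


# ---------------------------------------------------------------------------
# Closed-form building blocks
# ---------------------------------------------------------------------------

def _salaried_effort(gamma: float) -> float:
    # FOC of U^N in e: e = 1/gamma
    return 1.0 / gamma


def _partner_effort(p: float, gamma: float) -> float:
    # FOC of U^P in e: e = (2+p)/(2 gamma)
    return (2.0 + p) / (2.0 * gamma)


def _profit_new(params: ModelParams) -> float:
    """Expected profit of hiring a new salaried doctor (wage 0)."""
    m, p, pi, g = params.m, params.p, params.pi, params.gamma_v
    return m + p * p / 2.0 + p * (g + pi - g * pi) / g


def _profit_manager(params: ModelParams, gamma: float, wage: float = 0.0) -> float:
    """Manager's profit with a partner of cost ``gamma`` at salary ``wage``."""
    m, p = params.m, params.p
    base = (gamma * (2.0 * m + p * p) + p * (p + 2.0)) / (4.0 * gamma)
    return base - wage / 2.0


def _partner_utility(params: ModelParams, gamma: float, wage: float, b: float) -> float:
    m, p = params.m, params.p
    return b + (p + 2.0) ** 2 / (8.0 * gamma) + (2.0 * m + p * p + 2.0 * wage + 4.0 * p) / 4.0


def _salaried_utility(params: ModelParams, gamma: float, wage: float, b: float) -> float:
    p = params.p
    e = _salaried_effort(gamma)
    q = p
    return wage + (q + e) - gamma * e * e / 2.0 + b


def equilibrium_outcomes(
    params: ModelParams,
    contract: Contract | str,
    doctor_type: DoctorType | str,
    location: int = 1,
    wage: float | None = None,
) -> ContractOutcome:
    """Closed-form stage-2 equilibrium for one contract configuration.

    For a salaried hire the doctor exerts ``e = 1/gamma`` (the quality payment
    does not reach her) and the practice invests ``q = p``; the reported profit
    is the practice's ex-ante expectation over the new doctor's type. For a
    partnership the profit share raises effort to ``e = (2+p)/(2 gamma)`` while
    investment is unchanged. Wages default to the outside option 0.

    ``doctor_type`` may be ``"unknown"`` only for a salaried hire, in which
    case effort, quality and utility are reported in expectation over types.
    """
    contract = Contract(contract)
    doctor_type = DoctorType(doctor_type)
    if wage is None:
        wage = params.w_outside
    b = params.amenity(location)
    p = params.p

    if contract == Contract.NEW_SALARIED:
        profit = _profit_new(params) - wage  # wage 0 in the baseline
        if doctor_type == DoctorType.UNKNOWN:
            pi, gv = params.pi, params.gamma_v
            effort = pi * _salaried_effort(gv) + (1.0 - pi) * _salaried_effort(1.0)
            utility = pi * _salaried_utility(params, gv, wage, b) + (1.0 - pi) * _salaried_utility(params, 1.0, wage, b)
        else:
            g = params.gamma(doctor_type)
            effort = _salaried_effort(g)
            utility = _salaried_utility(params, g, wage, b)
        investment = p
        return ContractOutcome(
            contract=contract,
            doctor_type=doctor_type,
            effort=effort,
            investment=investment,
            quality=investment + effort,
            wage=wage,
            doctor_utility=utility,
            practice_profit=profit,
        )

    if doctor_type == DoctorType.UNKNOWN:
        raise ValueError("a partnership requires a doctor of known type")
    g = params.gamma(doctor_type)
    effort = _partner_effort(p, g)
    investment = p
    return ContractOutcome(
        contract=contract,
        doctor_type=doctor_type,
        effort=effort,
        investment=investment,
        quality=investment + effort,
        wage=wage,
        doctor_utility=_partner_utility(params, g, wage, b),
        practice_profit=_profit_manager(params, g, wage),
    )


# ---------------------------------------------------------------------------
# Parameter regions
# ---------------------------------------------------------------------------

def region_membership(params: ModelParams, gamma_z: float) -> RegionReport:
    """Evaluate the partnership-profitability regions for a type with cost ``gamma_z``.

    The necessary condition for offering a partnership, Pi^M > max(0, Pi^N),
    holds on the union S = S1 ∪ S2, with S1 the high-``pi`` branch (requiring
    the quality price to exceed ``p_bar``) and S2 the low-``pi`` branch. Both
    require ``m < m_bar`` and ``gamma_z < 1``: no practice ever offers a
    partnership to the inefficient type. ``in_s_hat`` additionally requires
    ``0 < t < Pi_v^M - Pi_nv^M`` so that poaching the efficient doctor is
    feasible.
    """
    if not (0.0 < gamma_z <= 1.0):
        raise ValueError(f"gamma_z must lie in (0, 1], got {gamma_z}")
    m, p, pi, g = params.m, params.p, params.pi, gamma_z

    if g == 1.0:
        m_bar = p * (p - g * p + 2.0 * (1.0 + 2.0 * g * (pi - 1.0) - 2.0 * pi)) / (2.0 * g)
        pi_cutoff = float("-inf")
        p_bar = float("inf")
        in_s1 = in_s2 = False
    else:
        m_bar = p * (p - g * p + 2.0 * (1.0 + 2.0 * g * (pi - 1.0) - 2.0 * pi)) / (2.0 * g)
        p_bar = 2.0 * (2.0 * pi - 1.0 - 2.0 * g * (1.0 - pi)) / (1.0 - g)
        pi_cutoff = (1.0 - 2.0 * g) / (2.0 * (1.0 - g))
        in_s1 = (0.0 <= m < m_bar) and (p > p_bar) and (pi_cutoff < pi < 1.0)
        in_s2 = (0.0 <= m < m_bar) and (p > 0.0) and (0.0 < pi < pi_cutoff)

    in_s = in_s1 or in_s2
    delta_pm = _profit_manager(params, params.gamma_v) - _profit_manager(params, 1.0)
    in_s_hat = in_s and (0.0 < params.t < delta_pm)
    return RegionReport(
        in_s1=in_s1,
        in_s2=in_s2,
        in_s=in_s,
        in_s_hat=in_s_hat,
        m_bar=m_bar,
        p_bar=p_bar,
        pi_cutoff=pi_cutoff,
    )


# ---------------------------------------------------------------------------
# Competition over the efficient doctor
# ---------------------------------------------------------------------------

def competition_outcomes(params: ModelParams) -> CompetitionOutcome:
    """Wage competition when the efficient doctor is local to practice 1.

    Practice 2 bids up to the salary ``w_bar_2`` at which poaching (net of the
    relocation package ``t``) yields no more than a new salaried hire; the
    doctor's indifference condition then forces practice 1 to concede
    ``w_bar_1 = w_bar_2 - 2 (b1 - b2)``. The contested profit of practice 1
    exceeds the new-hire profit by exactly ``b1 - b2 + t``.

    Requires parameters in the feasibility region (raises RegionError
    otherwise, for the efficient type).
    """
    report = region_membership(params, params.gamma_v)
    if not report.in_s_hat:
        raise RegionError("parameters outside the competition-feasibility region")
    m, p, pi, g, t = params.m, params.p, params.pi, params.gamma_v, params.t
    w_bar_2 = (
        p * p - g * (2.0 * m + p * p + 4.0 * t) + 2.0 * p * (1.0 + 2.0 * g * (pi - 1.0) - 2.0 * pi)
    ) / (2.0 * g)
    w_bar_1 = w_bar_2 - 2.0 * (params.b1 - params.b2)
    profit_contested = _profit_manager(params, g, wage=w_bar_1)
    profit_advantage = profit_contested - _profit_new(params)
    return CompetitionOutcome(
        w_bar_2=w_bar_2,
        w_bar_1=w_bar_1,
        profit_contested=profit_contested,
        profit_advantage=profit_advantage,
    )


# ---------------------------------------------------------------------------
# Stage-1 contract choice
# ---------------------------------------------------------------------------

def stage1_contract_choice(
    params: ModelParams,
    local_types: tuple[DoctorType | str, DoctorType | str],
) -> Stage1Choice:
    """Profit-maximising stage-1 choice of both practices.

    Each practice compares a local partnership with a new salaried hire (offer
    a partnership only when ``Pi^M > max(0, Pi^N)``). With symmetric type
    configurations relocation costs rule out cross-practice offers. In the
    asymmetric (v, nv) case with feasible relocation the practices compete for
    the efficient doctor; practice 1 retains her whenever the contested profit
    is (strictly) higher than a new hire, i.e. ``b1 - b2 + t > 0``. Exact ties
    resolve to the status-quo new salaried hire.
    """
    types = tuple(DoctorType(z) for z in local_types)
    if any(z == DoctorType.UNKNOWN for z in types):
        raise ValueError("local doctors have known types")
    profit_new = _profit_new(params)

    def local_choice(z: DoctorType, location: int) -> ContractOutcome:
        partner = equilibrium_outcomes(params, Contract.LOCAL_PARTNERSHIP, z, location=location)
        if partner.practice_profit > max(0.0, profit_new):
            return partner
        return equilibrium_outcomes(params, Contract.NEW_SALARIED, DoctorType.UNKNOWN, location=location)

    asymmetric = types in ((DoctorType.V, DoctorType.NV), (DoctorType.NV, DoctorType.V))
    if asymmetric:
        # Relabel so the efficient doctor is local to practice "one"; the
        # opposite configuration is symmetric.
        v_loc = 1 if types[0] == DoctorType.V else 2
        nv_loc = 3 - v_loc
        report = region_membership(params, params.gamma_v)
        if report.in_s_hat:
            # Amenity differential seen from the efficient doctor's practice.
            b_own = params.amenity(v_loc)
            b_rival = params.amenity(nv_loc)
            if b_own - b_rival + params.t > 0.0:
                comp = competition_outcomes(params) if v_loc == 1 else competition_outcomes(
                    ModelParams(
                        m=params.m, p=params.p, pi=params.pi, gamma_v=params.gamma_v,
                        t=params.t, b1=params.b2, b2=params.b1, w_outside=params.w_outside,
                    )
                )
                retained = ContractOutcome(
                    contract=Contract.CONTESTED_PARTNERSHIP,
                    doctor_type=DoctorType.V,
                    effort=_partner_effort(params.p, params.gamma_v),
                    investment=params.p,
                    quality=params.p + _partner_effort(params.p, params.gamma_v),
                    wage=comp.w_bar_1,
                    doctor_utility=_partner_utility(params, params.gamma_v, comp.w_bar_1, b_own),
                    practice_profit=comp.profit_contested,
                )
                rival = equilibrium_outcomes(
                    params, Contract.NEW_SALARIED, DoctorType.UNKNOWN, location=nv_loc
                )
                pair = (retained, rival) if v_loc == 1 else (rival, retained)
                return Stage1Choice(*pair)
        # No feasible competition: each practice considers its local doctor only.
        one = local_choice(types[0], 1)
        two = local_choice(types[1], 2)
        return Stage1Choice(one, two)

    return Stage1Choice(local_choice(types[0], 1), local_choice(types[1], 2))


# ---------------------------------------------------------------------------
# Comparative statics
# ---------------------------------------------------------------------------

_TARGETS: dict[str, Callable[[ModelParams], float]] = {
    "w_bar_1": lambda q: competition_outcomes(q).w_bar_1,
    "w_bar_2": lambda q: competition_outcomes(q).w_bar_2,
    "profit_contested": lambda q: competition_outcomes(q).profit_contested,
    "partnership_advantage": lambda q: _profit_manager(q, q.gamma_v) - _profit_new(q),
    "effort_partner_v": lambda q: _partner_effort(q.p, q.gamma_v),
    "profit_new": _profit_new,
}

_REGION_TARGETS = {"w_bar_1", "w_bar_2", "profit_contested"}


def _replace_param(params: ModelParams, name: str, value: float) -> ModelParams:
    kwargs = {
        "m": params.m, "p": params.p, "pi": params.pi, "gamma_v": params.gamma_v,
        "t": params.t, "b1": params.b1, "b2": params.b2, "w_outside": params.w_outside,
    }
    if name not in kwargs:
        raise ValueError(f"unknown parameter {name!r}")
    kwargs[name] = value
    return ModelParams(**kwargs)


def comparative_static_sign(
    params: ModelParams,
    target: str,
    wrt: str,
    h_rel: float = 1e-5,
    zero_tol: float = 1e-8,
) -> int | None:
    """Sign of d(target)/d(wrt) by a central finite difference.

    Step ``h = h_rel * max(1, |param|)``. If perturbing the parameter crosses a
    region boundary (membership of the competition-feasibility region changes
    for region-restricted targets), a :class:`BoundaryWarning` is emitted and
    ``None`` is returned instead of a sign.
    """
    if target not in _TARGETS:
        raise ValueError(f"unknown target {target!r}; one of {sorted(_TARGETS)}")
    x0 = getattr(params, wrt)
    h = h_rel * max(1.0, abs(x0))
    try:
        lo, hi = _replace_param(params, wrt, x0 - h), _replace_param(params, wrt, x0 + h)
    except ValueError:
        warnings.warn(
            f"{wrt}={x0} lies on the parameter-domain boundary", BoundaryWarning, stacklevel=2
        )
        return None
    if target in _REGION_TARGETS:
        ok = all(region_membership(q, q.gamma_v).in_s_hat for q in (lo, params, hi))
        if not ok:
            warnings.warn(
                f"{wrt}={x0} lies on a region boundary for target {target!r}",
                BoundaryWarning,
                stacklevel=2,
            )
            return None
    f = _TARGETS[target]
    deriv = (f(hi) - f(lo)) / (2.0 * h)
    if abs(deriv) <= zero_tol:
        return 0
    return 1 if deriv > 0 else -1


# ---------------------------------------------------------------------------
# Numeric oracle
# ---------------------------------------------------------------------------

def _golden_max(f: Callable[[float], float], lo: float, hi: float, tol: float = 1e-10) -> float:
    """Golden-section maximisation of a unimodal function on [lo, hi].

    A final quadratic (one-step Newton) polish removes the O(sqrt(eps)) jitter
    of pure value comparisons near a flat optimum; the polish is skipped when
    the optimum sits on the box boundary.
    """
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    x = 0.5 * (a + b)
    h = 1e-3 * max(1.0, abs(x))
    if x - h > lo and x + h < hi:
        f1 = (f(x + h) - f(x - h)) / (2.0 * h)
        f2 = (f(x + h) - 2.0 * f(x) + f(x - h)) / (h * h)
        if f2 < 0.0:
            x_new = x - f1 / f2
            if lo <= x_new <= hi:
                x = x_new
    x = min(max(x, lo), hi)
    # snap to a box corner when the optimum sits on the boundary
    return max((lo, x, hi), key=f)


def numeric_oracle(
    params: ModelParams,
    contract: Contract | str,
    doctor_type: DoctorType | str,
    location: int = 1,
    wage: float = 0.0,
    e_max: float = 50.0,
    q_max: float = 50.0,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> ContractOutcome:
    """Stage-2 equilibrium by simultaneous best-response iteration.

    The doctor maximises utility over effort and the practice maximises profit
    over investment, each by golden-section search on a bounded box, iterating
    until a fixed point. Entirely independent of the closed forms; used to
    verify them to 1e-6.
    """
    contract = Contract(contract)
    doctor_type = DoctorType(doctor_type)
    m, p, pi = params.m, params.p, params.pi
    b = params.amenity(location)

    salaried = contract == Contract.NEW_SALARIED
    if salaried:
        gammas = [params.gamma_v, 1.0]  # both potential types choose effort
    else:
        if doctor_type == DoctorType.UNKNOWN:
            raise ValueError("a partnership requires a doctor of known type")
        gammas = [params.gamma(doctor_type)]

    def doctor_obj(gamma: float, q: float) -> Callable[[float], float]:
        if salaried:
            return lambda e: wage + (q + e) - gamma * e * e / 2.0 + b
        return lambda e: (
            0.5 * (m + p * (q + e) - wage - q * q / 2.0)
            + wage + (q + e) - gamma * e * e / 2.0 + b
        )

    def practice_obj(efforts: list[float]) -> Callable[[float], float]:
        if salaried:
            e_v, e_nv = efforts
            return lambda q: (
                m + p * (pi * (q + e_v) + (1.0 - pi) * (q + e_nv)) - wage - q * q / 2.0
            )
        (e,) = efforts
        return lambda q: 0.5 * (m + p * (q + e) - wage - q * q / 2.0)

    q = 0.0
    efforts = [1.0 for _ in gammas]
    for _ in range(max_iter):
        new_efforts = [_golden_max(doctor_obj(g, q), 0.0, e_max) for g in gammas]
        new_q = _golden_max(practice_obj(new_efforts), 0.0, q_max)
        shift = abs(new_q - q) + sum(abs(a - bb) for a, bb in zip(new_efforts, efforts))
        efforts, q = new_efforts, new_q
        if shift < tol:
            break
    else:
        raise ConvergenceError(f"no fixed point after {max_iter} iterations")

    if salaried:
        profit = practice_obj(efforts)(q)
        if doctor_type == DoctorType.UNKNOWN:
            effort = pi * efforts[0] + (1.0 - pi) * efforts[1]
            utility = pi * doctor_obj(params.gamma_v, q)(efforts[0]) + (1.0 - pi) * doctor_obj(
                1.0, q
            )(efforts[1])
        else:
            idx = 0 if doctor_type == DoctorType.V else 1
            effort = efforts[idx]
            utility = doctor_obj(params.gamma(doctor_type), q)(effort)
    else:
        effort = efforts[0]
        utility = doctor_obj(gammas[0], q)(effort)
        profit = practice_obj(efforts)(q)

    return ContractOutcome(
        contract=contract,
        doctor_type=doctor_type,
        effort=effort,
        investment=q,
        quality=q + effort,
        wage=wage,
        doctor_utility=utility,
        practice_profit=profit,
    )


# ---------------------------------------------------------------------------
# Region sampler (used by sweeps, tests and the acceptance script)
# ---------------------------------------------------------------------------

def sample_s_hat_params(
    rng: np.random.Generator,
    n: int,
    max_tries: int = 200_000,
) -> list[ModelParams]:
    """Rejection-sample ``n`` parameter draws inside the competition region.

    Draws gamma_v ~ U(0.1, 0.95), pi ~ U(0.02, 0.95), p ~ U(0.05, 6),
    m ~ U(0, m_bar), t ~ U within its feasible band and amenities U(0, 2),
    keeping draws that fall in the feasibility region.
    """
    out: list[ModelParams] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("rejection sampling exhausted")
        g = rng.uniform(0.1, 0.95)
        pi = rng.uniform(0.02, 0.95)
        p = rng.uniform(0.05, 6.0)
        probe = ModelParams(m=0.0, p=p, pi=pi, gamma_v=g, t=1e-9)
        rep = region_membership(probe, g)
        if rep.m_bar <= 0.0:
            continue
        m = rng.uniform(0.0, rep.m_bar * 0.999)
        delta_pm = p * (p + 2.0) * (1.0 - g) / (4.0 * g)
        t = rng.uniform(1e-6, delta_pm * 0.999)
        b1, b2 = rng.uniform(0.0, 2.0, size=2)
        cand = ModelParams(m=m, p=p, pi=pi, gamma_v=g, t=t, b1=b1, b2=b2)
        if region_membership(cand, g).in_s_hat:
            out.append(cand)
    return out
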