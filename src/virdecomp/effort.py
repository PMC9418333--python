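"""Optimal host clearance effort: benefit/cost trade-off model.

Host clearance effort ``c`` is the strength of the resistance mechanisms
acting toward pathogen clearance. Effort buys a clearance rate but costs
immunity resources; survival combines both:

    r(c)      = r0 * c                      (hypotheses H1/H2)
    r(c, E)   = r0 * c / (1 + kappa * E)    (H3: high exploitation makes
                                             clearance harder)
    S(c)      = exp(-P * E / r(c)) * exp(-gamma * c**2)

Infection harm accrues at rate ``P * E`` (damage per unit load times load
scale) for the expected infection duration ``1/r(c)``; the quadratic cost
term is the survival price of mounting the response. ``S`` is hump-shaped in
``c`` whenever ``P * E > 0``, and the interior optimum has the closed form

    c* = ( P * E * (1 + kappa * E) / (2 * gamma * r0) )**(1/3).

The hypotheses H1-H3 and their predictions P1-P3 are monotonicity statements
about ``c*`` and ``r(c*)`` under sweeps of PPP (``P``) and exploitation
(``E``); :func:`prediction_report` classifies them by finite differences.
With the default forms ``r(c*)`` is proportional to
``E**(1/3) * (1 + kappa*E)**(-2/3)``, so the direct-interference prediction
P3 (clearance rate decreasing in exploitation) holds exactly where
``kappa * E > 1``; the report locates that threshold numerically.

The benefit, cost and coupling shapes are injectable: any callables with the
same sign/concavity behaviour may replace the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "EffortModelParams",
    "clearance_rate",
    "survival",
    "optimal_effort",
    "closed_form_optimum",
    "rate_decline_threshold",
    "prediction_report",
]


@dataclass(frozen=True)
class EffortModelParams:
    """Parameters of the clearance-effort trade-off.

    E
        Exploitation level (dimensionless load scale).
    P
        Per-parasite pathogenicity: harm per unit load per day.
    r0
        Clearance-rate efficiency, per day per unit effort.
    gamma
        Immunity-cost curvature (per effort squared).
    kappa
        Exploitation-clearance coupling strength; 0 switches H3 off.
    c_max
        Upper bound of the effort domain.
    """

    E: float = 1.0
    P: float = 1.0
    r0: float = 1.0
    gamma: float = 0.5
    kappa: float = 0.0
    c_max: float = 10.0

    def __post_init__(self):
        if min(self.E, self.P, self.r0, self.gamma, self.kappa) < 0:
            raise ValueError("all parameters must be nonnegative")
        if self.c_max <= 0:
            raise ValueError("c_max must be > 0")


def clearance_rate(c, params: EffortModelParams, hypothesis: str = "H1",
                   benefit=None, coupling=None):
    """Per-day clearance rate at effort ``c`` under a hypothesis.

    H1/H2 share ``r = r0*c`` (exploitation does not interfere with
    clearance); H3 divides by ``1 + kappa*E``. H3 with ``kappa = 0`` is
    identical to H1/H2. The shapes are injectable: ``benefit(c, params)``
    replaces the linear effort-to-rate map (must be increasing with
    benefit(0) = 0) and ``coupling(E, params)`` the divisive H3 factor
    (must be >= 1 and increasing in E).
    """
    c = np.asarray(c, float)
    rate = params.r0 * c if benefit is None else np.asarray(
        benefit(c, params), float)
    if hypothesis == "H3":
        factor = (1.0 + params.kappa * params.E if coupling is None
                  else coupling(params.E, params))
        rate = rate / factor
    elif hypothesis not in ("H1", "H2"):
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    return rate if rate.ndim else float(rate)


def survival(c, params: EffortModelParams, hypothesis: str = "H1",
             benefit=None, coupling=None, cost=None):
    """Survival proxy S(c) in (0, 1]: clearance benefit times immunity cost.

    ``c = 0`` is handled as a limit: S -> 0 when there is pathogen harm
    (the infection is never cleared), S = 1 when ``P*E = 0``. ``cost(c,
    params)`` may replace the default quadratic immunity-cost survival
    factor ``exp(-gamma c^2)`` (must be decreasing with cost(0) = 1);
    ``benefit``/``coupling`` are forwarded to :func:`clearance_rate`.
    """
    c = np.asarray(c, float)
    rate = np.asarray(clearance_rate(c, params, hypothesis, benefit,
                                     coupling), float)
    harm = params.P * params.E
    with np.errstate(divide="ignore"):
        burden = np.where(rate > 0, harm / np.where(rate > 0, rate, 1.0),
                          np.where(harm > 0, np.inf, 0.0))
    cost_factor = (np.exp(-params.gamma * c ** 2) if cost is None
                   else np.asarray(cost(c, params), float))
    s = np.exp(-burden) * cost_factor
    return s if s.ndim else float(s)


def closed_form_optimum(params: EffortModelParams,
                        hypothesis: str = "H1") -> float:
    """Analytic optimum of the default forms: (PE(1+kE)/(2 gamma r0))^(1/3).

    The coupling factor enters only under H3 (it is 1 otherwise).
    """
    coupling = 1.0 + (params.kappa * params.E if hypothesis == "H3" else 0.0)
    harm = params.P * params.E
    if harm == 0:
        return 0.0
    return float((harm * coupling / (2.0 * params.gamma * params.r0)) ** (1.0 / 3.0))


def optimal_effort(params: EffortModelParams, hypothesis: str = "H1",
                   xatol: float = 1e-10, benefit=None, coupling=None,
                   cost=None) -> dict:
    """Effort maximising survival: returns c*, r(c*), S(c*) and flags.

    Bounded scalar optimisation on [0, c_max]; ``P*E = 0`` returns the
    boundary optimum c* = 0 with ``boundary = True``; an optimum binding at
    ``c_max`` is likewise flagged. Alternative benefit/cost/coupling
    callables are forwarded to :func:`survival`.
    """
    shapes = dict(benefit=benefit, coupling=coupling, cost=cost)
    if params.P * params.E == 0:
        return {"c_star": 0.0, "rate": 0.0, "survival": float(
            survival(0.0, params, hypothesis, **shapes)), "boundary": True}

    res = minimize_scalar(
        lambda c: -survival(c, params, hypothesis, **shapes),
        bounds=(0.0, params.c_max), method="bounded",
        options={"xatol": xatol})
    c_star = float(res.x)
    boundary = c_star >= params.c_max * (1 - 1e-6)
    return {"c_star": c_star,
            "rate": float(clearance_rate(c_star, params, hypothesis,
                                         benefit, coupling)),
            "survival": float(survival(c_star, params, hypothesis, **shapes)),
            "boundary": boundary}


def rate_decline_threshold(params: EffortModelParams,
                           e_bounds: tuple[float, float] = (1e-3, 50.0),
                           rel_step: float = 1e-5) -> float:
    """Exploitation level above which r(c*) decreases under H3.

    Solves d log r(c*(E)) / dE = 0 numerically (central differences +
    bisection); for the default forms the root sits at kappa * E = 1.
    Returns NaN if the derivative does not change sign on ``e_bounds``.
    """
    if params.kappa <= 0:
        return float("nan")

    def dlog_rate(E):
        h = rel_step * E
        lo = replace_E(params, E - h)
        hi = replace_E(params, E + h)
        r_lo = optimal_effort(lo, "H3")["rate"]
        r_hi = optimal_effort(hi, "H3")["rate"]
        return (np.log(r_hi) - np.log(r_lo)) / (2 * h)

    a, b = e_bounds
    fa, fb = dlog_rate(a), dlog_rate(b)
    if fa * fb > 0:
        return float("nan")
    from scipy.optimize import brentq

    return float(brentq(dlog_rate, a, b, xtol=1e-8))


def replace_E(params: EffortModelParams, E: float) -> EffortModelParams:
    """Copy of ``params`` with a new exploitation level."""
    return EffortModelParams(E=E, P=params.P, r0=params.r0,
                             gamma=params.gamma, kappa=params.kappa,
                             c_max=params.c_max)


def _sign(delta: np.ndarray, tol: float = 1e-10) -> str:
    if (delta > tol).all():
        return "+"
    if (delta < -tol).all():
        return "-"
    if (np.abs(delta) <= tol).all():
        return "0"
    return "mixed"


def prediction_report(p_grid=None, e_grid=None,
                      base: EffortModelParams | None = None,
                      kappa_h3: float = 8.0) -> pd.DataFrame:
    """Classify the monotonicity of c* and r(c*) under parameter sweeps.

    Rows (one per hypothesis x swept parameter) report the finite-difference
    sign of dc*/d(param) and dr(c*)/d(param): the qualitative content of
    predictions P1 (clearance rate rises with PPP), P2 (rises with
    exploitation when it only adds harm) and P3 (falls with exploitation when
    high loads directly hinder clearance). For H3 the row also reports the
    numerically located threshold exploitation level above which r(c*)
    decreases (kappa*E = 1 for the default forms), NaN when the sweep does
    not cross it. The default ``kappa_h3`` puts the whole default sweep in
    the strongly-coupled regime (kappa*E > 1) where the P3 decline holds;
    weaker coupling turns the H3 row into a rise-then-fall profile whose
    onset the threshold column locates.
    """
    base = base or EffortModelParams()
    p_grid = np.asarray([0.25, 0.5, 1.0, 2.0, 4.0] if p_grid is None else p_grid,
                        float)
    e_grid = np.asarray([0.25, 0.5, 1.0, 2.0, 4.0] if e_grid is None else e_grid,
                        float)
    if len(p_grid) < 3 or len(e_grid) < 3:
        raise ValueError("grids need >= 3 points")
    rows = []

    def sweep(hypothesis, param, grid, kappa):
        c_stars, rates = [], []
        for v in grid:
            kwargs = {"E": base.E, "P": base.P, "r0": base.r0,
                      "gamma": base.gamma, "kappa": kappa,
                      "c_max": base.c_max}
            kwargs[param] = float(v)
            opt = optimal_effort(EffortModelParams(**kwargs), hypothesis)
            c_stars.append(opt["c_star"])
            rates.append(opt["rate"])
        return np.asarray(c_stars), np.asarray(rates)

    # H1: PPP sweep, no coupling (prediction P1)
    c, r = sweep("H1", "P", p_grid, kappa=0.0)
    rows.append(("H1", "P", _sign(np.diff(c)), _sign(np.diff(r)), np.nan))
    # H2: exploitation sweep, no coupling (prediction P2)
    c, r = sweep("H2", "E", e_grid, kappa=0.0)
    rows.append(("H2", "E", _sign(np.diff(c)), _sign(np.diff(r)), np.nan))
    # H3: exploitation sweep with coupling (prediction P3)
    c, r = sweep("H3", "E", e_grid, kappa=kappa_h3)
    dr = np.diff(r)
    if (dr < 0).all():
        threshold = float(e_grid[0])  # decreasing over the whole sweep
    elif (dr < 0).any():
        threshold = float(e_grid[1:][np.argmax(dr < 0)])
    else:
        threshold = float("nan")
    rows.append(("H3", "E", _sign(np.diff(c)), _sign(dr), threshold))
    return pd.DataFrame(rows, columns=[
        "hypothesis", "swept", "d_c_star", "d_rate_at_optimum",
        "rate_decline_onset_E"])
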