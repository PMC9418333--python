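"""Synthetic per-fly infection experiments with the study's statistical structure.

The generator emulates a systemic-injection experiment in *Drosophila
melanogaster*: four bacterial species x five injection doses (92-92,000 CFU) x
three replicates, a 36-fly survival cohort checked daily, and an independent
homogenisation cohort of four flies per treatment per sampling day
(days 1, 2, 3, 4, 7, 14, 21, 28, 35).

Within-host model (discrete daily steps, injection at day 0):

* log load grows linearly at ``growth_rate`` from log(dose) and saturates at a
  dose-dependent set-point bacterial load (SPBL),
  ``log SPBL = spbl_log_scale + spbl_exp * log(dose)``, with a per-fly
  lognormal offset (``load_sd``).
* each day an infected fly clears with probability
  ``clear_base * exp(-clear_load_coef * log L(t) - clear_decay * a(t))``
  (absorbing; load drops to zero) -- a positive ``clear_load_coef`` makes
  high loads harder to clear, the load-dependent-clearance hypothesis (H3),
  and the post-acute decay term means infections are mostly cleared early or
  persist at the set point;
* conditional on not clearing, it dies with per-day hazard (used directly as
  the daily death probability)
  ``exp(baseline_log_hazard + ppp_true * log L(t) - acute_decay * a(t))``,
  where ``a(t)`` is the time since the acute phase ended (the later of load
  saturation and ``acute_days``). ``ppp_true`` is the per-parasite
  pathogenicity (damage per unit log load); the decay term makes infection
  mortality peak during the acute phase and wane once the infection is
  controlled at the set point, so the maximum hazard is a structural peak at
  height ``exp(baseline_log_hazard + ppp_true * log SPBL)``.
* uninfected flies (controls, and flies that cleared) die with the baseline
  injection-trauma hazard ``exp(baseline_log_hazard) * w(t)`` where
  ``w(t) = (t/3) * exp(1 - t/3)`` peaks at 1 around day 3 -- the
  infection-free maximum hazard is then ``exp(baseline_log_hazard)``, the
  y-intercept of the species reaction norm.
* at the experiment level every fly additionally faces a Gompertz aging
  hazard ``exp(aging_log_hazard + aging_rate * t)``, negligible inside the
  0-20 day virulence window but dominant from roughly day 40, so cohorts die
  out towards the end of the 78-day follow-up and the dead-fly
  infection-status data span the chronic phase.

Clearance is resolved before death within a day. Observation layer: loads
below the plating detection limit are recorded as zero with a
``below_detection`` flag; loads above the species' highest countable value are
recorded at that maximum with ``at_max_censored``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DEAD_COLUMNS, LOAD_COLUMNS, SURVIVAL_COLUMNS

__all__ = [
    "SpeciesParams",
    "SimulationConfig",
    "default_species_params",
    "default_config",
    "simulate_fly",
    "simulate_experiment",
    "simulate_plating",
]

DOSES = (92, 920, 1840, 9200, 92000)
SAMPLING_DAYS = (1, 2, 3, 4, 7, 14, 21, 28, 35)


@dataclass(frozen=True)
class SpeciesParams:
    """Within-host parameters of one bacterial species.

    Attributes
    ----------
    growth_rate
        Early-phase log-load growth, per day.
    spbl_log_scale, spbl_exp
        Intercept and slope of the log set-point load on log dose.
    ppp_true
        Per-parasite pathogenicity: slope of the log death hazard on log load.
    baseline_log_hazard
        Log per-day death hazard at load 1 (and of uninfected/cleared flies).
    clear_base
        Per-day clearance probability at log load 0.
    clear_load_coef
        Exponential decline of the clearance probability per unit log load.
    load_sd
        Between-fly SD of the lognormal load offset.
    max_countable_cfu
        Highest back-calculable load; larger loads are censored at this value.
    acute_decay
        Per-day waning of the infection death hazard once the acute phase is
        over (0 keeps the hazard flat at the set point).
    acute_days
        Minimum acute-phase duration in days; waning starts at the later of
        this and the load-saturation day.
    clear_decay
        Per-day waning of the clearance probability after the acute phase
        (established set-point infections become hard to clear).
    """

    name: str
    growth_rate: float
    spbl_log_scale: float
    spbl_exp: float
    ppp_true: float
    baseline_log_hazard: float
    clear_base: float
    clear_load_coef: float
    load_sd: float
    max_countable_cfu: float = 1e6
    acute_decay: float = 0.25
    acute_days: float = 3.0
    clear_decay: float = 0.2

    def __post_init__(self):
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")
        if not 0 <= self.clear_base <= 1:
            raise ValueError("clear_base must be in [0, 1]")
        if self.load_sd < 0:
            raise ValueError("load_sd must be >= 0")

    def log_spbl(self, dose: float) -> float:
        return self.spbl_log_scale + self.spbl_exp * np.log(dose)


def default_species_params() -> dict[str, SpeciesParams]:
    """Presets named after the four study species.

    Tuned only to qualitative orderings (lowest exploitation and damage for
    *E. cloacae*, extreme virulence for *Ps. entomophila*, persistent loads of
    tens-to-hundreds vs tens-of-thousands of CFU); they are illustrative, not
    fitted to the deposited data.
    """
    return {
        "E_cloacae": SpeciesParams(
            "E_cloacae", growth_rate=1.0, spbl_log_scale=1.0, spbl_exp=0.30,
            ppp_true=0.10, baseline_log_hazard=-4.2, clear_base=0.30,
            clear_load_coef=0.35, load_sd=0.4, max_countable_cfu=1e6),
        "Pr_burhodogranariea": SpeciesParams(
            "Pr_burhodogranariea", growth_rate=1.5, spbl_log_scale=2.0,
            spbl_exp=0.30, ppp_true=0.45, baseline_log_hazard=-4.2,
            clear_base=0.15, clear_load_coef=0.45, load_sd=0.4,
            max_countable_cfu=1e6),
        "L_lactis": SpeciesParams(
            "L_lactis", growth_rate=2.0, spbl_log_scale=3.0, spbl_exp=0.30,
            ppp_true=0.50, baseline_log_hazard=-4.2, clear_base=0.10,
            clear_load_coef=0.50, load_sd=0.4, max_countable_cfu=3e4),
        "Ps_entomophila": SpeciesParams(
            "Ps_entomophila", growth_rate=3.0, spbl_log_scale=6.0,
            spbl_exp=0.40, ppp_true=0.50, baseline_log_hazard=-4.2,
            clear_base=0.15, clear_load_coef=0.30, load_sd=0.4,
            max_countable_cfu=1e6),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Full experimental design: arms, cohort sizes, observation limits."""

    species_params: Mapping[str, SpeciesParams] = field(
        default_factory=default_species_params)
    doses: Sequence[int] = DOSES
    n_replicates: int = 3
    n_survival_per_treatment: int = 36
    n_homog_per_day: int = 4
    sampling_days: Sequence[int] = SAMPLING_DAYS
    detection_limit_cfu: float = 7.0
    horizon_days: int = 78
    contamination_rate: float = 0.02
    aging_log_hazard: float = -7.6
    aging_rate: float = 0.07
    seed: int = 0

    def __post_init__(self):
        counts = (self.n_replicates, self.n_survival_per_treatment,
                  self.n_homog_per_day)
        if any(c < 1 for c in counts):
            raise ValueError("all cohort counts must be >= 1")
        days = list(self.sampling_days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("sampling_days must be strictly increasing")


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    return SimulationConfig(seed=seed, **overrides)


def _child_rng(master_seed: int, *key) -> np.random.Generator:
    """Independent per-arm stream from a stable hash of the arm identity."""
    tag = ":".join([str(master_seed), *map(str, key)]).encode()
    return np.random.default_rng(zlib.crc32(tag))


def _log_load(params: SpeciesParams, dose: float, eps: np.ndarray,
              day: float) -> np.ndarray:
    base = min(np.log(dose) + params.growth_rate * day, params.log_spbl(dose))
    return base + eps


_TRAUMA_T0 = 3.0  # day of the injection-trauma mortality peak


def _trauma(day: float) -> float:
    """Baseline (infection-free) hazard shape, peaking at 1 on day ``t0``."""
    return (day / _TRAUMA_T0) * np.exp(1.0 - day / _TRAUMA_T0)


def _acute_end(params: SpeciesParams, dose: float) -> float:
    """Day the acute phase ends: load saturation, but at least acute_days."""
    if params.growth_rate > 0:
        t_sat = max(0.0, (params.log_spbl(dose) - np.log(dose))
                    / params.growth_rate)
    else:
        t_sat = 0.0
    return max(t_sat, params.acute_days)


def _simulate_cohort(params: SpeciesParams, dose: float, n: int, horizon: int,
                     rng: np.random.Generator, aging: tuple | None = None):
    """Vectorised daily competing-risk walk for ``n`` flies of one arm.

    Returns ``(death_day, cleared_day, eps)`` where days are ``inf`` when the
    event never happened before the horizon. ``dose == 0`` simulates an
    uninfected (control) arm with only the baseline hazard. ``aging`` is an
    optional experiment-level ``(log_hazard, rate)`` Gompertz pair added to
    every fly's hazard.
    """
    eps = rng.normal(0.0, params.load_sd, n) if dose > 0 else np.zeros(n)
    death_day = np.full(n, np.inf)
    cleared_day = np.full(n, np.inf)
    alive = np.ones(n, bool)
    cleared = np.zeros(n, bool) if dose > 0 else np.ones(n, bool)
    acute_end = _acute_end(params, dose) if dose > 0 else 0.0
    h_base = np.exp(params.baseline_log_hazard)
    for day in range(1, horizon + 1):
        if not alive.any():
            break
        if dose > 0:
            log_load = _log_load(params, dose, eps, day)
        else:
            log_load = np.zeros(n)
        infected = alive & ~cleared
        post_acute = max(0.0, day - acute_end)
        # clearance first within the day (absorbing)
        p_clear = np.clip(
            params.clear_base * np.exp(-params.clear_load_coef * log_load
                                       - params.clear_decay * post_acute),
            0.0, 1.0)
        u = rng.random(n)
        newly_cleared = infected & (u < p_clear)
        cleared_day[newly_cleared] = day
        cleared |= newly_cleared
        # death: infected flies face the load-dependent hazard (waning after
        # the acute phase); uninfected/cleared flies the trauma baseline
        waning = params.acute_decay * post_acute
        with np.errstate(invalid="ignore"):
            h_inf = np.exp(params.baseline_log_hazard
                           + params.ppp_true * log_load - waning)
        h_inf = np.nan_to_num(h_inf, nan=0.0)
        hazard = np.where(alive & ~cleared, h_inf, h_base * _trauma(day))
        if aging is not None:
            hazard = hazard + np.exp(aging[0] + aging[1] * day)
        p_death = np.clip(hazard, 0.0, 1.0)
        v = rng.random(n)
        dying = alive & (v < p_death)
        death_day[dying] = day
        alive &= ~dying
    return death_day, cleared_day, eps


def simulate_fly(params: SpeciesParams, dose: float,
                 rng: np.random.Generator, horizon: int = 35) -> pd.DataFrame:
    """Single-fly daily trajectory: load, alive and cleared flags per day.

    The load column reports the true (unobserved) CFU load, zero after
    clearance; rows continue after death with ``alive == 0`` for bookkeeping.
    Tracks the within-host infection process only; the experiment-level
    trauma/aging mortality of :func:`simulate_experiment` is not applied.
    """
    if dose <= 0:
        raise ValueError("dose must be > 0")
    death_day, cleared_day, eps = _simulate_cohort(params, dose, 1, horizon, rng)
    days = np.arange(1, horizon + 1)
    load = np.array([
        float(np.exp(_log_load(params, dose, eps, d)[0])) for d in days])
    load[days >= cleared_day[0]] = 0.0
    return pd.DataFrame({
        "day": days,
        "load": load,
        "alive": (days < death_day[0]).astype(int),
        "cleared": (days >= cleared_day[0]).astype(int),
    })


def _arm_treatments(doses) -> list[tuple[str, int]]:
    return [("bacterial", int(d)) for d in doses] + [("ringer", 0), ("naive", 0)]


def simulate_experiment(config: SimulationConfig):
    """Simulate the full design; returns (survival, load, dead-fly) tables.

    Per species block and replicate there are seven treatment arms (five doses
    plus Ringer's and naive controls), each with its own survival cohort and an
    independent destructively-sampled homogenisation cohort. Flies alive at
    the horizon are right-censored (``event == 0``). Dead-fly infection status
    is recorded for survival-cohort flies dying in the chronic-phase windows
    14-35 and 56-78 days post injection.
    """
    surv_rows, load_rows, dead_rows = [], [], []
    sampling_days = list(config.sampling_days)
    for species, params in config.species_params.items():
        for replicate in range(1, config.n_replicates + 1):
            for treatment, dose in _arm_treatments(config.doses):
                rng_s = _child_rng(config.seed, species, treatment, dose,
                                   replicate, "survival")
                n = config.n_survival_per_treatment
                aging = (config.aging_log_hazard, config.aging_rate)
                death_day, cleared_day, _ = _simulate_cohort(
                    params, dose, n, config.horizon_days, rng_s, aging)
                persons = rng_s.choice(["A", "B"], n)
                for i in range(n):
                    died = np.isfinite(death_day[i])
                    day = death_day[i] if died else config.horizon_days
                    fly = f"{species[:2]}-{treatment[0]}{dose}-r{replicate}-s{i}"
                    surv_rows.append((fly, species, treatment, dose, replicate,
                                      persons[i], float(day), int(died)))
                    if died and treatment == "bacterial" and (
                            14 <= day <= 35 or 56 <= day <= 78):
                        infected = int(not cleared_day[i] <= death_day[i])
                        dead_rows.append((fly, species, dose, replicate,
                                          persons[i], int(day), infected))
                # homogenisation cohort: n_homog_per_day flies pre-assigned to
                # each sampling day, homogenised only if still alive that day
                rng_h = _child_rng(config.seed, species, treatment, dose,
                                   replicate, "homog")
                n_h = config.n_homog_per_day * len(sampling_days)
                h_death, h_cleared, h_eps = _simulate_cohort(
                    params, dose, n_h, config.horizon_days, rng_h, aging)
                assigned = np.repeat(sampling_days, config.n_homog_per_day)
                contam = rng_h.random(n_h) < config.contamination_rate
                for i, day in enumerate(assigned):
                    if h_death[i] <= day:
                        continue  # died before its sampling day
                    if dose > 0 and h_cleared[i] > day:
                        load = float(np.exp(
                            _log_load(params, dose, h_eps[i:i + 1], day)[0]))
                    else:
                        load = 0.0
                    below = int(load < config.detection_limit_cfu)
                    at_max = 0
                    if below:
                        load = 0.0
                    elif load > params.max_countable_cfu:
                        load, at_max = params.max_countable_cfu, 1
                    fly = f"{species[:2]}-{treatment[0]}{dose}-r{replicate}-h{i}"
                    load_rows.append((fly, species, dose, replicate, int(day),
                                      load, below, at_max, int(contam[i])))
    survival = pd.DataFrame(surv_rows, columns=SURVIVAL_COLUMNS)
    loads = pd.DataFrame(load_rows, columns=LOAD_COLUMNS)
    dead = pd.DataFrame(dead_rows, columns=DEAD_COLUMNS)
    return survival, loads, dead


def simulate_plating(load_cfu: float, dilutions: Sequence[float],
                     droplet_volume_ul: float, homogenate_volume_ul: float,
                     rng: np.random.Generator, n_droplets: int = 3) -> np.ndarray:
    """Poisson droplet counts for a serial-dilution plating of one homogenate.

    ``dilutions`` are dilution factors (1 for neat, 1e-3 for 1:10**3 ...);
    the expected count per droplet is
    ``load_cfu * dilution * droplet_volume / homogenate_volume``.
    Returns an ``(n_dilutions, n_droplets)`` integer array.
    """
    if load_cfu < 0:
        raise ValueError("load_cfu must be >= 0")
    means = (load_cfu * np.asarray(dilutions, float)
             * droplet_volume_ul / homogenate_volume_ul)
    return rng.poisson(means[:, None], size=(len(means), n_droplets))
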