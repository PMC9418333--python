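"""Bacterial clearance: plating arithmetic, clearance indices and models.

A fly counts as having *cleared* its infection when no colonies are visible in
any plated droplet, i.e. its load is below the detection limit (~7 CFU for
100 uL homogenate and three 5 uL droplets). The clearance index of an arm
(species x dose x replicate) over a day set D is

    index = mean_{d in D} [ P(cleared | alive, sampled at d) * P(alive at d) ],

estimating the proportion of the whole initial population that cleared the
infection; days with no live sampled flies are dropped from the mean.

Statistical comparisons: species differences in the index use a
Kruskal-Wallis test (chi-square approximation, tie-corrected) with pairwise
Mann-Whitney-U post hocs and Benjamini-Hochberg correction; day-7 load vs
injection dose, dead-fly clearance vs dose, and live/dead concordance are
ordinary linear, binomial-logistic and quasibinomial fits respectively.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PlatingResult",
    "ClearanceIndex",
    "SeparationError",
    "detection_limit",
    "backcalculate_load",
    "proportion_cleared_live",
    "proportion_alive",
    "clearance_index",
    "clearance_indices",
    "summarise_overall_clearance",
    "summarise_dead_clearance",
    "mann_whitney_u",
    "benjamini_hochberg",
    "compare_clearance_species",
    "fit_dose_spbl",
    "fit_dead_clearance",
    "fit_live_dead_concordance",
    "live_dead_counts",
]


class SeparationError(RuntimeError):
    """Complete separation in a logistic fit: estimates diverge."""


@dataclass(frozen=True)
class PlatingResult:
    """Back-calculated load from serial-dilution droplet counts."""

    droplet_counts: np.ndarray
    chosen_dilution: float | None
    load_cfu: float
    cleared: bool
    at_max_censored: bool = False


@dataclass(frozen=True)
class ClearanceIndex:
    """Clearance index of one arm over a day set; NaN when undefined."""

    species: str
    dose_cfu: int
    replicate: int
    day_set: tuple[int, ...]
    value: float
    days_available: tuple[int, ...]

    @property
    def defined(self) -> bool:
        return len(self.days_available) > 0


def detection_limit(homogenate_volume_ul: float, n_droplets: int,
                    droplet_volume_ul: float) -> tuple[float, int]:
    """Smallest detectable load: one expected colony across all droplets.

    Returns the raw limit ``homogenate / (n_droplets * droplet_volume)`` and
    its integer ceiling. (100 uL, 3, 5 uL) -> (6.67, 7).
    """
    if min(homogenate_volume_ul, n_droplets, droplet_volume_ul) <= 0:
        raise ValueError("all plating arguments must be > 0")
    plated = n_droplets * droplet_volume_ul
    if plated > homogenate_volume_ul:
        raise ValueError("plated volume exceeds homogenate volume")
    raw = homogenate_volume_ul / plated
    return raw, math.ceil(raw)


def backcalculate_load(droplet_counts, dilutions, homogenate_volume_ul: float,
                       droplet_volume_ul: float,
                       countable_range: tuple[float, float] = (10.0, 60.0),
                       max_droplet_count: int = 200) -> PlatingResult:
    """Back-calculate CFU per fly from droplet counts at serial dilutions.

    ``droplet_counts`` has one row of colony counts per dilution;
    ``dilutions`` are the matching dilution factors (1 for neat, 0.01 for
    1:100, ...) in order of increasing dilution (strictly decreasing factor).
    The chosen dilution is the lowest one whose droplet mean lies in
    ``countable_range``; if none does, the lowest dilution with all droplets
    below ``max_droplet_count`` is used. Load = droplet mean / dilution factor
    x (homogenate volume / droplet volume). All-zero plates mean the
    infection was cleared; plates overgrown at every dilution yield an
    ``at_max_censored`` signal (the caller assigns the species maximum).
    """
    counts = np.atleast_2d(np.asarray(droplet_counts, float))
    factors = np.asarray(dilutions, float)
    if len(factors) != counts.shape[0]:
        raise ValueError("one dilution factor per row of droplet counts")
    if (np.diff(factors) >= 0).any():
        raise ValueError("dilutions must be strictly increasing "
                         "(strictly decreasing factors)")
    if (counts == 0).all():
        return PlatingResult(counts, None, 0.0, cleared=True)
    means = counts.mean(axis=1)
    lo, hi = countable_range
    in_range = (means >= lo) & (means <= hi)
    chosen = None
    if in_range.any():
        chosen = int(np.argmax(in_range))  # lowest dilution in range
    else:
        all_countable = (counts <= max_droplet_count).all(axis=1)
        if all_countable.any():
            chosen = int(np.argmax(all_countable))
    if chosen is None:
        return PlatingResult(counts, None, float("nan"), cleared=False,
                             at_max_censored=True)
    load = float(means[chosen] / factors[chosen]
                 * homogenate_volume_ul / droplet_volume_ul)
    return PlatingResult(counts, float(factors[chosen]), load, cleared=False)


def _arm_loads(loads: pd.DataFrame, species, dose, replicate, day):
    return loads[(loads["species"] == species)
                 & (loads["dose_cfu"] == dose)
                 & (loads["replicate"] == replicate)
                 & (loads["day_sampled"] == day)
                 & (loads["contaminated"] == 0)]


def proportion_cleared_live(loads: pd.DataFrame, species, dose, replicate,
                            day) -> tuple[float, int, int]:
    """Proportion of live homogenised flies cleared at ``day``: (p, k, n).

    NaN with zero counts when no (non-contaminated) fly was sampled alive --
    e.g. arms where mortality left no flies to homogenise.
    """
    cell = _arm_loads(loads, species, dose, replicate, day)
    n = len(cell)
    if n == 0:
        return float("nan"), 0, 0
    k = int((cell["below_detection"] == 1).sum())
    return k / n, k, n


def proportion_alive(survival: pd.DataFrame, species, dose, replicate,
                     day) -> float:
    """Proportion of the arm's survival cohort still alive at ``day``."""
    cohort = survival[(survival["species"] == species)
                      & (survival["dose_cfu"] == dose)
                      & (survival["replicate"] == replicate)]
    if len(cohort) == 0:
        raise ValueError(f"empty survival cohort for "
                         f"({species}, {dose}, {replicate})")
    dead = (cohort["event"] == 1) & (cohort["death_day"] <= day)
    return float((~dead).sum() / len(cohort))


def clearance_index(survival: pd.DataFrame, loads: pd.DataFrame, species,
                    dose, replicate, day_set=(3, 4)) -> ClearanceIndex:
    """Population-level clearance of one arm, averaged over ``day_set``.

    Per day: (cleared | alive) x (alive), i.e. the proportion of the initial
    population estimated to be alive and cleared; days without live sampled
    flies are dropped (not imputed as zero) and reported in
    ``days_available``.
    """
    per_day, avail = [], []
    for day in day_set:
        p_cl, _, n = proportion_cleared_live(loads, species, dose, replicate,
                                             day)
        if n == 0:
            continue
        per_day.append(p_cl * proportion_alive(survival, species, dose,
                                               replicate, day))
        avail.append(int(day))
    value = float(np.mean(per_day)) if per_day else float("nan")
    return ClearanceIndex(species, int(dose), int(replicate), tuple(day_set),
                          value, tuple(avail))


def clearance_indices(survival: pd.DataFrame, loads: pd.DataFrame,
                      day_set=(3, 4)) -> pd.DataFrame:
    """Clearance index for every bacterial arm; undefined arms flagged."""
    arms = (loads[["species", "dose_cfu", "replicate"]]
            .drop_duplicates().sort_values(
                ["species", "dose_cfu", "replicate"]))
    rows = []
    for species, dose, rep in arms.itertuples(index=False):
        if dose == 0:
            continue
        ci = clearance_index(survival, loads, species, dose, rep, day_set)
        rows.append((species, dose, rep, ci.value,
                     ",".join(map(str, ci.days_available)), ci.defined))
    return pd.DataFrame(rows, columns=[
        "species", "dose_cfu", "replicate", "value", "days_available",
        "defined"])


def summarise_overall_clearance(loads: pd.DataFrame,
                                by: str = "species") -> pd.DataFrame:
    """Cleared / total homogenised flies pooled across doses and days.

    Percentage reported to one decimal place; contaminated flies excluded.
    """
    ok = loads[loads["contaminated"] == 0]
    out = (ok.assign(cleared=(ok["below_detection"] == 1).astype(int))
           .groupby(by)
           .agg(n_cleared=("cleared", "sum"), n_total=("cleared", "size"))
           .reset_index())
    out["percent"] = (100.0 * out["n_cleared"] / out["n_total"]).round(1)
    return out


def summarise_dead_clearance(dead: pd.DataFrame,
                             by: str = "species") -> pd.DataFrame:
    """Flies uninfected at death / total homogenised dead flies, percent."""
    out = (dead.assign(cleared=(dead["infected_at_death"] == 0).astype(int))
           .groupby(by)
           .agg(n_cleared=("cleared", "sum"), n_total=("cleared", "size"))
           .reset_index())
    out["percent"] = (100.0 * out["n_cleared"] / out["n_total"]).round(1)
    return out


def _u_statistic(pooled_ranks: np.ndarray, idx: tuple, n1: int, n2: int):
    r1 = pooled_ranks[list(idx)].sum()
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney_u(x, y, exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test: (U of the first sample, p value).

    Exact permutation enumeration (tie-aware, via midranks) when the combined
    sample size is at most ``exact_max_n``; otherwise the normal approximation
    with tie correction. The two-sided exact p is the permutation fraction
    with |U - n1*n2/2| at least as large as observed.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if n1 + n2 <= exact_max_n:
        mu = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mu) - 1e-12
        hits = total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = _u_statistic(ranks, idx, n1, n2)
            total += 1
            if abs(u - mu) >= dev_obs:
                hits += 1
        return u_obs, hits / total
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=False)
    return u_obs, float(res.pvalue)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (FDR control)."""
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]


def compare_clearance_species(indices: pd.DataFrame, value_col: str = "value",
                              group_col: str = "species") -> dict:
    """Kruskal-Wallis across species plus BH-corrected pairwise Mann-Whitney.

    ``indices`` holds one clearance-index value per arm; undefined (NaN)
    values are dropped. Returns ``{"kruskal_h", "kruskal_df", "kruskal_p",
    "pairwise"}`` with a per-pair DataFrame.
    """
    d = indices.dropna(subset=[value_col])
    groups = {g: sub[value_col].to_numpy()
              for g, sub in d.groupby(group_col, sort=True)}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with data")
    values = list(groups.values())
    if np.ptp(np.concatenate(values)) == 0:
        h, p = 0.0, 1.0  # all observations identical: no evidence
    else:
        h, p = sps.kruskal(*values)
    pairs, praw = [], []
    for a, b in itertools.combinations(sorted(groups), 2):
        u, pv = mann_whitney_u(groups[a], groups[b])
        pairs.append((f"{a} vs {b}", u, pv))
        praw.append(pv)
    padj = benjamini_hochberg(praw) if praw else np.array([])
    pairwise = pd.DataFrame(
        [(name, u, pv, pa) for (name, u, pv), pa in zip(pairs, padj)],
        columns=["pair", "U", "p_raw", "p_bh"])
    return {"kruskal_h": float(h), "kruskal_df": len(groups) - 1,
            "kruskal_p": float(p), "pairwise": pairwise}


@dataclass
class GlmReport:
    """Slim fit report for the dose-load, dead-fly and concordance models."""

    model_id: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n_used: int
    dispersion: float | None = None
    deviance: float | None = None
    result: object = None


def fit_dose_spbl(loads: pd.DataFrame, species: str, transform: str = "log",
                  day: int = 7, exclude_at_max: bool = False,
                  person: pd.Series | None = None) -> GlmReport:
    """Day-7 load on injection dose: log(load) ~ log(dose) + replicate.

    Below-detection flies are removed first (they carry no load information);
    ``exclude_at_max`` additionally drops maximum-censored flies.
    ``transform="loglog"`` iterates the logarithm on both load and dose (used
    for species whose dose-load relation is closer to log-log-linear). An
    optional aligned ``person`` factor is included when provided (the load
    schema itself does not carry one).
    """
    d = loads[(loads["species"] == species)
              & (loads["day_sampled"] == day)
              & (loads["contaminated"] == 0)
              & (loads["below_detection"] == 0)].copy()
    if exclude_at_max:
        d = d[d["at_max_censored"] == 0]
    if person is not None:
        d["person"] = person.reindex(d.index)
    if len(d) == 0:
        raise ValueError(f"no usable day-{day} loads for {species}")
    if d["dose_cfu"].nunique() < 3:
        raise ValueError("need >= 3 distinct doses after filtering")
    tf = (lambda v: np.log(np.log(v))) if transform == "loglog" else np.log
    d["y"] = tf(d["load_cfu"])
    d["x"] = tf(d["dose_cfu"].astype(float))
    formula = "y ~ x"
    if d["replicate"].nunique() > 1:
        formula += " + C(replicate)"
    if "person" in d and d["person"].nunique() > 1:
        formula += " + C(person)"
    res = smf.ols(formula, data=d).fit()
    return GlmReport("dose_spbl", res.params, res.bse, res.pvalues,
                     int(res.nobs), result=res)


def fit_dead_clearance(dead: pd.DataFrame, species: str,
                       include_replicate: bool = False,
                       include_day: bool = True) -> GlmReport:
    """Infection status at death vs dose: binomial logistic regression.

    Formula: infected ~ log(log(dose)) x log(day found) + person
    [+ replicate]; ``include_day=False`` drops the day term (needed when all
    flies were found on one day). Raises when only one outcome class is
    present (the model is then meaningless) and :class:`SeparationError` on
    complete separation.
    """
    d = dead[dead["species"] == species].copy()
    if len(d) == 0:
        raise ValueError(f"no dead-fly records for {species}")
    if d["infected_at_death"].nunique() < 2:
        raise ValueError("only one outcome class present: cannot fit")
    if (d["dose_cfu"] <= np.e).any():
        raise ValueError("log(log(dose)) requires dose > e")
    d["lldose"] = np.log(np.log(d["dose_cfu"].astype(float)))
    d["lday"] = np.log(d["day_found"].astype(float))
    formula = ("infected_at_death ~ lldose * lday" if include_day
               else "infected_at_death ~ lldose")
    if d["person"].nunique() > 1:
        formula += " + C(person)"
    if include_replicate and d["replicate"].nunique() > 1:
        formula += " + C(replicate)"
    model = smf.glm(formula, data=d, family=sm.families.Binomial())
    try:
        res = model.fit()
    except Exception as err:  # statsmodels PerfectSeparationError
        if "eparation" in type(err).__name__ or "eparation" in str(err):
            raise SeparationError(
                f"complete separation in dead-fly fit for {species}") from err
        raise
    mu = res.fittedvalues.to_numpy()
    if np.all((mu < 1e-8) | (mu > 1 - 1e-8)):
        raise SeparationError(
            f"complete separation in dead-fly fit for {species}")
    return GlmReport("dead_clearance", res.params, res.bse, res.pvalues,
                     int(res.nobs), deviance=float(res.deviance), result=res)


def live_dead_counts(loads: pd.DataFrame, dead: pd.DataFrame) -> pd.DataFrame:
    """Pooled uninfected/infected counts per species x dose, live and dead."""
    live = loads[(loads["contaminated"] == 0) & (loads["dose_cfu"] > 0)]
    live_tab = (live.assign(uninf=(live["below_detection"] == 1).astype(int))
                .groupby(["species", "dose_cfu"])
                .agg(live_uninfected=("uninf", "sum"),
                     live_total=("uninf", "size")).reset_index())
    live_tab["live_infected"] = live_tab["live_total"] - live_tab["live_uninfected"]
    dead_tab = (dead.assign(uninf=(dead["infected_at_death"] == 0).astype(int))
                .groupby(["species", "dose_cfu"])
                .agg(dead_uninfected=("uninf", "sum"),
                     dead_total=("uninf", "size")).reset_index())
    dead_tab["dead_infected"] = dead_tab["dead_total"] - dead_tab["dead_uninfected"]
    out = live_tab.merge(dead_tab, on=["species", "dose_cfu"], how="inner")
    return out.drop(columns=["live_total", "dead_total"])


def fit_live_dead_concordance(counts: pd.DataFrame) -> GlmReport:
    """Dead-fly clearance vs live-fly clearance: overdispersed binomial fit.

    The response is the (uninfected, infected) count pair of dead flies per
    species x dose cell; the predictor is the live-fly uninfected proportion.
    The dispersion is estimated as Pearson X^2 / df (quasibinomial) and Wald
    tests are scaled accordingly.
    """
    d = counts.copy()
    if len(d) < 3:
        raise ValueError("need >= 3 species x dose cells")
    d["live_prop"] = d["live_uninfected"] / (
        d["live_uninfected"] + d["live_infected"])
    if np.ptp(d["live_prop"].to_numpy()) == 0:
        raise ValueError("degenerate predictor: live proportion is constant")
    endog = d[["dead_uninfected", "dead_infected"]].to_numpy()
    exog = sm.add_constant(d["live_prop"].to_numpy())
    res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    # quasibinomial dispersion: Pearson X^2 on the count scale / df
    trials = endog.sum(axis=1)
    mu = res.fittedvalues
    x2 = float(np.sum(trials * (endog[:, 0] / trials - mu) ** 2
                      / (mu * (1 - mu))))
    dispersion = x2 / res.df_resid
    params = pd.Series(res.params, index=["intercept", "live_prop"])
    bse = pd.Series(res.bse * np.sqrt(dispersion), index=params.index)
    tvals = params / bse
    pvals = pd.Series(
        2 * sps.t.sf(np.abs(tvals.to_numpy()), res.df_resid),
        index=params.index)
    return GlmReport("live_dead_concordance", params, bse, pvals,
                     int(res.nobs), dispersion=dispersion,
                     deviance=float(res.deviance), result=res)
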