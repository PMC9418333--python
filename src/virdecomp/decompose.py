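"""Virulence decomposition: species virulence, exploitation and PPP.

Virulence (log maximum hazard) is decomposed into two pathogen components:

* **exploitation** -- infection intensity, operationalised as the geometric
  mean bacterial load over days 1-2 post injection (+1 offset so that cleared
  flies can be included);
* **per-parasite pathogenicity (PPP)** -- damage per unit load,
  operationalised as the species-specific slope of log maximum hazard on log
  exploitation (the species x load interaction).

Three linear models:

* virulence model:     log(h_max) ~ species                      (bacterial arms)
* PPP model:           log(h_max) ~ log(exploitation) x species  (+ Ringer's
  controls entering at exploitation = 1, i.e. the uninfected intercept)
* exploitation model:  log(exploitation) ~ species               (bacterial arms)

ANOVA tables use type-II sums of squares by default (switchable); pairwise
comparisons of level means or species slopes are Tukey-adjusted via the
studentized range, with Cohen's d = adjusted difference / residual sigma.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import studentized_range, t as t_dist
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "DecompositionFit",
    "geometric_mean_load",
    "exploitation_by_arm",
    "replicate_summaries",
    "apply_decomposition_filters",
    "fit_linear_anova",
    "fit_virulence_model",
    "fit_exploitation_model",
    "fit_ppp_model",
]


@dataclass
class DecompositionFit:
    """A fitted decomposition model with ANOVA table and adjusted contrasts."""

    model_id: str
    params: pd.Series
    bse: pd.Series
    anova_table: pd.DataFrame
    contrasts: pd.DataFrame
    sigma: float
    n_used: int
    species_slopes: pd.Series | None = None
    exclusions: list = field(default_factory=list)
    result: object = None  # underlying statsmodels results


def geometric_mean_load(loads) -> float:
    """Geometric mean of CFU loads with a +1 offset: exp(mean(log(load + 1))).

    The offset keeps flies with zero (cleared / below-detection) load in the
    mean; an all-zero arm therefore has exploitation 1 (log exploitation 0).
    """
    arr = np.asarray(loads, float)
    if arr.size == 0:
        raise ValueError("no load values: exploitation undefined")
    if (arr < 0).any():
        raise ValueError("loads must be nonnegative")
    return float(np.exp(np.mean(np.log1p(arr))))


def exploitation_by_arm(loads: pd.DataFrame, days=(1, 2)) -> pd.DataFrame:
    """Per (species, dose, replicate): geometric-mean load over early days.

    Contaminated records are excluded; ``n_load_day1`` counts usable day-1
    records (arms without any feed the no-day-1-data exclusion rule).
    """
    ok = loads[loads["contaminated"] == 0]
    rows = []
    for (species, dose, rep), grp in ok.groupby(
            ["species", "dose_cfu", "replicate"], sort=True):
        early = grp[grp["day_sampled"].isin(days)]
        n_day1 = int((grp["day_sampled"] == days[0]).sum())
        expl = (geometric_mean_load(early["load_cfu"])
                if len(early) else np.nan)
        rows.append((species, dose, rep, expl, len(early), n_day1))
    return pd.DataFrame(rows, columns=[
        "species", "dose_cfu", "replicate", "exploitation", "n_load", "n_load_day1"])


def replicate_summaries(hazards: pd.DataFrame,
                        loads: pd.DataFrame) -> pd.DataFrame:
    """Join per-arm maximum hazards with per-arm exploitation.

    ``hazards`` is the output of
    :func:`virdecomp.hazard.max_hazard_by_replicate`; control arms keep
    exploitation 1 (uninfected flies; log exploitation 0).
    """
    expl = exploitation_by_arm(loads)
    out = hazards.merge(expl, on=["species", "dose_cfu", "replicate"],
                        how="left")
    controls = out["treatment"] != "bacterial"
    out.loc[controls, "exploitation"] = 1.0
    out.loc[controls, ["n_load", "n_load_day1"]] = (
        out.loc[controls, ["n_load", "n_load_day1"]].fillna(0))
    return out


def apply_decomposition_filters(
        summaries: pd.DataFrame,
        hazard_meta: pd.DataFrame | None = None,
        exclude_species: tuple[str, ...] = ("Ps_entomophila",),
        require_day1: bool = True):
    """Apply the replicate-exclusion rules; returns (retained, report).

    Rules (order-independent, every removal carries a reason code):

    a. ``no-mortality-in-window`` -- h_max could not be estimated;
    b. ``max-hazard-before-day-1`` -- t_at_max < 1 day for *every* bandwidth
       in ``hazard_meta`` (columns species, treatment, dose_cfu, replicate,
       bandwidth_b, t_at_max); load sampling then happens after the hazard
       peak, so causal ordering is lost;
    c. ``no-day1-load-data`` -- a bacterial arm without usable day-1 loads;
    d. ``hazard-at-sampling-time`` -- species whose peak hazard coincides with
       the first load sampling (default *Ps. entomophila*), excluded entirely.
    """
    reasons: dict[int, list[str]] = {}

    def flag(mask, reason):
        for idx in summaries.index[mask]:
            reasons.setdefault(idx, []).append(reason)

    flag(summaries["h_max"].isna(), "no-mortality-in-window")
    if hazard_meta is not None and len(hazard_meta):
        keys = ["species", "treatment", "dose_cfu", "replicate"]
        all_early = (hazard_meta.assign(early=hazard_meta["t_at_max"] < 1.0)
                     .groupby(keys)["early"].all())
        early_arms = set(all_early.index[all_early])
        mask = summaries.set_index(keys).index.isin(early_arms)
        flag(pd.Series(mask, index=summaries.index), "max-hazard-before-day-1")
    if require_day1:
        bacterial = summaries["treatment"] == "bacterial"
        flag(bacterial & (summaries["n_load_day1"].fillna(0) == 0),
             "no-day1-load-data")
    flag(summaries["species"].isin(exclude_species), "hazard-at-sampling-time")

    report = [(summaries.loc[i, "species"], summaries.loc[i, "dose_cfu"],
               summaries.loc[i, "replicate"], ";".join(r))
              for i, r in sorted(reasons.items())]
    retained = summaries.drop(index=list(reasons)).copy()
    return retained, report


def _check_design(result, data_n: int):
    exog = result.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # identify an aliased column by pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(exog, pivoting=True)
        aliased = [result.model.exog_names[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")


def _tukey_contrasts(names, L, result, sigma):
    """Pairwise Tukey-adjusted contrasts of the linear combinations ``L``."""
    est = L @ result.params.to_numpy()
    cov = L @ result.cov_params().to_numpy() @ L.T
    df_resid = result.df_resid
    k = len(names)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = est[i] - est[j]
        se = float(np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j]))
        tval = diff / se
        p_raw = 2 * float(t_dist.sf(abs(tval), df_resid))
        p_adj = float(studentized_range.sf(abs(tval) * np.sqrt(2), k, df_resid))
        rows.append((f"{names[i]} - {names[j]}", diff, se, tval,
                     p_raw, min(1.0, max(p_adj, p_raw)), diff / sigma))
    return pd.DataFrame(rows, columns=[
        "contrast", "estimate", "se", "t", "p_raw", "p_tukey", "cohens_d"])


def fit_linear_anova(data: pd.DataFrame, response: str, factor: str,
                     covariate: str | None = None, interaction: bool = False,
                     anova_type: int = 2, model_id: str = "",
                     contrast_on: str = "means") -> DecompositionFit:
    """Least-squares fit with type-II ANOVA and Tukey-adjusted contrasts.

    ``contrast_on`` selects what is compared pairwise across factor levels:
    adjusted level means (``"means"``) or per-level covariate slopes
    (``"slopes"``, requires ``interaction=True``).
    """
    levels = sorted(data[factor].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    terms = [f"C({factor})"]
    if covariate is not None:
        terms = ([f"{covariate} * C({factor})"] if interaction
                 else [covariate, f"C({factor})"])
    formula = f"{response} ~ " + " + ".join(terms)
    result = smf.ols(formula, data=data).fit()
    _check_design(result, len(data))
    anova = sm.stats.anova_lm(result, typ=anova_type)
    sigma = float(np.sqrt(result.mse_resid))
    pnames = list(result.params.index)

    def basis(level, kind):
        row = np.zeros(len(pnames))
        for idx, name in enumerate(pnames):
            if kind == "mean":
                if name == "Intercept" or name == f"C({factor})[T.{level}]":
                    row[idx] = 1.0
            else:  # slope of the covariate for this level
                if name == covariate or name == f"{covariate}:C({factor})[T.{level}]":
                    row[idx] = 1.0
        return row

    kind = "slope" if contrast_on == "slopes" else "mean"
    L = np.array([basis(lv, kind) for lv in levels])
    contrasts = _tukey_contrasts(levels, L, result, sigma)
    slopes = None
    if kind == "slope":
        slopes = pd.Series(L @ result.params.to_numpy(), index=levels,
                           name="slope")
    return DecompositionFit(
        model_id=model_id, params=result.params, bse=result.bse,
        anova_table=anova, contrasts=contrasts, sigma=sigma,
        n_used=int(result.nobs), species_slopes=slopes, result=result)


def fit_virulence_model(summaries: pd.DataFrame,
                        anova_type: int = 2) -> DecompositionFit:
    """Virulence differences: log(h_max) ~ species, bacterial arms only."""
    d = summaries[(summaries["treatment"] == "bacterial")
                  & summaries["h_max"].notna()].copy()
    d["log_hmax"] = np.log(d["h_max"])
    return fit_linear_anova(d, "log_hmax", "species", anova_type=anova_type,
                            model_id="virulence")


def fit_exploitation_model(summaries: pd.DataFrame,
                           anova_type: int = 2) -> DecompositionFit:
    """Exploitation differences: log(exploitation) ~ species, bacterial arms."""
    d = summaries[(summaries["treatment"] == "bacterial")
                  & summaries["exploitation"].notna()].copy()
    d["log_expl"] = np.log(d["exploitation"])
    return fit_linear_anova(d, "log_expl", "species", anova_type=anova_type,
                            model_id="exploitation")


def fit_ppp_model(summaries: pd.DataFrame,
                  anova_type: int = 2) -> DecompositionFit:
    """PPP reaction norms: log(h_max) ~ log(exploitation) x species.

    Ringer's control arms enter with exploitation 1 (log 0), anchoring the
    uninfected intercept; the per-species slopes are the PPP estimates and the
    interaction F test measures PPP variation across species.
    """
    d = summaries[summaries["h_max"].notna()
                  & summaries["exploitation"].notna()
                  & summaries["treatment"].isin(["bacterial", "ringer"])].copy()
    d["log_hmax"] = np.log(d["h_max"])
    d["log_expl"] = np.log(d["exploitation"])
    return fit_linear_anova(d, "log_hmax", "species", covariate="log_expl",
                            interaction=True, anova_type=anova_type,
                            model_id="ppp", contrast_on="slopes")
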