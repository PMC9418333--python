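# virdecomp

Virulence decomposition and bacterial clearance analysis for persistent
infections in insect hosts.

After a systemic bacterial infection a host may die, carry a persistent
infection, or clear it. This package implements a complete analysis pipeline
for dose–response injection experiments (the motivating system is
*Drosophila melanogaster* injected with bacteria spanning a wide virulence
range) that connects those outcomes:

* **Virulence** is measured per species × dose × replicate arm as the
  maximum hazard `h_max`: the peak of a boundary-corrected Epanechnikov
  kernel estimate of the mortality hazard,
  `ĥ(t) = Σ_i K_b(t − t_i)·d_i/Y(t_i)`, in a 0–20 day window.
* **Decomposition.** Virulence is split into pathogen *exploitation*
  (infection intensity: the geometric mean CFU load on days 1–2 post
  injection, +1 offset) and *per-parasite pathogenicity* (PPP: the
  species-specific slope of `log h_max` on log exploitation, i.e. the
  species × load interaction of `log(h_max) ~ log(exploitation) × species`),
  with type-II ANOVA, Tukey-adjusted contrasts and Cohen's d.
* **Clearance.** A fly is cleared when no colony grows from any plated
  droplet (≈7 CFU detection limit). The clearance index of an arm over a day
  set D is `mean_{d∈D}[ P(cleared | alive, d) × P(alive, d) ]` — the
  estimated fraction of the initial population that cleared. Species are
  compared by Kruskal–Wallis with exact pairwise Mann–Whitney post hocs and
  Benjamini–Hochberg correction; dose→day-7 load, dead-fly infection status
  and live/dead concordance have their own linear, logistic and
  quasibinomial models.
* **Inference.** Clearance indices are regressed on log exploitation and PPP
  with a logit-link Gaussian model: `y ~ N(logistic(Xβ + u_s), exp(Wγ))`,
  `u_s ~ N(0, τ²)` — a modelled heteroscedastic variance and a species
  random intercept, fitted by maximum likelihood with adaptive Gauss–Hermite
  quadrature. A negative exploitation coefficient is the signature of
  load-dependent clearance interference (hypothesis H3 / prediction P3).
* **Effort model.** A static optimality model of host clearance effort:
  `S(c) = exp(−PE/r(c))·exp(−γc²)` with `r(c) = r0·c/(1+κE)`, closed-form
  optimum `c* = (PE(1+κE)/(2γr0))^{1/3}`, reproducing the qualitative
  predictions P1–P3 and locating the κE = 1 threshold where higher
  exploitation starts lowering the optimal clearance rate.
* **Synthetic data.** A generator simulates the full design (4 species × 5
  doses × 3 replicates; 36-fly survival cohorts; 4 homogenised flies per arm
  per sampling day; detection-limit and max-count censoring) from an
  explicit within-host model, so everything above runs end-to-end without
  any download. See `docs/methods.md` for the model and its limitations.

## Worked example

```python
import virdecomp as vd

res = vd.run_study(vd.SimulationConfig(seed=1))

res["ppp"].species_slopes.round(3)
# E_cloacae              0.026
# L_lactis               0.483
# Pr_burhodogranariea    0.357
# interaction F = 15.83, p = 5.3e-06

res["clearance_fit"].beta.round(3)
# beta0                 0.936
# beta_exploitation    -0.656
# beta_ppp             -3.442
```

The reaction-norm slopes are the PPP estimates: *E. cloacae* is nearly flat
(little damage per unit load) while the two high-virulence species have
similar, steep slopes — the significant interaction says PPP varies across
species. In the clearance fit, the negative `beta_exploitation` (−0.66 on
the logit scale per log load unit, n = 43 arms) means arms with higher early
loads cleared less later in the infection — the load-interference signature.

The `examples/` directory walks through each capability: simulation, hazard
estimation, decomposition, clearance indices, clearance inference and the
effort model. Each script prints its numbers with a line on what they mean.

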