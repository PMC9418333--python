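# Methods

`virdecomp` analyses persistent bacterial infections in an insect host the
way a dose-response injection experiment is analysed: per-arm virulence from
time-of-death data, a decomposition of virulence into pathogen exploitation
and per-parasite pathogenicity (PPP), clearance indices that estimate the
fraction of the initial population that cleared its infection, a mixed model
relating clearance to the virulence components, and a static optimality model
of host clearance effort. A synthetic-data generator supplies experiments
with the same design and statistical structure, so every stage is testable
without external data.

## Virulence: the windowed maximum hazard

Virulence is the maximum of a smoothed mortality-hazard curve in a fixed
window (default 0–20 days post injection), estimated per species × dose ×
replicate arm from the ~36-fly survival cohort. The estimator smooths the
Nelson–Aalen increments,

    h(t) = Σ_i K_b(t − t_i) · d_i / Y(t_i),

with an Epanechnikov kernel of global half-width `b` (default 2 days;
1, 3 and 5 available) replaced by Müller–Wang boundary kernels within `b` of
a window edge; negative boundary-kernel artefacts are clipped at zero. The
grid has 401 points by default; halving the step changes `h_max` by <1% on
smooth inputs. Arms with no death inside the window have no estimate and are
carried with an explicit exclusion reason rather than dropped. Risk sets
count the survival cohort only — homogenised flies are a separate,
destructively sampled cohort.

A property worth knowing: the maximum of a noisy curve is positively biased,
and the relative bias grows as in-window deaths get sparse. With ~36 flies
the estimate is useful when mortality is concentrated (a structural hazard
peak) and unreliable as a point estimate when only 1–3 deaths occur; the
per-arm log maximum hazard then carries substantial noise. The analysis
models absorb this as residual variance.

## Decomposition: exploitation and PPP

Exploitation is the geometric mean bacterial load over days 1–2 post
injection with a +1 offset (`exp(mean(log(load+1)))`), so cleared flies
contribute and an all-clear arm has log exploitation 0. PPP is the
species-specific slope of log maximum hazard on log exploitation — the
reaction norm of damage against load. Three least-squares models:

* `log(h_max) ~ species` (virulence differences; all species),
* `log(h_max) ~ log(exploitation) × species` (reaction norms; Ringer's
  control arms enter at exploitation 1 and anchor the uninfected intercept),
* `log(exploitation) ~ species` (exploitation differences).

ANOVA tables use type-II sums of squares (switchable to I/III); pairwise
comparisons of level means or slopes are adjusted with the studentized range
(Tukey) and reported with Cohen's d = difference / residual σ. Replicate
exclusion rules are independent and order-free: no mortality in the window;
peak before day 1 at *every* bandwidth (load sampling would then postdate the
peak, destroying the causal ordering); no day-1 load data; and a
species-level exclusion (default the hyper-virulent species, whose peak
coincides with the first sampling day).

End-to-end, fitted PPP slopes are mildly attenuated (≈0.05–0.1 for true
slopes of 0.5 at study scale) because arm exploitation is itself an estimate
(eight flies) and extreme loads are censored at the highest countable value;
both mechanisms exist in the real assay as well. Slope *ordering* and
contrast detection are unaffected at the study's scale, which is what the
recovery experiments assert.

## Clearance indices and their models

A homogenised fly counts as cleared when its load is below the plating
detection limit (homogenate volume / plated volume ≈ 7 CFU for 100 µL and
three 5 µL droplets); back-calculation takes the droplet mean at the lowest
countable dilution (target 10–60 colonies/droplet) times the dilution and
volume factors, with all-overgrown plates signalling max-count censoring.

The clearance index of an arm over a day set D (either {3,4} or {7,14,21})
averages `P(cleared | alive at d) × P(alive at d)` over d ∈ D, using the
survival cohort of the same arm for the alive proportion. Days with no live
sampled flies are dropped from the mean (not imputed as zero) and reported;
an arm with no usable day is undefined and excluded downstream with a
reason.

Species are compared on the day-3/4 index with a Kruskal–Wallis test
(chi-square approximation, tie-corrected) and pairwise Mann–Whitney-U post
hocs, Benjamini–Hochberg corrected. Mann–Whitney is an exact tie-aware
permutation enumeration for combined n ≤ 12 and the tie-corrected normal
approximation otherwise. Dose→day-7 load is an OLS fit per species on the
log (or iterated-log) scale, after removing below-detection flies.
Dead-fly infection status is a binomial logistic regression on
log(log(dose)) × log(day); complete separation is detected and raised, never
silently returned. Live/dead concordance is a quasibinomial fit whose
dispersion is the count-scale Pearson X²/df (computed directly — the
underlying GLM library's built-in `X2` scale uses proportion-scale residuals
for two-column outcomes, which is not the quasibinomial convention) with
t-referenced Wald tests.

## Clearance inference: heteroscedastic logit-mean mixed model

The clearance index is modelled on its raw [0,1] scale with a logistic mean
and Gaussian errors — appropriate because many indices sit at or near zero,
where a transform-and-regress approach breaks:

    y_i ~ N( logistic(β0 + β_E·logE_i + β_P·PPP_s(i) + u_s), exp(w_i'γ) ),
    u_s ~ N(0, τ²),

with the log error variance linear in the same two predictors (dispersion
submodel) and a species random intercept (PPP is already a species-level
covariate, so species cannot also be a fixed effect). PPP enters as the
point estimate from the reaction-norm model; its estimation uncertainty is
not propagated. The marginal likelihood integrates `u_s` per species by
adaptive Gauss–Hermite quadrature: a grid+Newton mode search, curvature
scaling, 15 nodes, with a direct evaluation when τ < 1e-6. Optimisation is
multi-start L-BFGS-B (default 5 jittered starts from moment-based values,
fixed start-RNG); τ at its lower bound is reported as a boundary fit.

Wald inference uses a small-sample correction chosen before the calibration
experiment was frozen: the inverse-Hessian covariance is inflated by
n/(n−p) (ML variance bias) and referenced against t with n−p df. At the
study scale this puts both coefficients' type-I error inside the binomial
95 % band at 400 simulations when τ is small. With only three species the
species-level coefficient remains fragile: for τ ≳ 0.5 its Wald test turns
anti-conservative (measured ≈0.13) — the few-random-levels problem. The
power machinery therefore demonstrates the exploitation-vs-PPP power
asymmetry at equal coefficients on the predictors' natural scales, where it
is robust (≈0.9 vs ≈0.05).

## Effort optimality model

Host clearance effort c buys clearance rate `r(c) = r0·c` (divided by
`1 + κE` under the load-interference hypothesis H3) at quadratic survival
cost; survival is `S(c) = exp(−PE/r(c))·exp(−γc²)` — harm accrues at rate
P·E for the expected infection duration 1/r. These are the simplest forms
satisfying the framework's qualitative statements (linear benefit, convex
cost, divisive coupling); all three shapes are injectable. The interior
optimum is `c* = (PE(1+κE)/(2γr0))^{1/3}`, used as the analytic oracle for
the bounded scalar optimiser (agreement 1e-6 relative). Since
`r(c*) ∝ E^{1/3}(1+κE)^{−2/3}`, the clearance rate at optimum declines in
exploitation exactly where κE > 1; the prediction report locates this
threshold numerically and classifies the monotonicity signs that constitute
predictions P1–P3. The default H3 sweep uses κ = 8 so the whole default grid
sits in the declining regime.

## The synthetic-data generator

The generator reproduces the design — 4 species × 5 doses
(92–92,000 CFU) × 3 replicates, 36-fly survival cohorts per arm (7 arms per
species block: 5 doses + Ringer's + naive), 4 homogenised flies per arm per
sampling day {1,2,3,4,7,14,21,28,35}, daily checks, right-censoring at a
78-day horizon — and a within-host model in discrete daily steps:

* log load rises at `growth_rate` from log(dose) and saturates at a
  dose-dependent set point, `log SPBL = scale + exp·log(dose)`, with a
  per-fly lognormal offset (SD 0.4);
* clearance is absorbing with daily probability
  `clear_base·exp(−clear_load_coef·logL − clear_decay·(post-acute days))`:
  higher loads are harder to clear (the H3 mechanism) and established
  set-point infections are rarely cleared;
* infected flies die with daily probability
  `exp(base + ppp·logL − acute_decay·(post-acute days))` — mortality peaks
  during the acute phase and wanes once the infection is controlled, making
  the maximum hazard a structural peak of height `exp(base + ppp·log SPBL)`;
* uninfected and cleared flies face an injection-trauma baseline
  `exp(base)·(t/3)e^{1−t/3}` peaking at day 3 (so control arms have an
  estimable maximum, the reaction norm's intercept), plus — like everyone —
  a Gompertz aging hazard that dominates from ~day 40 and closes the cohort
  by the horizon.

Observation layer: loads below 7 CFU are recorded as zero with a
below-detection flag (clearance is operationally indistinguishable from
sub-detection persistence, as in the real assay); loads above a species'
highest countable value are censored at that maximum; ~2 % of homogenates
are flagged contaminated and excluded by every analysis. Seeding derives an
independent stream per arm from a stable hash of (species, treatment, dose,
replicate, cohort), so arms are independent and one species' parameters
never perturb another's tables.

Species presets are illustrative, tuned only to the qualitative orderings
the study reports (lowest exploitation/PPP and most clearance for
*E. cloacae*; persistent loads of tens-to-hundreds vs thousands of CFU;
extreme early virulence for *Ps. entomophila*) and to the structural
requirements above (enough in-window deaths per arm that the maximum hazard
is estimable, since the max-statistic bias of sparse-death arms would
otherwise distort the reaction norms). They are not fitted to the deposited
dataset. What passing tests show is therefore that the *pipeline* recovers
the generator's known structure at the study's scale — slope orderings,
contrast detection, the negative exploitation→clearance coefficient — not
that the presets match any particular species' biology. Features of real
data the generator does not emulate: between-replicate variance components
(none are reported to calibrate against), block/person effects on outcomes
(person is recorded but has no effect), within-fly load dynamics beyond the
saturating trajectory, and any immune-effector mechanism.

## Problem sizes and numerical choices

Recovery experiments run at the study's own scale: 100 simulated experiments
for the slope-ordering and contrast-detection rates, 200 for the
exploitation-sign rate, 400 model-level simulations for the type-I
calibration, 200 for the coefficient-recovery check — sizes chosen to give
Monte-Carlo standard errors of a few percent on the reported rates. Exact
Mann–Whitney enumeration is capped at combined n = 12 (924 assignments).
Ties in the ANOVA contrasts break by sorted level order; hazard-curve ties
break toward the earliest grid time. Degenerate inputs (empty cells,
single-class outcomes, constant predictors, rank-deficient designs) raise
typed errors naming the problem instead of returning silent results.

## Known limitations

* The kernel hazard estimator replicates the published smoother's *family*
  (boundary-corrected Epanechnikov, global bandwidth), not its exact grid or
  boundary-variant choices; agreement is asserted at the level of
  qualitative orderings across bandwidths.
* PPP propagates into the clearance model as a known constant; its
  estimation error is ignored (as in the original analysis).
* With three species, τ and the species-level coefficient are weakly
  identified; boundary fits are flagged and species-level Wald tests should
  be read cautiously.
* Interval censoring from daily checks is treated as exact death days.
* The effort model is a static optimality argument, not an evolutionary or
  dynamical model, and no claim is made that its functional forms match any
  unpublished supplementary formulation.
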