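# Methods

`bemipop` implements a physiologically based, stage-structured cohort model
of the cassava whitefly *Bemisia tabaci*, together with (i) an assimilation
step that estimates the initial cohort sizes and initial physiological ages
from field monitoring counts by differential evolution, and (ii) a
back-casting step that inverts the forward ageing process to date the first
oviposition — the likely field-invasion date. This note records the model,
its assumptions, the numerical choices, and what the synthetic study
conditions do and do not show.

## Population model

The population is a set of cohorts, each a same-aged group within one life
stage: egg, nymph, 'pupa' (the final intermediate stage of this
hemimetabolous insect, labelled 'pupa' by convention), reproductive adult
and post-reproductive adult. Cohort sizes are continuous densities, not
integers, because daily survival acts multiplicatively.

**Development.** Each immature stage i accumulates physiological age

    Q_i(n) = r0_i + sum_{day=1..n} r_i(T_day) * dt,    dt = 1 day,

where r_i(T) is the temperature-dependent development rate (day⁻¹) and
r0_i the age already accumulated at the first monitoring date t₁. Age
advances only when the daily mean temperature lies inside the stage's
permissive range (TL_i, TU_i); at Q = 1 the whole surviving cohort moves to
the next stage at age 0.

**Survival.** Daily immature survival is S_i = (1 − m_i(T))^{r_i(T)}, with
m_i(T) the temperature-dependent mortality rate; raising to the day's
development fraction weights mortality by developmental progress, so a day
of zero development costs nothing. At or beyond the lethal limits
(LLT = 4 °C, ULT = 36 °C) survival is 0. A multiplicative reading
S = (1 − m)·r is available as the `survival_mode: product` config switch.
Adults carry no background temperature mortality; they die only through
completed senescence (a lethal-limit kill switch for adults exists and is
off by default).

**Reproduction.** Reproductive adults lay one aggregate daily egg cohort of
size f = SR·φ(T)·ψ(T)·N_A, with sex ratio SR = 0.5, daily oviposition
fraction φ(T) (zero outside 4–36 °C), lifetime capacity ψ(T) (eggs per
female) and N_A the total reproductive adults. A cohort's fecund period
ends when ∫φ dt reaches 1; it then becomes post-reproductive and dies when
the senescence integral ∫s(T) dt reaches 1. The first senescence increment
lands on the day the cohort turns post-reproductive (the accumulators
advance in one pass per day).

**Crowding and host crop.** Nymph survival is additionally multiplied by
the density-dependent factor sD = 1/(1 + K·Nn) (Nn = total nymphs at the
day's start; K ≥ 0 the crowding strength, estimated from data) and by crop
suitability CS(t) ∈ [0, 1], a non-increasing function of crop age. The
simulation's day 0 is the first monitoring date, which follows planting by
`planting_offset` days (default 17, ≈ two and a half weeks).

**Daily operation order** (fixed; the literature leaves it open): survival →
ageing → transitions → reproduction → adult accumulators → removal of
cohorts below the extinction threshold ε = 10⁻⁶. Rationale: mortality acts
on the population present at the day's start, and eggs laid today cannot
age today. Age overshoot above 1 at a transition is discarded — with a
1-day step, carrying it would imply sub-daily knowledge the input lacks.

## Rate functions

The exact functional forms and calibrated thermal parameters for the
SSA-ESA cassava biotype are not redistributable here, so the package ships
literature-standard shapes behind a named registry
(`bemipop.register_rate_form`), swappable per config without touching the
engine:

| response | default form | default parameters |
|---|---|---|
| development r_i(T) | Brière-1: a·T·(T−TL)·√(TU−T) | TL = 10, TU = 35 °C; a set for ≈7/13/6-day egg/nymph/'pupa' durations at 26 °C |
| mortality m_i(T) | quadratic bowl, clipped to [0,1] | minimum 0.02 at 27 °C, curvature 0.001 |
| oviposition φ(T) | Brière-1 on the 4–36 °C range | ≈12-day fecund period at 26 °C |
| capacity ψ(T) | Gaussian | peak 160 eggs/female at 27 °C, σ = 6 °C |
| senescence s(T) | linear max(0, a + bT) | ≈10-day post-reproductive life at 26 °C |
| crop suitability CS(t) | 1/(1+(t/t_half)^h) | t_half = 90 d, h = 4 |

These defaults are placeholders producing realistic tropical dynamics; they
are **not** lab-calibrated, and no test treats them as ground truth — the
synthetic scenarios state their parameters explicitly. The CS form is a
logistic in log-time chosen so that CS(0) = 1 and CS(t_half) = 1/2 hold
exactly while remaining monotone on [0, ∞).

## Estimation

The decision vector in `free_age` mode is
(size_egg, size_nymph, size_pupa, r0_egg, r0_nymph, r0_pupa, K) with
bounds sizes ∈ [0, 10⁶], r0 ∈ [0, 0.99], K ∈ [10⁻⁵, 10²]; `zero_age` mode
pins the three ages at 0 (the conventional no-thermal-history assumption)
and searches 4 dimensions. The objective is the pooled, unweighted residual
sum of squares RSS = Σ_k (O_k − S_k)² over all Ω monitoring records, each
matched to the simulated total of its stage on its exact calendar date
(adult records match reproductive + post-reproductive adults; no
interpolation — an observation outside the simulated horizon is an error).
Per-stage weights are exposed in config but default to 1.

The optimiser is classic DE/rand/1/bin: uniform initialisation in the box,
mutant v = x_r1 + F·(x_r2 − x_r3) with distinct partners, binomial
crossover with one guaranteed mutant coordinate, clipping to the box, and
greedy selection (hence a monotone best-RSS trace). Defaults are the
canonical Storn–Price settings NP = 10×dimension, F = 0.8, CR = 0.9, with a
stop when the best RSS improves by < 10⁻⁸ (relative) over 50 generations or
at 500 generations. An optional seeded initial population supports nesting
experiments (embedding the zero-age optimum into the free-age start
population makes the nesting inequality exact under greedy selection).
Everything is reproducible from the settings seed.

Because the per-day thermal responses do not depend on the decision vector,
the fitting objective precomputes them once per dataset; the engine's daily
loop then runs on preallocated arrays. This fast path is asserted
bit-identical to the reference single-day update in the test suite.

## Back-casting

Starting from the estimated age q = r0 at t₁, step backwards one day at a
time subtracting r(T_d) (zero on days outside the permissive range); the
first day whose subtraction drives q to ≤ 0 is the origin t₀, with ties
resolving to that day. For cohorts beyond the egg stage the inversion
chains through each earlier stage's full development (age 1 → 0), ending at
egg age 0 = the first oviposition. The anchor is the developmentally oldest
non-empty cohort ('pupa' before nymph before egg) — the pioneer cohort is
the most advanced one at t₁. If the temperature record is exhausted first,
the result carries the unexplained residual age and a flag instead of
raising. The round-trip guarantee is discrete: forward accumulation from t₀
recovers r0 within one day's maximum rate increment.

## Evaluation

Observed counts are regressed on simulated totals by OLS; the report gives
slope and intercept with 95% CIs, R², the regression F-test p-value, and a
Gaussian AIC n·ln(RSS_reg/n) + 2p with p = 3 (slope, intercept, variance).
The AIC omits the additive normalisation constant, so it ranks fits within
this package only. A fit is flagged consistent with the 1:1 line when the
intercept CI covers 0 and the slope CI covers 1.

## Synthetic study conditions

The generator emulates a lowland West-African cassava trial: 150 monitored
days of tropical weather (sinusoidal annual cycle, mean 26 °C, amplitude
2 °C, daily Gaussian noise 1 °C, clipped to [−10, 50] °C) with a 40-day
pre-history for back-casting; adults observed twice weekly (3/4-day
alternation) from the first monitoring day, nymphs weekly from 18 days
later (≈ five weeks after planting); observation noise none, Poisson
(default choice for visual counts) or negative-binomial. The reference
truth is a single egg cohort of 50 at age 0.5 with K = 0.01. Because the
generator fixes r0_egg as a primitive, its "true" oviposition date is
defined by inverting the ageing process under the true parameters and
temperatures; the round-trip acceptance check therefore isolates the error
introduced by fitting.

What passing these conditions does not show: real trap counts are
per-plant subsamples on an unknown scale relative to absolute density, adult
counts are biased by flight during sampling, and rain/humidity and natural
enemies add mortality the model omits — so recovery on synthetic data
bounds methodological error only, not field accuracy.

## Numerical choices

- Completion tolerance 10⁻⁹ on the age/fecundity/senescence accumulators
  and the backward deficit: sums of daily increments meant to reach exactly
  1 (e.g. 10 × 0.1) miss by float rounding; the tolerance restores the
  exact discrete arithmetic (ceil((1−r0)/r) completion days, ceil(q/r)
  backward days).
- Extinction threshold 10⁻⁶ individuals for cohort removal.
- DE boundary handling by clipping (simplest scheme preserving
  feasibility); K is searched on its natural scale within [10⁻⁵, 10²].
- Degenerate inputs: TL ≥ TU, negative counts/sizes, ages outside
  [0, 0.99], gapped temperature series, unknown stage labels and non-finite
  temperatures are hard validation errors; a perfect regression guards the
  AIC log with the smallest positive float.
- Problem sizes: the default tests and the acceptance script fit the
  150-day scenario (62 observations, 7- and 4-dimensional searches, DE
  budget 400 generations with early stopping) and check inversion on 100
  random 140-day weather series — sizes at which the whole pipeline's
  behaviour is exercised end to end while each full run stays in the
  low minutes on a single core.

## Known limitations

- No immigration after day 0, no spatial structure, no diapause.
- No abiotic (rain, humidity) or biotic (predation, parasitism, disease)
  mortality beyond the phenomenological density dependence.
- Whether the field "adult" count corresponds to all adults or only
  reproductive ones is unknowable from count data; the model assumes all.
- The shipped thermal parameters are placeholders; conclusions about real
  populations require calibrated rate functions dropped into the registry.
- t₀ is a point estimate; no uncertainty interval is propagated from the
  DE fit (a bootstrap over replicate fits would be the natural extension).
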