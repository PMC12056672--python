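# bemipop

Temperature-driven population dynamics of the cassava whitefly *Bemisia
tabaci*, with monitoring-data assimilation and invasion-date back-casting.

Whiteflies transmit the cassava mosaic and brown streak viruses, and their
development, survival and fecundity are strongly temperature-dependent.
Physiologically based models can forecast their stage-structured dynamics
from weather data — but a simulation is only as good as its initial
conditions, and field monitoring rarely reveals how many immatures were
already present, or how far developed they were, when the first trap visit
happened. `bemipop` addresses exactly that: it fuses a mechanistic cohort
model with trap-count time series to estimate the size **and physiological
age** of the founding cohorts, and then runs the ageing process backwards
through the temperature record to date the first oviposition — the likely
day the field was invaded.

The package is for quantitative entomologists and pest-risk modellers: the
engine, estimator and back-caster are library functions, and a `bemipop`
command-line tool orchestrates the workflow on CSV inputs.

## Model in brief

Cohorts (same-aged groups per stage: egg, nymph, 'pupa', adult) accumulate
physiological age Q = r0 + Σ r(T_day)·Δt with a stage-specific
temperature-dependent development rate r(T), zero outside the permissive
range (TL, TU); transition occurs at Q = 1. Daily immature survival is
S = (1 − m(T))^{r(T)}, zero at or beyond the lethal limits 4 and 36 °C;
nymphs are further thinned by crowding sD = 1/(1 + K·Nn) and declining crop
suitability CS(t). Adults lay f = SR·φ(T)·ψ(T)·N_A eggs per day until
∫φ dt = 1, then senesce. Initial sizes, initial ages r0 and K are estimated
by differential evolution (DE/rand/1/bin) minimising
RSS = Σ_k (O_k − S_k)² over the monitoring records, and the fitted r0 is
inverted day by day through the temperature record to the age-zero date t₀.
Details and all defaults: [docs/methods.md](docs/methods.md).

## Worked example

Fit the reference synthetic scenario (a 150-day tropical season whose
ground truth is a single egg cohort of 50 at physiological age 0.5, with
density dependence K = 0.01) and date the invasion:

```python
import bemipop as bp

truth = bp.default_scenario(seed=1)           # known ground truth
temps, monitoring, true_t0 = bp.generate_dataset(truth)

fit = bp.fit_initial_conditions(
    monitoring, temps, truth.engine,
    bp.DESettings(seed=7, max_generations=400))
print(f"RSS {fit.rss:.3g} after {fit.generations} generations")
print(f"egg size {fit.ic.egg_size:.2f}, r0_egg {fit.ic.egg_age:.3f}, "
      f"K {fit.K:.4f}")

bc = bp.backcast_invasion(fit, truth.t1_date, temps,
                          truth.engine.stage_params)
print(f"estimated first oviposition {bc.t0_date.date()} "
      f"(truth {true_t0.date()})")
```

prints

```
RSS 5.03e-16 after 273 generations
egg size 50.00, r0_egg 0.496, K 0.0100
estimated first oviposition 1988-12-01 (truth 1988-12-01)
```

The estimator recovers the founding cohort essentially exactly on
noiseless data — size 50, initial age 0.496 vs 0.5, K to four decimals —
and the back-cast lands on the generator's true oviposition date, four
days before the first monitoring visit: the field was already infested
when monitoring began, which is precisely the information an age-zero
assumption would have thrown away.

The same workflow from the shell:

```sh
bemipop synth --seed 1 --outdir data/
bemipop fit --temperature data/temperature.csv --monitoring data/monitoring.csv \
        --seed 7 --outdir out/
bemipop backcast --temperature data/temperature.csv --t1 1988-12-05 \
        --fit-result out/fit_result.kv --outdir out/
bemipop evaluate --monitoring data/monitoring.csv --simulated out/stage_series.csv
```

`bemipop config --write config.yaml` emits the fully documented default
configuration (thermal parameter forms per stage, lethal limits, crop and
density effects, DE settings); every rate function is swappable by name
through `bemipop.register_rate_form`.

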