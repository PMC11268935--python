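# ttdcomp

Competitive **time-to-detection (TTD) occupancy modelling** for camera-trap
monitoring of ephemeral resources — carcasses, artificial nests, fruit falls —
contested by two or more consumer species.

## The problem

When a fresh resource is placed in front of a camera trap, the first species
to find it usually consumes or destroys it, so every rival's potential use is
*censored* at that moment (as it is when the camera fails or the survey ends).
Raw detection frequencies therefore understate how much the subordinate
species would have used the resource, and with it the intensity of
consumptive competition and the redundancy of the ecosystem function the
consumers provide. `ttdcomp` treats the first-detection time of each species
as a right-censored survival outcome mixed with an occupancy state, which
recovers the *potential* use of every species from the censored record.

## The model

For station `k = 1..K` and each species, the data are `(t_k, c_k)`: the
elapsed time (days) to first detection (`c_k = 0`) or to censoring
(`c_k = 1`). With occupancy probability `ψ` and a parametric detection-time
distribution (density `f`, survival `S = 1 − F`; exponential, gamma,
log-normal or Weibull), each record contributes

```
L_k = [ψ · f(t_k)]^(1−c_k) · [1 − ψ + ψ · S(t_k)]^(c_k)
```

and species factorize under independent detection, for any number of rivals.
Fitting is Bayesian (adaptive Metropolis, several independent chains,
split-R-hat < 1.1, WAIC for family choice). From the posterior of
`(ψ_A, θ_A, ψ_B, θ_B)` the package computes, per draw:

- **Competition Intensity Index** `CII_A = ψ_B ∫₀ᵛ F_B(u) f_A(u) du` — the
  share of resource potentially available to A that the rival B takes first
  within the availability window `v` (`v = ∞` for gradually decaying
  resources);
- **Potential Functional Contribution** `PFC_A = ψ_A F_A(v)` — what A would
  consume with no rival;
- **Unique Functional Contribution** `UFC_A = PFC_A (1 − PFC_B)` — the net
  functional loss if A were removed (and `PFC_A · PFC_B`, the redundant
  share);
- **Resource allocation**
  `∫₀ᵛ ψ_A [1 − ψ_B + ψ_B S_B(u)] f_A(u) g(u) du` — the expected fraction of
  the resource's *initial value* captured by A when its value decays as
  `g(t)`, a Gompertz curve `g(t) = 1 − (1−γ) exp(−exp(−β(t−α)))` fitted to
  wet-mass monitoring data with multiplicative gamma error.

A synthetic-data module simulates the full generative process (occupancy,
competing latent detection times, camera failure, survey end, decaying
masses) and doubles as a brute-force Monte-Carlo oracle for every metric.

## Worked example

```python
import ttdcomp as tc

fox = tc.SpeciesModel(0.74, tc.TimeDistribution("lognormal", mu=2.16, sigma=0.64))
dog = tc.SpeciesModel(0.48, tc.TimeDistribution("lognormal", mu=2.48, sigma=0.72))

scenario = tc.SimulationScenario(
    n_stations=200,
    species_models={"fox": fox, "raccoon_dog": dog},
    survey_length=90.0,
    seed=42,
)
dataset, _ = tc.simulate_ttd(scenario)

from ttdcomp.io import format_summary
print(format_summary(dataset))

post = tc.fit_ttd(dataset, family="lognormal", chains=4, iterations=2000,
                  warmup=800, seed=1)
print(post.summary().round(3))
print("all R-hat < 1.1:", tc.diagnose(post).attrs["converged"])

cii = tc.posterior_metric(post, "cii", "fox", "raccoon_dog", max_draws=2000)
print(f"CII(fox)  = {cii.point:.3f}  95% CI [{cii.ci_low:.3f}, {cii.ci_high:.3f}]")
```

prints

```
K = 200 monitored stations
  fox: first detection at 117 stations (58.5%), censored at 83
  raccoon_dog: first detection at 53 stations (26.5%), censored at 147
  no detection: 30 stations (15.0%)
                    median  ci_low  ci_high
parameter
psi[fox]             0.728   0.649    0.803
mu[fox]              2.140   2.033    2.257
sigma[fox]           0.658   0.577    0.749
psi[raccoon_dog]     0.456   0.363    0.558
mu[raccoon_dog]      2.292   2.117    2.503
sigma[raccoon_dog]   0.683   0.566    0.852
all R-hat < 1.1: True
CII(fox)  = 0.197  95% CI [0.151, 0.253]
```

Foxes were detected first at 58.5% of stations, raccoon dogs at 26.5% — but
the model attributes this partly to censoring: fox occupancy is ~0.73 and
raccoon-dog occupancy ~0.46, and the competition index says raccoon dogs
pre-empt roughly 0.20 of the resource share potentially available to foxes
(the generating value is 0.178, inside the interval).

## Command line

```sh
ttdcomp simulate --config scenario.yaml --out detections.csv --seed 7
ttdcomp summarize detections.csv
ttdcomp compare-families detections.csv --out waic.csv
ttdcomp fit detections.csv --family lognormal --out fit
ttdcomp decay-fit masses.csv --out decay
ttdcomp metrics detections.csv --species-a fox --species-b raccoon_dog --v inf
ttdcomp run --config analysis.yaml     # full pipeline with report bundle
```

Detection tables are long-format CSV (`station_id,species_id,time_days,`
`censored[,cause]`, one row per station × species); mass tables are
`resource_id,time_days,wet_mass_g`; configs are YAML (see
`ttdcomp.io.RunConfig`).

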