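# sonoextract

Kinetic modelling of solid–liquid extraction of bioactive compounds
(polyphenols, flavonoids, antioxidant capacity) from plant byproducts, for
conventional stirred and ultrasound-assisted aqueous extraction. The package
is aimed at food-bioprocess researchers who measure extraction-yield curves
at several temperatures and want a single kinetic description of the whole
temperature range, plus the calorimetric characterisation of their
ultrasonic equipment.

## The model

The extraction yield `Y(t)` (percent of the extractable content `C_max`)
follows a Weibull (stretched-exponential) law whose characteristic time
depends on temperature through an Arrhenius relation:

    Y(t) = Y_eq · (1 − exp(−(t / α(T))^β)),       α(T) = α₀ · exp(+Eₐ / (R·T))

* `α(T)` — characteristic extraction time (s); smaller α = faster
  extraction. The *rate* 1/α obeys the standard Arrhenius law
  `1/α = (1/α₀)·exp(−Eₐ/(R·T))`, so heating accelerates extraction when
  `Eₐ > 0`.
* `β` — dimensionless shape; `β = 1` is first-order kinetics, `β < 1` a rate
  that decays over time.
* `Y_eq` — equilibrium yield, the observed terminal (30 min) value, held
  fixed during fitting.
* `Eₐ` — activation energy (J/mol) for release of the compound from the
  solid matrix.

All observations across temperatures enter **one** nonlinear least-squares
problem that identifies `(α₀, Eₐ, β)` simultaneously; standard errors and
95% t-intervals come from the Jacobian-based covariance at the optimum.
Companion modules estimate effective ultrasonic power from calorimetric
temperature-rise traces (`P = m·c_p·dT/dt`, power density `P/V` in W/L),
regress equilibrium yields on temperature, and score model adequacy with the
mean relative error `MRE = 100/n · Σ |Y_exp − Y_cal| / Y_exp`.

## Worked example

```python
import sonoextract as sx

design = sx.SyntheticDesign(
    true_params=sx.WeibullArrheniusParams(5.09e-7, 43058.2, 0.529),
    equilibrium={5.0: 74.7, 15.0: 74.7, 25.0: 74.7},
    noise_sd=2.0,
    seed=42,
)
gen = sx.generate_extraction_dataset(design)       # 3 T × 9 times × 3 reps
res = sx.fit_weibull_arrhenius(gen.dataset)
print(res.summary())
```

```
Weibull-Arrhenius extraction kinetics
==================================================================
condition: SIM        response: SIM
temperatures (degC): 5, 15, 25
n_obs: 27   dof: 24   RSS: 20.11   converged: True
MRE of fit: 1.07 %
------------------------------------------------------------------
param       estimate     std err         [95% CI             ]
alpha0     4.781e-07    4.83e-07       5.937e-08      3.85e-06
Ea         4.325e+04    2.35e+03       3.841e+04      4.81e+04
beta          0.5418      0.0196          0.5028        0.5837
==================================================================
alpha(T) = alpha0*exp(+Ea/(R*T)); alpha0 [s], Ea [J/mol]
```

The simulated triplicate curves (noise sd 2 yield-points) were generated
from `α₀ = 5.09×10⁻⁷ s`, `Eₐ = 43 058 J/mol`, `β = 0.529`; the fit recovers
all three within their confidence intervals, and a mean relative error of
1.07% says the fitted curves track the noisy observations to about one
percent of the yield. `res.predict(times, temperature_C)` evaluates the
fitted curve anywhere in the temperature range.

A command-line surface wraps the same functions:

```sh
sonoextract simulate --alpha0 5.09e-7 --ea 43058.2 --beta 0.529 \
    --y-eq 74.7 --seed 1 --out curves.csv
sonoextract fit curves.csv --out results/
sonoextract calorimetry trace.csv --volume 0.2
```

## Reference parameter tables

`sonoextract.reference` ships the published kinetic parameters and
equilibrium-yield lines for aqueous extraction from orange juice byproduct
(conditions CE = stirred 80 rpm, UAE1 = 520 W/L, UAE2 = 790 W/L sonication;
responses TPC, TFC, AA over 5–25 °C). `reference_dataset(condition,
response)` regenerates noiseless curves from those tables — the raw curves
were never deposited — and refitting them recovers the published values,
which the test suite uses as an end-to-end check.

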