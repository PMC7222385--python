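# Methods

## Model and assumptions

Extraction of a biocompound from a milled solid into well-mixed solvent is
described empirically by a Weibull law on the yield scale,

    Y(t; T) = Y_eq · (1 − exp(−(t/α(T))^β)),

with the temperature dependence of the characteristic time carried by an
Arrhenius relation α(T) = α₀·exp(+Eₐ/(R·T)), R = 8.314 J/(mol·K). The model
assumes: the extract starts solute-free (Y(0) = 0); the equilibrium yield
`Y_eq` is known per temperature (taken as the terminal, 30-minute
observation, per the usual convention for these experiments) and is *not* a
fitted parameter; the shape β and the Arrhenius pair (α₀, Eₐ) are shared
across the temperature range for one condition/response; and residuals on
the yield scale are homoscedastic, which motivates the unweighted pooled
sum of squares.

### The sign of the Arrhenius exponent

Published parameter tables for this class of experiment list α₀ of order
10⁻¹⁰–10⁻² s together with Eₐ of order 1.5–6.6 × 10⁴ J/mol *and*
characteristic times of tens to hundreds of seconds at 5–25 °C. Only

    α(T) = α₀ · exp(+Eₐ/(R·T))

is consistent with all three at once (a negative exponent would make α
astronomically small). Equivalently, the extraction *rate* 1/α follows the
textbook Arrhenius form (1/α₀)·exp(−Eₐ/(R·T)). The package uses this
convention throughout and prints it in every summary. α is treated as a
time in seconds — the dimensional analysis of (t/α)^β admits nothing else,
even though such tables sometimes label it s⁻¹. α(T) is evaluated in log
space (log α = log α₀ + Eₐ/(R·T)) so extreme Eₐ/(R·T) ratios cannot
overflow. Temperatures are Celsius at every user-facing interface and
Kelvin internally (T_K = T_C + 273.15).

## Fitting

All observations of one condition/response — every temperature, every
sampling time, by default the per-time replicate means (a pooled-replicates
option exists) — enter a single trust-region-reflective least-squares
problem (`scipy.optimize.least_squares`) on internal coordinates
(log₁₀ α₀, Eₐ, log β). The log scales are required: α₀ alone spans ten
orders of magnitude across realistic systems and raw-scale optimisation
stalls. Default box bounds are log₁₀ α₀ ∈ [−14, 2], Eₐ ∈ [0, 2×10⁵] J/mol,
β ∈ [10⁻³, 3] (identified shapes as small as 0.009 occur, hence the low
floor). Convergence tolerance is 10⁻¹⁰ on the relative cost change with up
to 500 iterations per start.

Starting values are data-driven: per-temperature linearised Weibull fits
(regress ln(−ln(1 − Y/Y_eq)) on ln t for β and α), then an Arrhenius
regression of ln α on 1/T for (α₀, Eₐ). A 5×5×5 multistart grid over the
box is the fallback, its order shuffled by the config seed; the fit itself
is deterministic given data and configuration, and the best (lowest-RSS)
converged solution wins. Equal lower and upper bounds pin a parameter.

### Uncertainty

With J the residual Jacobian at the optimum, σ̂² = RSS/(n − 3) and
Cov = σ̂²(JᵀJ)⁻¹ on the internal scale. Standard errors on the natural
(α₀, Eₐ, β) scale use the delta method. Confidence intervals are
t-intervals (quantile t₁₋ₐ/₂,dof) formed on the *internal* scale with their
endpoints mapped through the monotone parameter transform: a symmetric
natural-scale interval for α₀ ignores the strong log-normal skew of its
sampling distribution and, in our Monte-Carlo study, covered the truth in
only 79% of nominal-95% replicates, while the transformed-endpoint interval
covers at 89–90% for all three parameters. A singular or near-singular JᵀJ
(condition number > 10¹²) triggers a rank-deficiency warning and a
pseudo-inverse. Zero-residual fits yield degenerate intervals equal to the
estimates. The SE scale used by other software for such tables is not
always documented; we report the delta-method natural-scale SEs and make no
attempt to match any other convention.

## Calorimetry

Effective ultrasonic power comes from the initial heating rate of the
unthermostated solvent: P = m·c_p·dT/dt, with dT/dt the OLS slope of
temperature against time over the first 300 s of 1 Hz logging (a regression,
not a two-point difference, for robustness to sensor noise; the window is
configurable). Defaults: c_p = 4186 J/(kg·°C) (water), solvent mass =
volume × 0.998 kg/L when not given — both configurable, and the mass
default is logged because the solvent charge actually heated is an
assumption, not a measurement. Synchronised traces from multiple
thermocouples are averaged pointwise before regression. The slope's OLS
standard error propagates linearly to the power; acoustic power density is
P/V (W/L), summarised over replicate runs as mean ± sample sd.

## Equilibrium yields

Y = 100·C/C_max converts concentrations to yields; values above 100%
(measurement noise near exhaustion) are warned about but never truncated.
Y_eq is the terminal-time observation (replicates averaged). Its
temperature dependence is an OLS line with the ordinary r²; the
`temperature_dependent` flag is a two-sided t-test on the slope at
α = 0.05 with n − 2 dof, replacing eyeballed judgements. A perfectly flat
response returns slope 0, r² = 1 (collinear points) and no dependence.

## Model adequacy

MRE = 100/n · Σ|Y_exp − Y_cal|/Y_exp, over observations with Y_exp > 0;
zero-time points are excluded (the standard sampling design starts at
1 min, so nothing is lost). Summaries report the mean and *sample* (n−1)
standard deviation, displayed at one decimal with half-up rounding; raw
values are kept internally. Two reporting quirks of the published summary
tables are worth knowing: the antioxidant-activity column of one-decimal
MREs (5.0, 2.7, 1.8) has raw mean 3.1667, which displays as 3.2 though the
original summary prints 3.1 (evidently computed on unrounded MREs), and the
polyphenol column's sample sd is 1.54 (displays 1.5) against a printed 1.6
— same cause. The package reproduces every summary computable from the
printed cells and documents these two last-digit differences rather than
adjusting anything.

## Synthetic data

The generator emulates the standard design: triplicate curves at 5, 15 and
25 °C sampled at 1, 2, 3, 4, 5, 6, 8, 10 and 30 min, mean given *exactly*
by the package's own forward model (shared code path, asserted in tests)
plus i.i.d. additive Gaussian noise on the yield scale, truncated at zero
with a truncation counter. Replicate-level scatter was never published for
these experiments; the default sd of 2 yield-points is a stand-in chosen to
resemble typical error bars on such curves and touches the truncation bound
in well under 1% of draws. Homoscedastic additive noise is an assumption —
real assay error may grow with concentration — so passing recovery and
coverage tests demonstrates correctness of the estimation machinery under
the stated noise model, not robustness to assay-specific error structure.
Curves generated for fitting studies carry the *true* equilibrium yield as
their asymptote (matching the convention that Y_eq is a fixed known input);
deriving Y_eq from the noisy terminal observation instead is possible via
the loader and slightly degrades coverage.

Reference datasets regenerated from the published parameter tables are
noiseless by construction; their refit recovers the tables to ~10⁻¹¹
relative, which validates the pipeline but says nothing about noise
robustness (the Monte-Carlo study covers that).

## Problem sizes

The Monte-Carlo coverage study uses 200 replicates of the full
3 × 9 × 3 design (27 fitted means each), which characterises coverage to
about ±2 percentage points and completes in seconds; the acceptance script
re-runs it from the supplied seed. Calorimetry simulations use 301-point
(5 min, 1 Hz) traces with noise sd 0.05 K.

## Known limitations

* Single-response, single-condition fits only; no hierarchical sharing of β
  across conditions, no degradation term for temperatures high enough to
  destroy analytes.
* Y_eq is fixed, so its measurement error is not propagated into the
  parameter uncertainties.
* Alternative empirical kinetics (Peleg, Page, two-site diffusion) are out
  of scope.
* The slope t-test for temperature dependence inherits the usual small-n
  caveats at three temperatures.
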