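# Methods

`humidistat` analyses behavioural hydroregulation experiments in an annular
laboratory humidity gradient, and ships a synthetic study generator so the
whole analysis chain can be validated by parameter recovery. This note
documents the models, the numerical choices, and what the synthetic study
does and does not establish about real data.

## Psychrometrics

Relative humidity is not comparable across temperatures; the quantity an
evaporating animal experiences is the vapour pressure deficit
`VPD = WVP_sat(T) − WVP_act`, the drying power of the air (kPa). Saturation
vapour pressure uses the Tetens-form expression
`e_s(T) = a·exp(bT/(T+c))` with the Campbell–Norman constants
`(0.611, 17.502, 240.97)`. The classic Tetens constants
`(0.61078, 17.27, 237.3)` are provided as an alternative; the two variants
differ by well under 1% over the −10…50 °C range the package accepts, but can
flip a value rounded to two decimals in extreme cells, which is why tests pin
only robust reference points. RH is carried on the 0–100 scale everywhere;
values strictly inside (0, 1) are rejected as probable fractions rather than
silently rescaled.

## Arena geometry and humidity field

The arena is a ring (outer radius 45 cm, inner 30 cm) divided into an inner
and outer lane at 37.5 cm. Dry air enters at 0°, humid air at 180°, mixed air
at the two mirrored 90° ports, so the gradient is angular and mirror-symmetric
about the dry–humid axis. Analysis therefore works on the *folded* angle
`min(θ mod 360°, 360° − θ mod 360°) ∈ [0°, 180°]`.

Conventions worth stating explicitly:

* Image coordinates have y pointing down, so after re-centring on the annulus
  centroid the polar angle increases clockwise on screen; 0° is the dry-port
  direction. The pixel scale comes from the known outer radius against its
  pixel radius (default 10 px/cm).
* Step distances are minimal (wrap-aware) arcs `r·Δθ` at the lane's mean
  radius (inner lane 33.75 cm, outer 41.25 cm). A 30 s step cannot plausibly
  exceed half the annulus, so the minimal arc is the only defensible rule.
* Humidity is assigned from the folded angle only; radial position within a
  lane is ignored (the gradient is angular, and the lanes are narrow).

The angle→RH calibration is an ordinary least-squares line fitted to
per-record hygro-logger data from stations every 22.5°. The reported R² is
that of the per-record fit, so sensor noise lowers it even when station means
are perfectly linear — this matches how the physical apparatus is
characterised (R² ≈ 0.85). A zero-variance (flat) calibration is reported
with slope 0 and R² = 0 by convention to keep the pipeline total. Field
predictions are clipped to [0, 100]%. VPD at an angle is the field RH pushed
through the psychrometric map at the field's *nominal* temperature (the
loggers' local temperature readings are not used; this keeps RH↔VPD
summaries internally consistent).

## Trials and summaries

A trial is 12 h imaged every 30 s (1440 frames); the first 3 h are
habituation and are excluded from all hypothesis-level summaries, leaving a
9 h experimental period (360/1080 frames). Timestamps are reconstructed from
slice number × frame interval. Single missing slices are filled by linear
interpolation of (x, y) and flagged; gaps are never extrapolated beyond the
observed ends, and a track missing more than 5% of its interior slices is
rejected rather than repaired.

Per-trial outcomes are the median selected RH, median selected VPD and the
total distance moved `D_t` (sum of per-step minimal arcs, metres). Medians
use the midpoint-of-middle-two convention; since VPD is strictly monotone in
RH at fixed temperature, `median(VPD) = VPD(median(RH))` holds exactly within
a constant-temperature trial, and the pipeline asserts it.

## Water balance

EWL is gravimetric: `(mass_pre − mass_post)/duration` with 1 g water ≡ 1 ml.
The default denominator is the full 12 h in the gradient; the 9 h
experimental period is a supported alternative (the choice shifts rates by a
constant factor 4/3 and none of the comparative conclusions). ReR is the mass
gained over a standardised 30 min immersion, scaled ×2 to an hourly rate.
Net gains during a trial (or losses during rehydration) produce negative
rates with a warning, not an error. Thermal sensitivity is the Van't Hoff
coefficient `Q10 = (R2/R1)^(10/(T2−T1))`; per-individual Q10 values come from
each animal's paired rates at the two temperatures. The cohort is summarised
both by the arithmetic mean ± SD (the conventional report, upward-biased
under multiplicative trial noise) and by the geometric mean, the consistent
estimator of a shared underlying Q10 — recovery tests use the geometric mean
for exactly this reason.

## Mixed models

Every response is fitted as `response ~ fixed terms + (1 | animal)` by
restricted maximum likelihood (statsmodels `MixedLM`), because each animal
is tested once at each temperature. Four presets mirror the study design:

| preset | model |
|---|---|
| `vpd` | median VPD ~ temperature + log M_b |
| `rh` | median RH ~ temperature + log M_b |
| `ewl` | log EWL ~ VPD + temperature + log M_b + D_t |
| `rer` | log ReR ~ log EWL + temperature + log M_b |

Temperature is a two-level factor with 17 °C as reference; covariates are not
standardised, so estimates are on raw/log scales. Confidence intervals and
p-values are Wald with the normal approximation; Satterthwaite-type df
corrections are deliberately out of scope (at 44 groups the difference is a
~3% narrowing of intervals). Repeatability is `ICC = τ00/(τ00 + σ²)`;
explained variance uses the variance-partition (Nakagawa–Schielzeth)
definitions, with the fixed-effect variance taken over the observed design.
Marginal means predict each factor level with covariates held at sample
means, using the fixed-effect covariance for intervals. Residual diagnostics
report lag-1..10 autocorrelations against ±1.96/√n bands (flagging when more
than one lag escapes — a rule whose false-flag rate calibrates to ≈5–6% for
white noise at n = 88) and a Shapiro–Wilk statistic.

Degenerate designs are handled explicitly: a rank-deficient fixed-effect
matrix is rejected with the redundant term named; data with one observation
per animal drive τ00 to the boundary and the fixed effects agree with OLS
(asserted to 1e−6 in tests); REML estimates are cross-checked against lme4
on identical data in the test suite.

## Synthetic study generator

The generator reproduces the study design: 44 animals (22 F/22 M, sexes
carried as metadata with no effect), each tested once per temperature
(17, 22 °C), 1440 frames per 12 h trial, lognormal body masses (mean 12 g,
SD 4 g) with small between-trial jitter.

**Behaviour.** The agent is a humidistat: a correlated random walk on the
folded angle (persistence 0.5, innovation SD 6.2°/step) with drift
proportional to the gap between the local VPD and a personal target,
`target_i = 0.56 kPa + 0.05·(log m_i − mean log m) + b_i`, reflecting at 0°
and 180° and released at the 90° intermediate station. Because the target is
a VPD, the cohort selects higher RH at 22 °C purely through psychrometrics
(implied offset ≈ 7.7 percentage points at the target) — the effect the RH
model must detect while the VPD model finds nothing.

**Calibrated defaults.** The field spans (48→95% RH at 17 °C, 60→97.5% at
22 °C) place the 0.56 kPa target at the 90° midpoint of the gradient, which
removes the reflection-truncation bias of the cohort mean; station noise
(6.4 / 5.3 %) puts fitted field R² in the 0.80–0.90 band. Drift gain
(0.8°/step per kPa) and the step parameters were calibrated once so that the
total distance moved is ≈ 40 m per trial and the walk's slow mixing produces
trial-to-trial variation in the median. The walk transmits personal targets
to realised trial medians with slope ≈ 0.26, so the individual-intercept SD
(0.16 kPa) is set on the realised scale to give a VPD-model ICC ≈ 0.25.
These are the study conditions; they are not adjusted per run.

**Physiology.** `EWL = 0.0236·m^0.67·VPD·exp(ε)`, ε ~ N(0, 0.35): an
allometric surface-area exponent, linear VPD dependence, lognormal trial
noise; post-trial mass follows gravimetrically. `ReR = 0.18·Q10^((T−17)/10)·
exp(ε)` ml/h with Q10 = 2.5 and ε ~ N(0, 0.4); the rehydrated mass is capped
at the pre-trial mass (animals at most regain their initial mass; under the
default rates the cap binds in ≪1% of trials and negligibly biases Q10
recovery).

**What the generator does not emulate.** Real salamanders pause, coil, and
follow wall geometry; the walk has no behavioural states, no radial
behaviour, and its within-trial variance of the median (σ² ≈ 0.008 kPa²) is
smaller than a real cohort's. Logger noise is white per record, with no
drift or station-specific bias. Sex has no effect. Passing recovery tests
therefore demonstrates that *the pipeline estimates what the design can
identify* — not that the movement model is a kinematic description of real
animals.

## Problem sizes and tolerances

Recovery runs use the full design (44 × 2 trials). Replicated checks use two
tiers: full resolution (1440 frames, 30 s) where the quantity depends on
within-trial sampling (ICC, Q10, cohort means), and a reduced tier
(200 frames, 216 s — same 12 h trial and 3 h/9 h split) for the 200-replicate
temperature-contrast pattern, where frame count only widens per-trial noise.
Monte-Carlo tolerances are ~3 SEs of the replicate means (±0.10 on ICC,
±0.30 on Q10). Numerical identities (arc-length oracle equivalence, median
transform, psychrometric round trips, LMM→OLS collapse) are asserted at
1e−9/1e−6 as appropriate.
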