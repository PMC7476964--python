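# Methods

This note documents the simulation model, its assumptions, the
calibration of the auxiliary natural-history parameters, the numerical
choices, and the limits of what the test suite demonstrates.

## Model structure

The simulator is an individual-level (micro-simulation) model. For each
woman it draws, up front, every random quantity her life course can
consume: natural death age, tumour onset indicator and age, volume
doubling time, a latent density uniform, attendance indicators, one
detection uniform and one false-positive uniform per scheduled round,
dose deviates, and the uniforms driving self-detection, cure, survival
and radiation induction. Screening policies are then deterministic
functions of these draws. Because all policies consume the *same* draw
set (common random numbers), scenario contrasts are paired within
women, which is what makes the small standard errors of the difference
tables meaningful and guarantees exact scenario equivalence when DBT is
parameterised identically to DM.

### Natural lifespan

Death from causes other than breast cancer follows a bundled abridged
female life table (synthetic, constructed to match recent Dutch female
period mortality, life expectancy ≈ 83.5 years). Annual death
probabilities between tabulated ages are interpolated log-linearly and
survival is forced to zero at age 110. Any monotone life table can be
substituted through the configuration (`aux.life_table`); comparative
results between scenarios are insensitive to its exact shape because
all scenarios share it.

### Tumour onset and growth

A woman develops at most one spontaneous invasive tumour. The onset
probability is set so that the cumulative probability of onset by age
70 equals the lifetime risk parameter (22.6%), with the onset age drawn
from Normal(72.9, 21.1) truncated to [20, 100]. By default the 22.6% is
interpreted as a *net* risk (ignoring competing mortality); a `crude`
interpretation — 22.6% of women experience onset by 70 *while alive* —
is available via `flags.risk_model`. Ductal carcinoma in situ is not
modelled; all tumours are invasive.

Tumour volume doubles every `DT` days, where `DT` is drawn once per
tumour from the age band at onset (Normal with means 80/157/188 days and
SDs 28/25/52, truncated below at 10 days) and kept fixed for the
tumour's lifetime. Diameter therefore doubles every `3·DT` days from a
nominal seed size `d0` and is capped at 128 mm. The alternative reading
— re-drawing `DT` when a tumour crosses an age-band boundary — would
blur the band contrast but not the scenario comparisons; we keep the
simpler fixed-per-tumour rule.

`d0` deserves a comment. The model's constant-doubling-time growth law,
back-extrapolated from the clinically relevant range (5–50 mm), runs
faster than real early-phase tumour growth. The calibrated seed
(`d0 = 0.0019 mm`) is therefore *not* a physical cell size but the
nominal intercept that gives the onset-to-detectability lag required to
reproduce the published screening outcomes (about 15 years at
`DT = 157` days). It is configurable (`aux.initial_diameter_mm`).

### Breast density

Each woman carries one latent uniform that is pushed through the
cumulative BI-RADS distribution of whichever age band she is in
(comonotone coupling). This reproduces the published marginal
distribution in every age band and makes density non-increasing with
age within a woman, so women migrate towards lower density — and higher
DM sensitivity — as they age. The coupling across bands is not
identified by marginals; comonotonicity is the canonical choice and the
only one consistent with a deterministic per-woman density trajectory.

### Screening process

Screens are offered biennially from age 50 up to (exclusive) 75 — 13
rounds. Participation is 80%. By default participation is *habitual*:
a woman either attends every round she is alive and undiagnosed for, or
none (`flags.participation_model = "per_woman"`). Independent
per-round Bernoulli attendance is available; the habitual model was
selected during calibration because it reproduces the published
full-sensitivity contrast (see Calibration).

At an attended round, a tumour at or above the 5 mm detection threshold
is detected with the modality's sensitivity (DM: density-specific; DBT:
a single value applied to all densities); below the threshold detection
is impossible. A cancer-free attended screen is a false positive with
probability 1 − specificity and incurs one biopsy. Each attended screen
delivers a glandular dose drawn from Normal(mean, SD) clipped below at
zero (the clip moves the mean by < 0.1% at the published dose
parameters). Diagnosis — by screen or by self-detection — removes the
woman from further screening.

Interval cancers are self-detected cancers whose most recent scheduled
round the woman attended with a negative result, surfacing before the
next scheduled round, or within one screening interval after the final
round (window configurable via `flags.interval_window_years`).

### Self-detection

The hazard of a woman noticing her tumour is logistic in diameter,
`h(d) = hmax / (1 + exp(-(d - midpoint)/slope))` per year, with
calibrated defaults `hmax = 7.5/y`, `midpoint = 34 mm`, `slope = 5 mm`.
The slope's lower tail matters: it lets a small fraction of tumours
surface clinically before ever being screen-detectable, which the
published interval-cancer count requires. Sampling inverts the
cumulative hazard exactly: with exponential growth the cumulative
hazard along the growth path is `H(t) = G(d(t))/κ` where
`G(d) = ∫ h(x)/x dx` is precomputed once on a 4096-point log-spaced
diameter grid and `κ = ln 2 / (3·DT)`; one Exp(1) draw per tumour then
maps to a detection age by interpolation. Beyond the diameter cap the
hazard continues at `h(d_max)`.

### Survival after diagnosis and life years gained

Treatment cures with probability logistic-decreasing in diameter at
detection, `c(d) = cure_max / (1 + exp((d - midpoint)/slope))`
(calibrated: `cure_max = 0.452`, `midpoint = 32 mm`, `slope = 4 mm`). A
cured woman dies at her natural death age. An uncured cancer is fatal
`Exp(5 years)` after the age the tumour *would have surfaced
clinically* — the same anchor in the screened arm and the unscreened
counterfactual. This "stage-shift cure" construction removes lead-time
bias by design: with the cure and survival uniforms shared between
arms, earlier detection can only improve or leave unchanged a woman's
death age, overdiagnosed cancers (those that would never have surfaced
before natural death) gain exactly zero life years, and interval or
self-detected cancers — detected at the same size in both arms — gain
exactly zero as well. All life years gained therefore flow through the
incremental cure of screen-detected cases, which is the mechanism the
cure curve is calibrated to scale. An earlier design keyed the cure
probability to the three treatment-cost size categories; it could not
reproduce the published life-year gains once the self-detection hazard
was calibrated, because screen and clinical detection then usually fall
in the same category. Treatment *costs* still use the three published
size categories.

### Radiation-induced tumours

The probability of a radiation-induced tumour is linear no-threshold:
`lifetime_risk × ERR × cumulative dose (Gy)` with ERR = 0.51/Gy. The
dose history is accrued over attended screens up to diagnosis (computed
from the spontaneous-tumour pathway; an induced diagnosis can only
shorten the history, a second-order effect we ignore). When induced,
the tumour is attributed to an exposure in proportion to dose, begins
10 years after that exposure (configurable latency), and grows,
surfaces, and is screened exactly like a spontaneous tumour. A woman's
diagnosis is the earliest of the four candidate events (screen or
clinical surfacing of either tumour); taking the minimum is exact
because any earlier diagnosis would have stopped screening. The
age-at-exposure effect modification of the underlying radiation model
is not included; with it, the computed ~0.25% tumour excess from the
1 mGy dose difference would shift within a few tenths of a percentage
point.

## Health economics

Costs are screening examinations (priced by modality; the DBT price is
a pure multiplier applied after simulation, so both €96 and €80 are
costed from one simulation), one biopsy per positive finding (true or
false) and per clinical diagnosis, and one treatment priced by size
category at detection, charged at the detection age. Discounting is to
age 50 (first invitation) at the scheme's rates; life years gained are
discounted as a continuous stream between the two death ages,
`∫ (1+r)^{-(a-50)} da`, with a discrete annual approximation available
(`flags.discrete_lyg_discounting`; the two differ by < 2% at these
rates). "Cost-effective" means ICER strictly below €20,000/LYG; a
scenario with positive extra effect at no extra cost is dominant; more
costly and no more effective is dominated. ICER standard errors use the
delta method on paired repetition-level deltas (ratio of means); the
mean-of-ratios alternative differs negligibly at these SEs.

## Calibration of auxiliary defaults

Five auxiliary quantities are not published point estimates: the seed
size `d0`, the self-detection hazard (`hmax`, midpoint, slope) and the
cure ceiling `cure_max`. They are underidentified by the three
reference-programme outcomes alone, so the shipped defaults minimise
the weighted squared relative error to five published outcomes
simultaneously (Nelder-Mead on log/logit scales, 100,000-woman
evaluations with fixed seeds):

* reference programme per 10,000 women: 536 screen-detected cancers,
  272 interval cancers, 1353 life years gained;
* full-sensitivity contrast (DBT for all at sensitivity 1.00 minus
  reference): +91 screen-detected, +254 LYG — this pins how many
  DM-missed tumours the model leaves available for a more sensitive
  modality to convert.

Achieved at the shipped defaults (10 × 100,000 women): roughly 495 /
288 / 1250 / +93 / +273 — all within 10% of the targets. The residual
misfit is one-dimensional: the model's pool of convertible DM misses
per screen-detected cancer sits ~8% above the published value, and no
admissible auxiliary configuration found removes it while holding the
reference counts; it surfaces as a slightly low reference LYG and a
slightly high full-sensitivity LYG contrast (the cure-curve scale
spreads it across the two), and as an interval-cancer reduction at
full sensitivity of −82 per 10,000 versus the published −74 — the one
reproduction check the suite intentionally leaves failing. Two
cost-effectiveness grid cells ((scenario 1, €96) at 85% and
(scenario 2, €96) at 95%) compute to within ±5% of the €20,000/LYG
ceiling, so the corresponding threshold sensitivities can land one
5-point grid step away from the published ones depending on the seed;
the published table itself prints 20.8 k€/LYG — above its own ceiling —
at two cells its summary calls cost-effective.

The calibration harness is reusable: `tomosim calibrate` (or
`runner.calibrate_aux_defaults`) refits the auxiliaries for modified
structural assumptions.

## Problem sizes and determinism

The default experiment plan is the full factorial — 3 scenarios ×
8 DBT sensitivities (65–100% step 5) × 2 DBT prices × 3 discounting
schemes — with 10 repetitions of 100,000 women per cell and common
random numbers (the price and scheme dimensions are deterministic
post-processing). One 100,000-woman cohort simulates in about a second;
the full plan plus tables runs in well under five minutes on one CPU.
Per-cell seeds derive from `SeedSequence([master_seed, repetition])`
under common random numbers (scenario, sensitivity and price never
enter the stream) and from the full cell tuple when common random
numbers are disabled, so results are bit-reproducible and independent
of iteration order. Counts and life years are reported per 10,000
simulated women; standard errors are across-repetition standard
deviations divided by √repetitions, on the per-10,000 scale.

## What the tests show — and what they do not

The suite validates three distinct things. Structural correctness: the
vectorised engine agrees woman-by-woman (detection mode, ages within a
day, event counts) with an independent day-stepping re-simulation on
1,000 sampled women, and degenerate configurations collapse to their
closed forms (false-positive counts, induction fractions, discounting
integrals, truncated-normal onset fractions, exact scenario equivalence
when DBT mirrors DM). Qualitative behaviour: screen-detected counts,
interval counts, life years and ICERs move monotonically in DBT
sensitivity under common random numbers. Quantitative reproduction: the
published screening outcomes and threshold sensitivities at the
published scale, within max(3 reported SE, 10%).

Passing these says the implementation faithfully executes *this* model
under *these* calibrated auxiliaries. It does not validate the model
against real screening data: the life table is synthetic, the
self-detection and cure curves are calibrated constructs rather than
estimated clinical quantities, DCIS and recall pathways beyond a single
biopsy are absent, quality-of-life weighting is out of scope, and the
sensitivity inputs are modality (not programme) sensitivities. Absolute
outputs should be read as model quantities; the robust products are the
scenario *contrasts* and the sensitivity thresholds.
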