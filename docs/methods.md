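# Methods

This note documents the models, parameter choices and numerical decisions in
`mirdpk`, and what the synthetic-data tests do and do not establish.

## Kinetic model and residence times

Organ VOI concentrations (fraction of injected activity per gram; blood pool
per mL at water density) are scaled by reference-adult organ masses — liver
1800/1400 g, spleen 150/130 g, kidneys 310/275 g, red marrow 1170/900 g
(male/female) — to whole-organ fractions, capped at 1.0 with a warning since
spill-in can nominally exceed the injected activity for small organs.

Fits are performed on **decay-corrected** data with physical decay restored
analytically at integration: τ = Σᵢ aᵢ/(bᵢ+λ). Whether fitting corrected or
uncorrected curves is equivalent in principle; fitting corrected data makes
the biological rates directly interpretable and the residence-time integral
exact in closed form, which is why it is the package convention. Residuals
are relative (PET VOI means carry roughly proportional error); amplitudes
are bounded to [0, 1] (fractions of injected activity) and rates to
[0, 50 /h] (sub-minute clearance half-lives are not resolvable with these
sampling designs, and unbounded spike components would otherwise absorb
single noisy points).

Bi-exponential fits use multi-start initialisation: all pairs from a
log-spaced rate grid {0.02, 0.1, 0.5, 2, 8}/h, amplitudes seeded by
non-negative linear least squares at the fixed rates, refined by
trust-region least squares (tolerances 1e-13), best objective wins.
Automatic model selection keeps the mono-exponential unless the
bi-exponential reduces the fitting objective by at least 25% and at least
four points are available; a mono fit at numerical perfection is never
"improved", since a four-parameter fit of noiseless two-parameter data only
overfits. Extrapolation beyond the last time point follows the fitted
exponentials; no conservative flat tail is applied.

The heart-content residence time scales the whole-blood residence time
(left-ventricle concentration × total blood volume, 5300/3900 mL) by the
chamber/blood volume ratio (500/5300 male, 370/3900 female).

## Voiding-bladder model

Cumulative decay-corrected urinary excretion is fitted with
A(t) = A₀(1 − e^(−A₁t)). A parcel excreted at time s carries physical
activity A₀A₁e^(−(A₁+λ)s)ds, so with complete voids at T, 2T, … (first void
at t = T; the offset is configurable) the physical bladder content in the
k-th interval is

    b(t) = A₀ e^(−λt) (e^(−A₁kT) − e^(−A₁t)),

whose interval integral is A₀e^(−(A₁+λ)kT)[(1−e^(−λT))/λ − (1−e^(−μT))/μ]
with μ = A₁+λ. Summing the geometric series over k to infinity (the residual
activity vanishes beyond machine precision; no truncation horizon is needed)
gives the retained bladder-content residence time in closed form. The voided
activity is tracked as a non-irradiating sink; retained + excreted equals
the total urine TIA A₀A₁/((A₁+λ)λ) to 1e-10, and the sum is what the
residence-table "bladder content" row reports, matching the accounting used
in the human study tables. Small-argument terms use `expm1` for stability.

## Residence accounting

The residence table carries six source regions (liver, kidneys, bladder
content, spleen, red marrow, heart content). The remainder of body is
computed by subtraction from the no-excretion total-body TIA:
remainder = T½/ln2 − total. This is the arithmetic evident in the study's
printed table (it reproduces all nine remainder entries within rounding) and
treats the excreted TIA as removed from the body. Rounding to 2 decimals
(residence) and 3 decimals (doses) happens only at reporting.

## S-value stand-in

The reference dosimetry software's internal S-values are not published, so
the packaged Cu-64 adult male/female sets (versioned CSVs under
`mirdpk/data/`, regenerated exactly by `dose_engine.build_svalue_set`) are an
analytic construction:

* mean electron energy 0.1224 MeV/decay (β⁻ 38.5% × 190.7 keV + β⁺ 17.5% ×
  278 keV), absorbed locally in the source organ; red marrow uses an electron
  self-absorbed fraction of 0.40 (trabecular escape plus marrow cellularity),
  with the escaped 60% deposited in the skeleton;
* mean photon energy 0.1854 MeV/decay (annihilation pairs + the 0.5%
  1.35-MeV gamma) with self-absorbed fraction φ(m) = min(0.35, 0.0115·m^⅓)
  and the escaping remainder spread uniformly over the body at a whole-body
  absorbed fraction of 0.34 (uniform cross-fire approximation);
* content→wall surface dose at half the equilibrium electron dose for the
  urinary bladder (content 200/160 g) and heart chambers;
* a remainder-of-body source whose electrons irradiate every tissue outside
  the explicit source organs.

This reproduces the scale and ordering of organ doses for Cu-64 tracers
(self-dose-dominated spleen/kidneys/liver, a near-uniform ~0.02 mSv/MBq
photon background for non-source organs) but is not a Monte Carlo transport
result: organ-pair geometry is ignored, so neighbouring-organ cross-fire and
skeletal photon doses are underestimated. Absolute per-organ agreement with
published human values is therefore expected at the tens-of-percent level;
the dose engine's verification rests on exact linear-algebra properties,
summary arithmetic, and rank statements rather than absolute values.

Dose ranking statements ("spleen highest") are made over parenchymal organs;
hollow-organ walls, skeleton, skin, lens and the whole-body entry are
reporting rows, not uptake organs, and the bladder wall would otherwise top
any high-excretion participant.

## Effective dose

ICRP-60 effective dose: tissue weights gonads 0.20; marrow/colon/lung/
stomach 0.12; bladder/breast/liver/esophagus/thyroid 0.05; skin/bone surface
0.01; remainder 0.05 as the arithmetic mean of adrenals, brain, kidneys,
muscle, pancreas, small intestine, spleen, thymus and uterus (when present).
The esophagus uses the thymus dose as surrogate and bone surface the
skeleton dose (standard reporting conventions); sex-absent organs fall back
to the muscle (soft-tissue) dose. ICRP-26 effective dose equivalent: gonads
0.25, breast 0.15, marrow and lung 0.12, thyroid and bone surface 0.03, and
0.06 for each of the five highest-dosed remaining organs. Reconstructing the
ICRP-60 effective dose from the study's printed per-participant organ doses
with these rules lands within 9% of the printed values for all nine
participants — the residual reflects the unknown exact remainder handling of
the original software. Doses and effective doses are reported in mSv/MBq
(the printed table's footer says Sv/MBq, but all magnitudes, including the
abstract's, are mSv/MBq).

## SUV statistics

SUV = concentration × body mass / injected activity, with concentrations
decay-corrected to scan start (convention configurable). Marrow SUV is the
arithmetic mean over lumbar vertebrae. The group comparison is a two-sample
two-tailed Student t-test (equal variance by default, Welch by flag),
significance at 0.05. A power simulation drawing normal groups with the
printed iliac-bone SUVmax summaries (12.05 ± 2.0, n = 5 vs 25.62 ± 9.38,
n = 3) rejects in ≈73% of simulations; this is the analytic power of the
pooled two-tailed test under those moments (a one-sided test would be ≈84%).

## Synthetic cohorts

Defaults emulate the study conditions: n = 9 (4 F / 5 M as labelled in the
dose tables), injected activity uniform on 247–433 MBq, body mass log-normal
around 75 kg, three static sessions (1, 4.5, 24 h) for everyone plus dynamic
0–1 h frames (blood pool and marrow) for three participants, urine
collections at 1, 2, 4, 8, 24 h. Population kinetics are mono-exponential
with median parameters chosen so the implied residence times sit mid-range
of the study's reported values (liver 0.80 h, kidneys 0.13 h, spleen 0.25 h,
marrow 2.5 h, heart content 0.05 h, urine filling A₀ = 0.45, A₁ = 0.30/h),
scattered log-normally at 25% CV between participants under the feasibility
constraint Σ amplitudes + A₀ ≤ 1. Measurement noise is multiplicative
log-normal, default CV 5%; urine curves are made non-decreasing after
noising.

What passing the recovery tests shows: the fit–integrate–account–dose chain
is unbiased and ~2% (median) accurate under proportional noise at the study's
sampling design. What it does not show: robustness to model misspecification
(true multi-compartment kinetics, partial-volume effects, respiratory
motion), to non-proportional noise, or to VOI delineation error — none of
which the generator emulates.

## Problem sizes

The shipped verification uses 1,000 random draws for the residence-integral
quadrature sweep, 500 draws each for the voiding-model discrete-time oracle
(Δt = 0.001 h) and the urine-TIA identity, 1,000 simulations for the SUV
power study, and 100 cohorts (4,500 organ fits) for end-to-end recovery;
together they run in a few minutes on one CPU.
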