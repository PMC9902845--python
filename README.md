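# mirdpk

MIRD-schema internal dosimetry and PET pharmacokinetics for first-in-humans
Cu-64 radiotracer biodistribution studies.

Radiopharmaceutical dosimetry turns a handful of PET volume-of-interest (VOI)
measurements and urine collections per participant into organ absorbed doses
per unit administered activity. `mirdpk` implements that chain for a
Cu-64-labelled tracer (half-life 12.7 h) as a tested, reusable pipeline, for
imaging physicists and pharmacokinetic modellers:

1. **Kinetics** — decay-corrected organ time-activity curves (liver, spleen,
   kidneys, red marrow, blood pool) are fitted with mono- or bi-exponential
   models, A(t) = Σᵢ aᵢ e^(−bᵢt), and integrated analytically with physical
   decay restored, giving the residence time
   τ = Σᵢ aᵢ/(bᵢ + λ) (hours), with λ = ln2/T½.
2. **Bladder** — cumulative urinary excretion is fitted with the filling
   function A(t) = A₀(1 − e^(−A₁t)) and pushed through the MIRD dynamic
   voiding-bladder model (complete voids every 2 h); the retained
   bladder-content TIA and the excreted, non-irradiating component together
   close to the urine TIA A₀A₁/((A₁+λ)λ) exactly.
3. **Accounting** — heart content scales the whole-blood residence time by
   the chamber/blood volume ratio; the remainder of body closes the balance:
   τ_total + τ_remainder = T½/ln2 = 18.32 h.
4. **Doses** — MIRD schema D(target) = Σ_source τ_source · S(target ← source)
   over packaged reference-adult male/female Cu-64 S-value matrices, plus the
   ICRP-60 effective dose and ICRP-26 effective dose equivalent.
5. **SUV statistics** — standardized uptake values
   (SUV = c · m_body / A_inj) and the two-sample Student t-test used for the
   patient-vs-healthy uptake comparison.
6. **Synthetic cohorts** — a generator reproducing the study design (n = 9,
   4 F / 5 M, 247–433 MBq, three static sessions 0–26 h plus a dynamic 0–1 h
   subset, 5% proportional VOI noise) with known ground truth, so every stage
   is testable end to end without any image data.

The packaged S-value sets are an analytic stand-in (the reference software's
internal values are unpublished); see `docs/methods.md` for their
construction and limits.

## Worked example

```sh
mirdpk simulate --n 9 --seed 42 --cv 0.05 --out cohort
mirdpk residence --measurements cohort/measurements.csv \
    --urine cohort/urine.csv --participants cohort/participants.csv \
    --out residence.csv
mirdpk doses --measurements cohort/measurements.csv \
    --urine cohort/urine.csv --participants cohort/participants.csv \
    --out doses
```

or equivalently `python analysis/01_simulate_cohort.py` …
`05_reference_checks.py`. On the seed-42 cohort this prints

```
highest cohort-average organ doses (mSv/MBq):
spleen                  0.153
red_marrow              0.107
urinary_bladder_wall    0.090
effective dose: 0.033 +/- 0.006 mSv/MBq
```

i.e. the spleen is the highest-dosed organ, red marrow second, with an
effective dose a little above 0.03 mSv/MBq — the magnitudes expected for a
rapidly renally cleared, marrow-avid Cu-64 tracer. The residence script also
confirms `total + remainder = 18.32 h` to machine precision for every
participant, and `analysis/02_fit_kinetics.py` reports a median residence-time
recovery error of ~2% at 5% measurement noise.

All times are hours post-injection; activities are decay-corrected fractions
of injected activity; doses are mSv/MBq.

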