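# Methods

This note records the statistical model behind `laceroc`, the choices made
where the published algorithms leave room, and what the synthetic cohort
does and does not emulate.

## The LACE index

Each discharge episode is scored

    total = L + A + C + E,  total ∈ [0, 19]

with L (0–7) from length-of-stay bins {<1 day → 0, 1 → 1, 2 → 2, 3 → 3,
4–6 → 4, 7–13 → 5, ≥14 → 7}, A = 3 for an emergent/unplanned admission and 0
otherwise, C (0,1,2,3,5) from the Charlson index (0→0, 1→1, 2→2, 3→3, ≥4→5),
and E = min(ED visits in the prior 6 months, 4). Both bin tables ship as CSV
data files rather than constants so alternative dialects can be swapped.

**E-component dialect.** Descriptions of the index disagree on whether E is
a five-level count component (0–4) or a binary one (0 or 4). The default
`count_capped` dialect follows the original scoring algorithm (one point
per visit, capped at 4); `--e-dialect binary` implements the binary
reading (0 if no visit, 4 if any). Both respect the 0–19 total; the choice
is exposed rather than guessed.

## Charlson comorbidity from ICD-10

Codes are normalized (uppercase, dots stripped) and matched by prefix
against the Quan et al. (2005) enhanced ICD-10 table for the 17 Charlson
condition groups — the standard coding for ICD-10 hospital abstracts.
Weights are the original Charlson weights (1 for the first ten groups, 2
for diabetes with complications / paraplegia / renal disease / malignancy,
3 for moderate-severe liver disease, 6 for metastatic solid tumour and
HIV/AIDS); whether a given study used original or updated weights is often
unstated, and the original weights are the deliberate default here. Three
severity hierarchies are applied (complicated diabetes over uncomplicated,
moderate/severe liver over mild, metastatic over any malignancy): the
flags record every matched group, the index counts only the severe member.
Unrecognized codes are ignored (DEBUG-logged), never errors: discharge
abstracts routinely carry codes outside the Charlson universe.

## ROC estimation

With the positivity rule "score ≥ t", sensitivity(t) is the fraction of
events at or above t and specificity(t) the fraction of non-events below
it, tabulated on the integer grid [min score, max score + 1]. The AUC is
the Mann–Whitney concordance probability with ties counted ½, computed from
the rank-sum identity; it equals the trapezoidal area under the ROC polygon
exactly, which the tests assert to 1e−12 alongside an all-pairs brute-force
oracle. The default AUC standard error is Hanley–McNeil (1982) — the
default of the major commercial statistics packages, so the natural choice
when mirroring published tables — with DeLong (1988) available via
`ci_method="delong"` as a cross-check. The P value reported against
AUC = 50% is a two-sided z-test on that standard error.

The Hanley–McNeil interval is approximate (it plugs the point AUC into an
exponential-model variance); a coverage test in the suite checks ≥ 90%
empirical coverage of a 95% interval over 1,000 binormal cohorts rather
than asserting nominal coverage.

## Two-graph threshold derivation

Sensitivity and specificity are treated as piecewise-linear functions of
the threshold between grid points. Their crossing θ₀ — sensitivity starts
at 1 above specificity, and the difference is non-increasing — is found by
linear interpolation within the sign-change segment; if the two curves
coincide over a flat segment, θ₀ is the segment midpoint (a documented
tie-break). Linear interpolation is asserted as this package's definition,
not as fidelity to any particular legacy implementation whose scheme is
unpublished. The intermediate-range bounds solve sensitivity(t) = level
(lower) and specificity(t) = level (upper) the same way; the level defaults
to 0.95 and 0.90 is supported (a lower level always narrows the range).
Bounds that are unattainable inside the score range are clipped to the
range end and flagged, never silently extrapolated.

Likelihood ratios at fractional thresholds use the same interpolation, so
an LR at θ₀ = 9.6 is well defined; on integer scores a half-point
threshold like 11.5 flags exactly the episodes a threshold of 12 would,
and this equivalence is unit-tested.

## Synthetic cohort

The generator emulates the *structure* of a two-year adult
unplanned-admission cohort: five age bands (18–49.9, 50–59.9, 60–69.9,
70–79.9, ≥80; top band truncated at 107 years) of sizes 8,403 / 4,304 /
4,739 / 6,068 / 8,756, with band-specific outcome rates — six-month
mortality 0.5/2.0/4.8/7.7/15.6%, thirty-day mortality 0.2/0.7/1.8/2.9/6.0%,
frequent (≥2 in 28 days) readmission 1.0/1.5/2.4/3.3/6.7%.

Component distributions (no published source specifies them; chosen once as
plausible for an acute admissions case mix):

| component | distribution | default |
|---|---|---|
| length of stay | geometric on {0,1,…} | mean 4 days |
| acuity emergent | Bernoulli | p = 1.0 (unplanned admissions only) |
| ED visits (6 mo) | Poisson, truncated | mean 1, cap 10 |
| Charlson index | categorical on 0–10 | truncated geometric, ratio 0.55 |

Each episode's Charlson index is drawn directly and, by default, realised
as a minimal ICD-10 code set that reproduces it through the coding module
(e.g. index 7 → {B20, I21}), so downstream re-scoring from codes exactly
recovers the generation-time score — a property the tests assert. Setting
`emit_icd10=False` leaves the code sets empty.

Outcomes follow a per-band logistic model on the episode's LACE total s:

    logit P(outcome | s) = c_band + β (s − mean_band(s))

β (`discrimination_slope`, log-odds per LACE point, scalar or per-band)
controls discrimination: β = 0 decouples score and outcome (AUC ≈ 0.5) and
the AUC is non-decreasing in β. The intercept c_band is calibrated by
Brent root-finding so the band's mean event probability equals its target
rate to 1e−6 (the mean logistic probability is strictly increasing in the
intercept, so the root is unique; for β = 0 the closed form logit(rate) is
used). Target rates of exactly 0 or 1 have no finite intercept and are
generated as constant outcomes. The default β = 0.5 was chosen once from
the binormal approximation AUC ≈ Φ(β·σ_s/√2) with the generator's score SD
σ_s ≈ 2.4, which lands the overall six-month-mortality AUC near 0.80 —
the realistic operating regime for this class of score.

Thirty-day death is a Bernoulli thinning of six-month death with
conditional probability equal to the band's rate ratio, which enforces the
subset invariant by construction. Readmission counts are drawn from a
Poisson whose mean λ_band solves P(X ≥ 2) = frequent-readmission rate,
conditioned on the frequent flag from the logistic model (non-frequent
episodes draw from {0,1}, frequent ones from {2,…}); the marginal count
distribution and the score–outcome link are therefore controlled jointly.
"Frequent" is always derived downstream as count ≥ 2, never stored.

**What the generator does not emulate.** Episodes are independent: there is
no within-patient correlation across admissions, no seasonality, sites or
discharge destinations, and no survival times beyond the two binary
horizons. Component draws are mutually independent, whereas in real
cohorts length of stay, comorbidity and ED usage are correlated with age
and with one another. Consequently, passing tests demonstrate that the
*analysis chain* is correct and calibrated — not that any particular
hospital's age gradient of AUCs or thresholds will be reproduced; with a
shared β, band-to-band differences in the reports come only from event
rates and sampling noise. A per-band β can plant a gradient, and one
pipeline test uses exactly that to verify the stratification plumbing.

## Numerical and reporting choices

- Root-finding uses `scipy.optimize.brentq` on [−60, 60] (intercepts) and
  (0, 60] (Poisson means) at xtol 1e−12.
- Report rounding mirrors clinical-table precision: AUC and CI in percent
  to 1 dp, LRs to 2 dp, θ₀ and IR bounds to 1 dp, P values below 0.001
  printed as "<0.001".
- A stratum with zero events (or zero non-events) for an outcome yields an
  undefined cell with a logged warning; the run continues.
- `LR+ = ∞` at perfect specificity is a flagged value, not an error.
- Reports are byte-deterministic for a fixed input and configuration (no
  timestamps in the payload).
- The study treats each episode as the analysis unit and does not
  deduplicate patients; report rows are labelled accordingly.
- An optional upstream filter drops episodes with cancer (C00–C97) or
  obstetric (O00–O99) codes, off by default for synthetic data.

## Problem sizes in the test suite

The suite runs the statistical checks at sizes chosen to make their
assertions well-powered while keeping the whole run around a quarter of a
minute: exhaustive LACE grids (≈15k combinations), all-pairs AUC oracles at
n ≤ 200, 1,000 cohorts of n = 500 for CI coverage, n = 50,000 for planted
equal-error-threshold recovery (tolerance 0.25 points), and 20,000 episodes
per band across four seeds for rate calibration against 99% binomial
intervals (requiring ≥ 95% of band × outcome cells inside, the expected
pass rate under exact calibration).
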