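# Methods

## The scoring model

Functional heart age is a deterministic function of two left atrial (LA)
measurements taken from four-chamber cine CMR: end-systolic volume (ESV, mL)
and ejection (emptying) fraction (EF, %). Three linear segments cover the
ESV axis — below 15 mL, 15–50 mL, above 50 mL — with the extreme segments
deliberately flat so that rare very small or very dilated atria do not
extrapolate to absurd ages. An EF threshold correction is then added: low
atrial emptying fraction marks reduced pump efficiency and ages the
prediction in steps (+20 / +15 / +5 / +2 years below 55 / 58 / 60 / 62 %).

Two conventions are not determined by the printed equations and are fixed
here once:

- **Segment boundaries.** At exactly 15 or 50 mL the mid segment applies
  (membership `[0,15)`, `[15,50]`, `(50,∞)`). The printed segment functions
  are discontinuous at the breakpoints, so the convention matters; the mid
  segment is the best-characterized one and gets the boundary points.
- **EF bands.** The printed band labels overlap at their endpoints
  ("55–58", "58–60", "60–62"); bands are half-open `[lower, upper)` so each
  EF maps to exactly one band, and EF ≥ 62 % adds nothing.

Predictions are floored at 0 years (flagged, never silently); missing
inputs raise — the model performs no imputation. Parameters are data, not
code: they ship in `src/heartage/data/default_model.yaml` and re-derived
models are drop-in replacements.

## Chamber volumetry

Volumes use the single-plane area–length estimate V = 8A²/(3πL). Only
four-chamber (single-plane) contours are modelled, so the biplane variant is
out of scope. From a volume–time curve: EDV = curve maximum (the
end-diastolic phase is located, not assumed at the trigger), ESV = minimum,
SV = EDV − ESV, EF = 100·SV/EDV, CO = SV·HR. Peak ejection/filling rates
are the extreme central differences of the cyclically extended curve over
the ejection (ED→ES) and filling intervals respectively, reported positive
in mL/s, with no smoothing — smoothing choices belong to the acquisition
software, not the metric definition. GLS = 100·(min L − max L)/max L,
negative for shortening, applied with the same convention to atria and
ventricles. LV mass = (V_epi − V_endo at ED) × 1.05 g/mL; the density is a
standard literature constant exposed as `MYOCARDIAL_DENSITY_G_PER_ML`.

## Model derivation

The derivation pipeline reconstructs how such a score is built from a
healthy cohort:

1. **Screen** every chamber metric against chronological age (Spearman ρ,
   two-sided p), attach per-decade medians over the seven age strata
   (10–19 … 70–85), and flag "complex" variables whose decade-median curve
   flips slope sign at least twice.
2. **Prune collinear candidates** (|pairwise ρ| ≥ 0.8 by default), keeping
   the variable ranked higher in a physiological relevance ordering. The
   ordering is user input; a default ranking (atrial volumetry first) covers
   the package's own schema. Greedy processing over the ranking makes the
   result independent of input order.
3. **Interpolate extremes.** Rather than fitting nonlinear models to the
   sparse tails, synthetic anchor points continue the mid-range OLS line
   beyond the breakpoints with a *blunted* slope — `blunt_fraction`
   (default 0.25) of the mid slope — anchored at the mid-fit value at the
   cut. Anchors lie strictly outside the mid range and are flagged
   synthetic. This is a parameterized reconstruction of the study-style
   "interpolated extremes" idea, not a published table.
4. **Fit** independent OLS lines per segment (≥ 3 points each).
5. **EF-band bias.** Offsets are per-band medians of
   (chronological − base prediction), monotonized non-increasing in EF by
   pool-adjacent-violators (weights = band counts), with the ≥ 62 % band
   pinned to 0 (so offsets are non-negative). Empty bands inherit the
   nearest populated lower-EF band and are flagged.

Derivation refuses cohorts containing comorbid subjects unless explicitly
overridden.

### Recovery studies

Two seeded Monte-Carlo studies quantify the fitter, at sizes chosen to
mirror a derivation cohort:

- **Slope recovery**: 169 design points spanning the three segments (90 %
  mid), age = piecewise(ESV) + N(0, 5 y), 100 replicates; the median
  absolute relative error of the mid-segment slope is ≈1 % (asserted < 5 %).
  Response-side noise is the standard design for validating a regression
  fitter; note that when scatter is instead placed on the *predictor* (as
  the cohort generator does for LA ESV), OLS of age on ESV is attenuated by
  σ²_noise/σ²_ESV — with 5-year-equivalent scatter that is a real ≈5–8 %
  downward bias, which is a property of errors-in-variables regression, not
  of this implementation.
- **EF-offset recovery**: 300 subjects balanced across the five EF bands
  (the natural designed experiment for band-wise offsets), true offsets
  (20, 15, 5, 2, 0), noise sd 3 y, 50 replicates; every offset is recovered
  within ±2 years.

## Synthetic cohorts

The generator's purpose is a cohort on which ground truth is known exactly:

- Ages are uniform on 10–85 y by default (the study-style seven-group size
  weighting is available as a preset).
- LA EF follows a piecewise-linear decline 66 → 55 % with a knee at
  (50 y, 64 %) — slow drift before the fifth decade, steeper after, which
  matches the described acceleration of atrial decline and places the
  healthy median EF near 64 % — plus N(0, 3) jitter.
- LA ESV is the *inverse of the full scorer* at (age − EF-band correction):
  with zero noise, `predict_heart_age` returns chronological age exactly on
  the interior domain, which is what makes the agreement statistics
  testable (Bland–Altman bias exactly 0, ρ = 1). Outside the mid segment's
  age span the inverse continues with the blunted slope used by the
  derivation, keeping the age→ESV map continuous and monotone. Noise
  (`noise_sd_years`, default 5 y, converted to mL via the mid slope) is
  added to ESV.
- All other chamber metrics are log-normal/normal marginals whose medians
  sit at published healthy medians, coupled by a shared per-subject "heart
  size" factor (sd 0.10 on the log scale); SV/EF/CO identities hold exactly
  by construction. LV EF is truncated at 50 % (the cohort inclusion rule).
- Unhealthy cohorts apply per-metric shifts whose defaults reproduce the
  direction and rough magnitude of the published healthy-vs-unhealthy
  median contrasts (LA ESV ×28/23, LA EF −3, LV mass ×111/85, …), sample
  comorbidity flags at the published prevalences, draw a right-skewed BMI
  (median 27.5, ≈29 % obese, ≈2 % class III), force BMI ≥ 25 for subjects
  with no disease flag (overweight is itself a qualifying condition), and
  push LA volumetry toward the obesity-class medians (class III: ESV ≈54 mL,
  EF ≈49 %, which scores > 100 y).

What the generator does *not* emulate: scanner/vendor/site effects,
longitudinal within-subject change, realistic cross-metric correlation
beyond the single size factor, survivor bias at old age, or treatment
effects in the comorbid group. Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline, not clinical
performance on real patients.

Contour synthesis inverts the volumetry: raised-cosine volume curves hit
the record's EDV/ESV exactly at the extreme phases (phase count even,
≥ 8), lengths scale so GLS matches the record, and the LV epicardial series
carries a constant myocardial shell reproducing LV mass at 1.05 g/mL.

## Validation statistics

- **Bland–Altman**: percent mode divides by the pair mean (the standard
  denominator); limits of agreement are bias ± 1.96·SD and are reported
  alongside the t-based CI of the bias, because clinical summaries often
  print the LoA where a "95 % CI" is announced — both are labelled
  explicitly here.
- **Spearman CI**: Fisher z with Bonett–Wright SE √((1 + ρ²/2)/(n−3)).
- **Group comparison**: Mann–Whitney U (asymptotic, tie-corrected) for two
  groups; Kruskal–Wallis otherwise, with Dunn z-tests (tie-corrected,
  Holm-adjusted) only when the omnibus p < 0.05.
- **Stepwise OLS**: univariate screen at p < 0.05, forward entry at 0.05,
  backward removal at 0.10 — conventional thresholds, exposed as arguments.
- **Heart-age gaps**: per-group one-sample t-tests of (functional −
  chronological) against zero; boolean comorbidity groupings additionally
  get an independent-samples t-test between flagged and unflagged subjects.

## Numerical choices and edge cases

- Degenerate Bland–Altman inputs (SD = 0) return p = 1 for exact agreement
  and a point CI rather than NaN.
- Numerically perfect Spearman correlations (|ρ| within 1e-12 of 1) are
  clamped to ±1 with a point CI.
- Flat volume curves are a hard error (no ejection), not a zero.
- Test problem sizes (cohorts of ~200–2000, 50–100 Monte-Carlo replicates)
  were chosen so the full suite runs in seconds while keeping Monte-Carlo
  margins comfortably away from their thresholds.

## Known limitations

- The blunted-anchor interpolation is this package's concrete, documented
  reconstruction of an under-specified development step; re-derived extreme
  segments equal the blunted continuation, not the shipped extreme
  coefficients, unless the data themselves follow those coefficients.
- The derivation estimates EF offsets once, after the segment fit, rather
  than iterating fit ↔ correction to convergence; on data where EF-band
  steps and the ESV trend are confounded (EF a deterministic function of
  age) the decomposition is not identifiable anyway.
- Single-plane area–length volumetry and the fixed 1.05 g/mL density are
  conventions, adequate for synthetic data and method testing, not a
  replacement for scanner-calibrated analysis software.
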