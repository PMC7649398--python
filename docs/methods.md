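# Methods

This note records the model as implemented, the choices made where the
source material was ambiguous, what the synthetic herds do and do not
emulate, and the package's numerical conventions and limitations.

## Model structure and assumptions

Excretion is predicted per animal and per day, in grams, by closing
nutrient balances around measured intake:

1. **Intake.** For each diet entry, net fresh intake (offered − leftover)
   times the feed's DM concentration gives the feed's DM intake; summing
   over feeds gives DMI, and weighting by the feed's digestible-DM, crude
   protein and P concentrations gives DDMI, CPI and PI. N intake is
   CPI/6.25 (Kjeldahl), indigestible DMI is DMI − DDMI, and the
   measurement-derived ("actual") faecal N is IDMI × faecal N
   concentration. Leftovers are assumed to have the composition of the
   offered feed and are subtracted per feed.
2. **Faecal N.** The Lucas relation DN = m·TN + b is an empirical
   regularity across feeds; on the quantity basis it yields
   Q_FN = (1 − m)·TNI − b·DMI/100. Defaults m = 0.92,
   b = −0.60 g/100 g DMI (survey-calibrated); the literature pair
   (0.92, −0.61) ships as the `literature` preset.
3. **Retention.** Milk N = yield × protein/6.38. Pregnancy retention uses
   the metabolizable-protein requirement
   MP_Preg = ((0.69·t − 69.2)·CBW/45)/0.33 over gestation days 190–279
   and N_Preg = MP_Preg/6.25; conceptus P accretion is the first
   difference of the cumulative curve 0.02743·e^((0.05527−0.000075t)·t).
   Growth retention applies to young stock only, through the NRC chain
   (net energy for gain → shrunk weight gain → retained energy → net and
   metabolizable protein); lactating and dry cows are assumed at zero
   protein balance for growth. Scurf protein 0.3·BW^0.6 is credited to
   all classes. Growth P is (1.2 + 4.635·MW^0.22·BW^−0.22)·WG/0.96 with
   WG in kg/d.
4. **Balances.** Q_UN = TNI − N_Ret − Q_FN; Q_TN = Q_FN + Q_UN;
   Q_FP = PI − P_Ret (urinary P neglected). Negative residuals — possible
   with measurement error — are clamped to zero and flagged on the
   result, never silently propagated.

Herd summaries report class means ± SE (SD/√n) and herd means weighting
every animal equally. Fractions of intake (N retained / faecal / urinary,
P retained / faecal) are ratios of herd means, not means of per-cow
ratios, so the N shares sum to one whenever no animal was clamped.
Reported tables round excretion quantities to whole grams; all internal
arithmetic is unrounded.

## Ambiguities resolved

* **Pregnancy-protein bracket.** The printed form of the MP_Preg equation
  can be read with the calf-birth-weight scaling applying to the whole
  requirement or only to its intercept term. The implementation scales
  the whole requirement (matching the NRC source convention); the
  alternative reading is available via
  `DesignConstants(cbw_scales_whole_mp_preg=False)`. The two coincide at
  CBW = 45 kg.
* **Growth-protein denominator.** The published MP_Growth expression has
  an unbalanced parenthesis; it is implemented as
  NP_g/(0.834 − EQSBW×0.00114). For animals at or below their mature
  weight EQSBW ≤ 478 kg and the denominator is safely positive; it is
  still guarded with a diagnostic error because the constants are
  configurable.
* **Weight-gain units.** Survey weight gain is recorded in g/d, but the
  exponentiated NRC forms (WG^1.2, WG/0.96) only produce physiological
  magnitudes with WG in kg/d; conversion happens inside the retention
  functions, at the type boundary.
* **Schoorl girth–weight relation.** The survey convention
  BW = (girth + 22)²/100 (girth in cm, BW in kg) is implemented from the
  cited literature convention, as the survey report does not print the
  formula. It is used only when no explicit live weight is given.
* **Lucas-parameter plausibility.** True digestibility must be positive;
  m > 1 or b > 0 are physically implausible but can arise from a
  legitimate OLS fit on noisy data (the slope SE on an 86-cow split is
  ≈ 0.1), so they warn rather than error. Erroring here would make the
  calibration CLI unusable on exactly the data that most needs scrutiny.
* **Sample-size quantiles.** The two-arm design n = 2δ²/d² uses standard
  normal quantiles, δ = z₁₋α + z₁₋β (the sum of the two one-sided
  quantile magnitudes — the only reading that produces design-scale n).
  Model reliability ρ (the R² of predicted on actual) attenuates the
  standardized effect, d′ = d·√ρ, hence n ∝ 1/ρ. Reported n is the
  ceiling (whole animals); an iterated central-t variant is available via
  `quantiles="t"`. The population SD σ is a required user input — it is
  not derivable from the model itself.
* **MSE decomposition.** Bias (P̄−Ā)², slope (s_P − r·s_A)² and random
  (1−r²)·s_A² use population (1/n) standard deviations, under which the
  three terms sum to the MSE exactly; sample variances would break the
  sum-to-one property. Degenerate cases: zero MSE reports shares
  (0, 0, 1); zero variance on one side sets r = 0 in the closed forms.

## The synthetic herd generator

`synthetic.generate` emulates a 144-cow smallholder survey: class counts
106/12/26 (lactating/dry/young), six feeds, per-class per-feed DM-intake
distributions with means from the survey and SDs reconstructed as
SE × √n_class, per-class live weights (means 433/419/278 kg; SDs are not
published and are set to plausible herd spreads), lactating milk yield
13 ± 3 kg/d with protein 34 g/kg and P 0.6 g/kg, and dry cows 210–240
days pregnant. One feed-composition table is drawn per herd at the
standard error of the survey's laboratory means — a herd-level draw at
the sample-to-sample scatter (SE × √n) would instead act as a large
systematic assay bias shared by all cows.

Each cow's digestible-N concentration is set by the configurable truth
DN = m·TN + b + ε, ε ~ N(0, 0.16) g/100 g DMI, and its faecal N
concentration is then **back-derived** as (TNI − DNI)/IDMI × 1000, so the
generated measurements are exactly consistent with truth-plus-noise and
calibration is a genuine parameter-recovery problem. The noise SD 0.16
was chosen so that held-out relative RMSE of the calibrated model lands
at the error level a field survey of this kind exhibits (≈ 20 %).

Sampling uses a symmetric truncated normal on [0, 2·mean] (inverse-CDF),
which forbids negative masses without introducing a point mass at zero
and preserves the mean exactly — important because several reconstructed
SDs are comparable to their means. Draws are keyed by
(seed, stream, class, cow index): regeneration is bit-identical and
enlarging a class never perturbs previously generated cows.

What the generator does **not** emulate, and hence what green tests do
not establish about real surveys:

* farm-level clustering — cows are independent, so between-farm variance
  components are understated;
* intake–composition covariance — the published summary tables lose it,
  so the generator's expected class CPI sits ~2 % below, and expected PI
  up to ~8 % below, the published class means (P concentrations are
  printed with one significant digit). Unbiasedness tests therefore
  target the generator's analytic expectation, with the offset to the
  published targets asserted separately;
* seasonal or temporal composition dynamics, and leftover feeds (the
  generator writes net offers with zero leftovers; leftover handling is
  exercised by the I/O and intake tests).

## Numerical conventions

* All masses g/animal/d, concentrations g/kg, weights kg; conversions
  only at type boundaries.
* CSVs are read with round-trip float parsing; write→read reproduces
  every numeric field bit-exactly.
* The training split takes round(n × fraction) cows, rounding half away
  from zero (144 × 0.6 → 86/58); splits are seeded permutations.
* OLS is delegated to statsmodels; tests verify agreement with direct
  normal-equation solutions to 1e−10 relative.
* Pregnancy terms are exactly zero outside gestation days 190–279; a dry
  cow with no recorded gestation day contributes zero with a flag.
* Problem sizes in tests and the acceptance script: survey-scale herds
  are 144 cows; Monte-Carlo checks use 50 herds (distribution fidelity,
  acceptance parameter recovery) or 200 herds (calibration unbiasedness),
  sizes at which Monte-Carlo SEs are a few per mil of the quantities
  checked.

## Known limitations

* The retention equations are deterministic requirement models; real
  animals in negative energy balance mobilise body protein, which the
  zero-growth assumption for lactating and dry cows ignores.
* Published class-mean retention for dry cows (29 g N/d) is lower than
  the pregnancy-plus-scurf retention the implemented equations yield at
  the surveyed gestation stages (≈ 35–43 g N/d); the per-cow growth and
  pregnancy traces are exposed (`ExcretionResult.growth_trace`,
  retention components) so users can audit the difference rather than
  having it hidden by re-tuned constants.
* Calibration is plain OLS on concentrations: no errors-in-variables
  treatment, no per-cow weighting by DMI, no robustness to outliers
  beyond what the validation layer rejects.
* A single random train/test split mirrors the survey protocol; it is
  not a substitute for cross-validation when data are scarce.
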