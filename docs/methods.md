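# Methods

## Problem

Heat production (HP) of a lactating cow — the energy dissipated during the
utilisation of metabolisable energy — can be measured accurately by indirect
calorimetry in a respiration chamber, but chambers are scarce and slow.
Milk mid-infrared (MIR/FTIR) spectra are recorded routinely at every milk
test and encode the fat, protein and lactose content of the milk, i.e. its
energy *density*; milk yield supplies the *quantity*. `mirhp` implements and
evaluates calibrations that predict mBW-normalised HP from fused
spectrum-and-yield predictors.

## Indirect calorimetry

Daily HP in kJ/d is computed from gas exchange with the Brouwer equation,

    HP = 16.18 V_O2 + 5.02 V_CO2 − 2.17 V_CH4 − 5.99 N_u,

gas volumes in L/d, urinary nitrogen N_u in g/d. When N_u is not measured
it is assumed at 150 g/d; at typical gas volumes (V_O2 ≈ 6740 L,
V_CO2 ≈ 7072 L, V_CH4 ≈ 570 L) the N_u term contributes ≈ 0.63% of HP, so
the assumption costs at most ~1% accuracy. HP is normalised to metabolic
body weight mBW = BW^0.75 (kg^0.75), the allometric scale of maintenance
energy; the response modelled throughout is HP/mBW in kJ/kg^0.75/d. Inputs
carry a single BW per cow-day; users with separate pre- and post-chamber
weighings should average them before input.

## Spectral preprocessing

Transmittance is converted to absorbance A = log10(1/T) (base 10, the
mid-IR convention; the transform is validated channel-wise and its inverse
10^(−A) round-trips to 1e−12). Only the channels in the three informative
regions 968–1577, 1720–1808 and 2564–2965 cm⁻¹ are retained (closed
intervals, channels compared by exact grid value); these cover the
fat-associated triacylglycerol C–O (≈1175 cm⁻¹), ester C=O (≈1750 cm⁻¹)
and acyl C–H (2800–3000 cm⁻¹) bands, the amide bands for protein and the
C–OH band (≈1080 cm⁻¹) for lactose, while excluding the water-saturated
windows. The retained channel count is grid-dependent and never hard-coded
(the default uniform 1060-point grid over 925–5008 cm⁻¹ retains 285
channels). Gap-difference derivatives of order 1 or 2 are implemented but
off by default: they are a standard pre-treatment option, and the default
pipeline uses raw absorbance.

Outlier screening fits a SIMPLS model with all requested latent variables
at once, estimates a robust centre and scatter of the score matrix by the
minimum covariance determinant (coverage 0.75, via scikit-learn's
`MinCovDet`), and flags rows whose squared Mahalanobis distance exceeds the
χ²(n_lv) quantile at 1 − α (default α = 0.025). The screen is report-only
by default (`drop_outliers=False`); a singular robust scatter is ridged by
1e−10·trace/k before failing.

## Spectrum/yield fusion (M1, M2, M3) and the L1 baseline

Per cow-day, with AM/PM absorbance spectra a_am, a_pm and session yields
y_am, y_pm:

* **M1** = (a_am + a_pm)/2 — density only;
* **M2** = M1 · (y_am + y_pm) — density × daily quantity;
* **M3** = (a_am·y_am + a_pm·y_pm)/2 — session-weighted density × quantity.

M3 divides by 2, not by total yield, so that yield magnitude is retained in
the predictor; `m3_divisor="total_yield"` switches to a true weighted mean.
Milk yield enters only as a spectral multiplier; `append_yield_column=True`
exposes the alternative of adding yield as an extra predictor column.
**L1** is the univariate OLS of HP/mBW on daily yield (via statsmodels),
the yield-only baseline.

## SIMPLS

The PLS core is an original implementation of de Jong's SIMPLS for a single
response: predictors are column-centred only (no autoscaling — the
chemometric convention for absorbance; zero-variance channels therefore
receive zero weight rather than causing failure), each step takes the
deflated cross-product vector s = Xcᵀyc as the weight direction, normalises
the score to unit length, and deflates s against an orthonormal basis of
x-loadings re-orthogonalised twice per step to resist drift on collinear
spectra. Scores are exactly orthonormal (asserted to 1e−8 in tests); the
full coefficient path over LV counts is stored so one fit serves every
model size. Rank exhaustion truncates the path with a warning. For one
response SIMPLS and NIPALS PLS1 give identical predictions; the test suite
verifies this against scikit-learn's NIPALS to 1e−6 on random problems, and
verifies the full-LV solution against the minimum-norm least-squares
pseudoinverse to 1e−8.

## Validation

* **Random 10×10 CV.** Per iteration the observation indices are permuted
  (one `numpy.random.default_rng(seed)` stream, one permutation per
  iteration) and split into 10 near-equal folds; each fold is predicted by
  a model fitted on its complement at every LV in the search range. RMSE
  and R² are computed on the pooled out-of-fold predictions of the
  iteration and averaged over the 10 iterations (RMSECV, R²CV). Pooling
  before averaging was chosen over averaging per-fold statistics for
  stability at fold sizes near 17.
* **LV selection.** The LV count minimising RMSECV, ties broken toward
  fewer LVs. The search range defaults to 1..min(20, rank).
* **Calibration statistics.** Training-set RMSE and R² at the chosen LV.
* **External 4-fold CV.** One random partition into quarters; for each
  held-out quarter the LV count is re-selected by an inner 10×10 CV on the
  calibration three-quarters (preventing selection leakage), the model
  refitted and the quarter predicted; RMSEV and R²V are means of the four
  per-quarter values.
* **Metrics.** R² is 1 − SSE/SST (not squared correlation; switchable via
  `r2_definition`). CCC uses population (divide-by-n) moments and is
  computed on the pooled cross-validated predictions by default
  (`ccc_on="calibration"` switches). RPD divides the reference SD (n−1) of
  the observed response by RMSECV; `rpd_denominator="sep"` uses the
  bias-corrected standard error of prediction instead.

Seeds: one master seed drives the random CV; the external partition uses a
fixed offset of that seed, and inner CVs draw their seeds from the external
stream. All runs are bit-reproducible for a fixed dataset, config and seed.

## Synthetic-data generator

The generator emulates the structure of a twice-daily-milking respiration
chamber study with 84 cows × 2 cow-days (168 observations, 336 milkings):

* **Body weight** per cow: truncated normal 692 ± 80 kg on [500, 915] kg
  (mBW then spans ≈ 105.7–166.4 kg^0.75).
* **Daily yield** per cow-day: truncated normal 25.7 ± 10.3 L on
  [5.2, 51.4] L, split AM/PM as fraction 0.55 ± 0.03 (clipped so both
  sessions stay positive).
* **Composition** per cow-day (g/kg): fat 42 ± 12, protein 34 ± 6, lactose
  48 ± 2.5, truncated at ±3 SD. The spreads are wider than a single-herd
  snapshot because the emulated population mixes breeds, diets and
  lactation stages; composition variance is exactly the information spectra
  add beyond yield.
* **Milk energy density** e (MJ/kg) = 0.0384·fat + 0.0223·protein +
  0.0199·lactose — a generator convention giving ≈ 3.3 MJ/kg at the mean
  composition, not a literature equation.
* **True HP** (kJ/d) = 500·mBW + 0.8·1000·e·yield + N(0, 23000). The
  maintenance coefficient (500 kJ/kg^0.75/d) and milk multiplier (0.8) give
  HP/mBW ≈ 1000 kJ/kg^0.75/d at the mean; the noise SD was set from a
  variance budget so that default runs land in a moderate cross-validated
  R² regime (≈ 0.5–0.6) rather than a near-noiseless one, which is the
  regime in which comparing the fusion schemes is informative.
* **Gas exchange** is back-solved from true HP: CH₄ = 32 L/kg × a latent
  DMI ≈ 5 + 0.5·yield kg/d, V_O2 = (HP + 2.17·V_CH4 + 5.99·N_u)/(16.18 +
  5.02·RQ) with RQ fixed at 1.05, V_CO2 = RQ·V_O2, N_u = 150 g/d. The
  Brouwer round-trip is therefore exact by construction (tested to relative
  1e−9).
* **Spectra**: absorbance = baseline 0.05 + Gaussian bands (library above
  the fat/protein/lactose assignments, absorptivity × concentration) +
  channel noise N(0, 0.01 AU); the water windows 1577–1720 cm⁻¹ and
  > 3000 cm⁻¹ are clamped to absorbance 2.0 (saturation); transmittance is
  10^(−A) clipped to (0, 1].

What the generator does **not** emulate: within-cow covariance of repeated
measurements (cow-days are independent given cow-level BW, matching the
analysis assumption of independent observations), lactation-stage and diet
dynamics, session-level composition differences (AM and PM share one
composition, so M2 and M3 coincide up to a constant factor on synthetic
data and their comparison is only exercised for equality), scatter effects,
instrument drift, and the correlated, non-Gaussian noise of real FTIR
hardware. Passing tests therefore demonstrate that the machinery recovers
planted signal under the stated statistical structure — not that real-data
performance will match.

## Numerical choices and degenerate inputs

Rank tolerance 1e−12 (relative) for LV extraction; zero-variance response
is an error; constant predictor channels get zero coefficients; RMSECV ties
resolve toward fewer LVs; CCC of two identical constant series is 1, of two
different constant series 0 with a warning; R² with constant observations
is an error; fold sizes differ by at most one observation. Cow-days missing
either milking session are dropped, not imputed; fewer than 10 usable
cow-days is an error.

## Known limitations

* The PLS scale-equivariance property (rescaling a channel rescales its
  coefficient inversely, predictions unchanged) holds only at the full-LV
  solution, where SIMPLS equals minimum-norm OLS; intermediate-LV latent
  directions are scale-dependent, as for any covariance-based projection.
* The external-validation R² is computed within each quarter against the
  quarter's own mean, so it is noisier than R²CV at n/4 ≈ 42.
* RPD depends on the chosen denominator (RMSECV vs bias-corrected SEP);
  both are offered because published values rarely state which was used.
* On synthetic data the default run sizes are the emulated study sizes
  (168 cow-days, 285 retained channels); a full four-model run completes
  in a few seconds on one core.
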