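# Methods

This note records the models, defaults and design choices behind
`bosspls`, and what the synthetic experiments do and do not establish.

## Calibration model

PLS1 regression relates SNV-treated absorbance spectra to the adulterant
volume fraction *y* (% v/v).  The kernel is a NIPALS decomposition
written to return the regression coefficient vector for *every*
intermediate factor count from a single pass at the maximum count.
Cross-validating the factor count therefore costs one decomposition per
fold rather than one per (fold, count) pair; this is what keeps the BOSS
loop — thousands of cross-validated sub-models per run — affordable on
one CPU.  For a single response, NIPALS and SIMPLS agree to numerical
precision, and at the maximal factor count the fit equals ordinary least
squares; both facts are asserted in the test-suite against
scikit-learn's `PLSRegression` and a closed-form least-squares oracle.

Numerical edge rules:

- Factor extraction stops early when the covariance weight vector
  underflows (`‖Xᵀy‖ ≤ 1e-12` relative to the first iteration); the
  effective count is reduced with a warning and the coefficient path is
  padded with its last attainable vector.  A constant response yields
  zero coefficients and a mean-only model.
- Cross-validation folds are a seeded shuffle followed by contiguous
  near-equal blocks.  One fold assignment is shared by every sub-model
  in a BOSS run so that duplicate subsets give bit-identical results.
- Factor-count selection minimises RMSECV; ties break toward fewer
  factors.  The count is capped at `min(15, P, smallest fold-training
  size − 1)`.
- RMSECV pools all out-of-fold residuals before the root
  (`n_folds = N` gives exact leave-one-out).
- Calibration R² is computed from the pooled out-of-fold predictions,
  consistent with RMSECV (`R²_cal = 1 − N·RMSECV²/Σ(y−ȳ)²`); validation
  figures come from the model refitted on the whole calibration set.

## BOSS selector

Defaults: `K = 1000` bootstrap subsets per iteration, top 10 % extracted,
5-fold CV, 15-factor cap, seedable throughout.  Choices made where the
procedure admits more than one reading:

- **Weight update.**  `w_i = Σ_k |b|_{i,k}` over the *extracted*
  sub-models only, with the coefficient vector taken over the
  sub-model's own variables (intercept excluded), ℓ₂-normalised, then
  made absolute.  Variables absent from every extracted sub-model get
  weight 0 and are excluded from all later draws (soft shrinkage).
- **Draw count.**  The next iteration's draw count is the round-half-up
  mean of the extracted sub-models' distinct-variable counts (floor 1);
  averaging over all `K` sub-models instead is available as
  `draw_count_over="all"`.  A strict-shrinkage guard caps the next count
  at one less than the current one: once subsets are small, the rounded
  mean frequently equals the current count and the loop would otherwise
  stall indefinitely short of the single-variable stopping condition.
- **Stopping and choice.**  The loop ends after the iteration whose draw
  count is one (or when the weight support is a single variable).  The
  returned subset is the best (lowest-RMSECV) sub-model's variable set
  at the chosen iteration.  The default choice rule is the *first local
  minimum* of the per-iteration best-RMSECV trajectory
  (`r_t < r_{t−1}` and `r_t ≤ r_{t+1}`); `global_min` is available, and
  is also the fallback when the trajectory has no interior local
  minimum.
- **Ties.**  Sub-model ranking breaks ties by fewer variables, then by
  stable input order.  All sampling flows from one `numpy` generator
  seeded by the run seed, so identical configuration implies a
  bit-identical result.
- **Repeats.**  The pipeline can rerun BOSS with independent seeds
  (`repeats`) and keep the run with the lowest RMSECV at its chosen
  iteration, reflecting the common practice of reporting the best of
  several stochastic selection runs.

## Synthetic data generator

No public adulterated-EVOO spectra exist, so the generator emulates the
study design: five adulterant oils (peanut, sunflower, soybean, sesame,
maize) blended into EVOO at 2.5–50 % v/v in 2.5 % steps → 100 samples;
absorbance on a uniform descending 1557-point grid from 9999.10 to
3999.64 cm⁻¹; a random split keeping 3 calibration samples per
concentration level (60/40).  Concentration levels are exact nominal
values, and replicate averaging is represented by a reduced noise sd
rather than explicit triplicates.

Pure oils are sums of Gaussian bands on a low-order polynomial
background; mixtures follow ideal Beer–Lambert volumetric mixing, so
absorbance is exactly affine in the volume fraction — the relationship
PLS assumes.  The adulterants share the common triacylglycerol band
structure and differ from EVOO in the 5840–5925 cm⁻¹ first-overtone and
4420–4690 cm⁻¹ combination regions, one signature pair per species, so a
correct selector should concentrate there.

Measurement artifacts, per spectrum:

- multiplicative gain `m ~ 1 + N(0, 0.05)` and additive offset
  `b ~ N(0, 0.02)` — the family SNV removes exactly;
- i.i.d. point noise, sd 0.005 AU (replicate-averaged level);
- **interferent bands** (8800, 6890, 5240, 4850 cm⁻¹) whose amplitudes
  fluctuate as signed Gaussians with sd 0.05–0.08 AU: water-vapour and
  temperature-sensitive variation that SNV does *not* remove;
- **degraded regions** — detector roll-off above 9000 cm⁻¹ and
  near-total absorption below 4150 cm⁻¹ — with strongly elevated point
  noise (0.02 AU on the full grid).

The last two components matter: gain/offset/white-noise artifacts alone
are either removed by SNV or harmless to a full-spectrum PLS, and a
variable selector then has nothing to gain on validation data.
Uninformative wavenumbers only hurt — as they do in real FT-NIR — when
they carry structured or high-variance y-uncorrelated variation.
Amplitudes were fixed, before the test thresholds were frozen, so that
the full-grid default dataset has study-like difficulty: the
full-spectrum model lands at RMSECV ≈ 3.5 % v/v and validation
R² ≈ 0.96–0.97, the regime reported for comparable laboratory
calibrations.

**Planted benchmark** (`make_planted_dataset`): a 200-channel version of
the grid where all adulterants share one signature of 10 very narrow
bands (width 0.4 grid steps) centred exactly on distinct grid channels,
giving ground truth for selector recall.  Planted channels are drawn
only from clean regions (outside the degraded intervals and > 3σ from
interferent centres): signal planted under interference is partly
unmeasurable, and the benchmark is about the selector, not the
interference.  Because only 36 of 200 channels fall in the degraded
regions (vs 280 of 1557 on the full grid), the benchmark uses a harsher
per-channel severity there (0.2 AU) to represent a comparable overall
burden of uninformative variance.

What passing these tests shows: under linear mixing with realistic
scatter, structured interference and heteroscedastic noise, the selector
recovers a planted signal support (median recall ≥ 0.8 over 20 seeds)
and the reduced model predicts held-out samples better than the
full-spectrum model (median over the same seeds).  What it does not
show: performance on real oils, whose band shapes, collinearity
structure, temperature sensitivity and preparation errors the generator
does not model; nor anything about non-volumetric (chemically
interacting) mixtures.

## Problem sizes

The shipped experiments use `K = 200` bootstrap subsets per BOSS
iteration (vs the 1000 default), a 200-channel grid for the recovery
benchmark, and 20 seeds for the median-based assertions — sizes chosen
to keep the whole study reproducible on a single CPU in minutes while
leaving the assertions comfortably clear of their thresholds.  All of
them are parameters, not constants; `scripts/acceptance.py --n-subsets
1000` restores the reference setting.

## Known limitations

- With small `K`, the first-local-minimum rule can fire early on a noisy
  RMSECV trajectory, returning larger subsets than the archetypal
  10–20-variable selections; `global_min` and larger `K` sharpen it.
- Sub-model RMSECV is also the selection criterion, so the RMSECV at the
  chosen iteration is optimistically biased relative to validation
  error; judge the final model by its independent-set RMSEP/R².
- SNV is undefined for constant spectra (an error, deliberately) and
  introduces mild nonlinearity in noise-free data (division by a
  concentration-dependent row sd); the pipeline's exactness checks
  therefore bypass it.
- The CSV dialect stores wavenumbers to 2 decimals; reading snaps them
  back onto the exact uniform grid when deviations are within rounding.
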