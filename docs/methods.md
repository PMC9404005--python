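# Methods

## Scope and model

`chromlogd` estimates apparent octanol/water distribution coefficients
(log *D* at mobile-phase pH 7.0) for ionizable solutes from isocratic
reversed-phase retention on a silica-based C18 column, in two chromatographic
modes: ion suppression (IS-RPLC; 20 mmol/L ammonium dihydrogen phosphate
buffer, pH 7.0) and ion pair (IP-RPLC; the same buffer plus 10 mmol/L
tetrabutylammonium bromide). The statistical core is a family of linear
QSRR models

log *D*₇.₀ = β₁·log *k*_w + β₂·*n*_e + β₃·*A* + β₄·*B* + β₀

fit by ordinary least squares with intercept, where log *k*_w is the
LSS-extrapolated retention at 0% organic modifier and *n*_e, *A*, *B* are
the solute's net static charge and H-bond acidity/basicity descriptors
(supplied as inputs, e.g. from ACD/Labs; the package never computes them).
Single- and two-descriptor reductions of this form are also exposed
(`model1`–`model4`) to show how charge and H-bonding terms rescue the plain
log *D*–log *k*_w correlation when solute ionization cannot be fully
suppressed.

### Assumptions

* **LSS linearity**: log₁₀ *k* is linear in the methanol volume fraction φ
  over the measured range (φ = 0.10–0.80). Fits below the *R*² gate
  (default 0.99) warn but are not dropped.
* **Monoprotic-acid ionization**: reference log *D* for the weak-acid model
  compounds follows log *D* = log *P* − log₁₀(1 + 10^(pH−p*K*a)). Bases and
  polyprotic microspecies are deliberately not computed (a
  `NotImplementedError`, never a silently wrong branch); such solutes get
  their log *D* from the retention models instead.
* **Mode equivalence for neutrals**: ion-pair reagent does not affect
  neutral-solute retention, so log *k*_w-IS ≡ log *k*_w-IP for the neutral
  class. The container warns when a dataset violates this.
* **Homoscedastic OLS**: coefficients carry classical standard errors from
  the unbiased residual variance; no weighting, selection or regularization.

## The cascade

Stage 1 fits the four-descriptor model on the 46 compounds with reference
log *D* (26 neutrals N1–N26 + weak acids W1–W20) against log *k*_w-IS and
labels the 19 ionized solutes that retain in IS-RPLC (W22–W26, W28–W32, S1,
S3–S5, S7–S9, S11, S12). Stage 2 fits the same form against log *k*_w-IP on
the 62-compound mixed model group: the neutrals, W2–W19, and 18 of the
stage-1-labeled solutes — S12 is reserved as an external-validation
reference and never trained on, and W1/W20 are held out likewise. The
stage-2 response uses the reference log *D* where one exists and the
stage-1 label otherwise. Training-set sizes are asserted (46 and 62) and
any mismatch fails loudly rather than silently refitting on a different
*N*. Prediction targets missing from a dataset are skipped; they never
affect training.

External validation predicts the three held-out solutes
(pentachlorophenol, benzoic acid, S12) with the stage-2 model and reports
signed errors against the reference precedence *literature (SFM/SSM) →
stage-1 label → software-calculated*. The relative-error criterion is
|predicted − reference| / |reference| ≤ 0.10 by default; the denominator
convention is configurable and zero-reference rows are excluded from
relative metrics with a note. Rows violating the bound are flagged, never
dropped: on the packaged table pentachlorophenol exceeds it (refit
prediction 3.22 vs reference 2.80) and is reported with a discrepancy flag.

## Data handling

The packaged table stores all 73 published rows verbatim, including
typography, with `NA` (no literature value) and `/` (not measurable)
preserved as missing-value provenance. Two data-quality repairs/decisions:

* **N5/N6 transposition.** As stored, anisole (log *P* 2.11) carries
  log *k*_w 5.60 and benzyl chloride (log *P* 5.50) carries 2.64 — each
  pair wildly off the Collander trend the other 71 rows follow, and fits on
  the literal table cannot reproduce the established models (stage-1 *R*²
  drops from 0.96 to 0.88). Exchanging the two log *k*_w entries restores
  both rows to the trend and reproduces all published fits within
  two-decimal rounding. The repair is explicit
  (`with_swapped_retention`), on by default in the cascade and pipeline,
  and can be switched off for literal replication. The alternative reading
  (transposed log *P* instead) yields nearly identical regressions; the
  log *k*_w swap was preferred because it leaves each compound its
  literature log *P*.
* **Single-predictor reference statistics.** The published fit statistics
  for the plain log *D*–log *k*_w-IS model (slope −0.072, *R*² 0.1745)
  cannot be obtained from the stored table under any reading tried (the
  refit gives slope ≈ 1.50, *R*² ≈ 0.90 on the repaired table, 0.76
  literal); all multi-descriptor models reproduce closely. The package
  reports its own refit and leaves the disagreement visible rather than
  special-casing it. The qualitative nested-model ordering
  *R*²(full) ≥ *R*²(two-descriptor) ≥ *R*²(single) still holds.

`select_by_ids` rejects duplicate requests so training *N* counts stay
auditable; duplicate ids in a table are a hard error.

## Retention numerics

* Retention factor *k* = (t_R − t_0)/t_0 (the universal definition; a
  `denominator="tr"` switch exists for replicating sources that print the
  (t_R − t_0)/t_R variant, whose log *k*_w values would otherwise be
  incommensurable).
* DP-RTC is the affine map fixed exactly by two reference compounds'
  observed/nominal times, applied before *k* computation when reference
  columns are present, skipped otherwise. Coincident anchors are a
  singular-anchor error.
* Replicate injections are averaged at the (compound, mode, φ) level before
  fitting.
* LSS fits use simple linear regression of log₁₀ *k* on φ; base-10
  logarithms throughout. When the residual sum of squares vanishes
  (noiseless or saturated two-point data) *R*² is reported as 1 by
  convention. Fewer than 4 points warns; fewer than 2 distinct φ levels is
  a singular-design error; *k* ≤ 0 is a domain error naming the
  measurement.

## Synthetic data generator

`SyntheticConfig` defaults emulate the reference measurement design:
descriptors uniform over the table's spans (log *k*_w ∈ [0.2, 5.7],
*n*_e ∈ [−2, 0], *A* ∈ [0, 1.6], *B* ∈ [0, 1.9]); true coefficients of
model-6-like magnitude (1.1, 2.4, 0.1, −1.6, intercept 0.1); residual SD on
log *D* of 0.1; a φ grid of 0.10–0.80 in steps of 0.10 (≥ 4 levels
enforced); LSS slopes uniform in [2, 5] (typical methanol values for small
aromatics); retention-time noise SD 0.01 min on a 1.0 min dead time; times
floored just above t_0. Grid points where the noiseless *k* falls below
10⁻³ are dropped and fully unretained solutes are flagged and excluded,
emulating strong ionized solutes in IS-RPLC. A bootstrap mode resamples
descriptor rows from a template set for realistic joint distributions;
the default uniform sampling deliberately ignores descriptor correlations.

What passing recovery tests show: the pipeline's estimators are unbiased
and correctly calibrated *under the linear model with independent Gaussian
noise*. They do not exercise ion-pair equilibria, silanol secondary
interactions, pH-dependent retention mechanisms, or descriptor measurement
error — real-data performance rests on the external validation, not on the
simulations.

## Problem sizes and determinism

Everything runs on the 73-row table in well under a second; the recovery
study uses 500 replicates of 50 solutes × 8 φ levels (about a minute on one
CPU) with seeds derived deterministically from a base seed. The report
bundle uses fixed float formatting and no timestamps, so two runs on the
same inputs are byte-identical.

## Known limitations

* The ionization correction covers monoprotic acids only, by design.
* The published polyvinyl-alcohol-column model is stored for cross-column
  comparison only; no underlying data exists here to refit it.
* Stage-2 labels inherit stage-1 model error; the package propagates no
  label uncertainty into stage-2 standard errors (matching standard
  practice for this workflow, but the stage-2 SEs are accordingly
  optimistic).
* Predictions are extrapolations for solutes whose descriptors leave the
  training span — pentachlorophenol's flagged validation row is the
  in-package example.
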