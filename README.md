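# chromlogd

Apparent *n*-octanol/water distribution coefficients (log *D*) of weakly and
strongly ionized compounds from reversed-phase LC retention, via cascaded
QSRR (quantitative structure–retention relationship) models.

## The problem

log *P* — the octanol/water partition coefficient of a compound's neutral
form — anchors drug design, environmental risk assessment and biodegradation
studies. For ionizable compounds the pH-dependent apparent coefficient
log *D* is the relevant quantity. RPLC estimates both cheaply: retention
extrapolated to a 100% aqueous mobile phase (log *k*_w, via the linear
solvent strength relation log *k* = log *k*_w − *S*·φ) correlates linearly
with log *D* across structurally similar model compounds.

Strongly ionized solutes (sulfonic acids, polycarboxylic acids) break this
scheme twice: they have essentially no experimental log *D* values to train
on, and they are unretained in ion-suppression RPLC (IS-RPLC) even at 10%
methanol. Ion-pair RPLC (IP-RPLC, here with tetrabutylammonium bromide)
restores their retention, but there are still no same-type model compounds.

`chromlogd` implements the two-stage cascade that bridges the gap on a
silica-based C18 column at pH 7.0, using three solute descriptors — net
static charge *n*_e, H-bond acidity *A* and H-bond basicity *B* — to connect
different compound types in a single model:

1. **Stage 1 (IS-RPLC).** Fit
   log *D*₇.₀ = *a*·log *k*_w-IS + *b*·*n*_e + *c*·*A* + *d*·*B* + *e*
   on 26 neutral compounds plus 20 weak carboxylic/phenolic acids whose
   log *D*₇.₀ follows from literature log *P*/p*K*a via the monoprotic-acid
   correction log *D* = log *P* − log₁₀(1 + 10^(pH−p*K*a)). Use the fit to
   label the 19 ionized solutes that are retained in IS-RPLC (*N* = 46,
   *R*² ≈ 0.96).
2. **Stage 2 (IP-RPLC).** Refit the same form on log *k*_w-IP over the
   62-compound *mixed model group* — neutrals, weak acids, and the stage-1
   labeled solutes — and predict the 8 strongly ionized solutes retained
   only with ion-pair reagent (*N* = 62, *R*² ≈ 0.95). Validate externally
   on held-out compounds of three different types.

The package ships the 73-compound reference table this workflow was
established on, the retention toolbox (retention factors, double-point
retention-time correction, LSS extrapolation with an *R*² ≥ 0.99 quality
gate), the ionization correction, the OLS/QSRR layer with classical
standard errors, external-validation reporting, and a synthetic-data
generator with known ground truth for parameter-recovery testing.

## Worked example

```python
from chromlogd import load_reference_table, run_cascade

result = run_cascade(load_reference_table())
print("stage 1 (IS-RPLC):", result.stage1.equation())
print("stage 2 (IP-RPLC):", result.stage2.equation())
print("benzenesulfonic acid   ", round(result.stage1_predictions["S1"], 2))
print("1,5-naphthalenedisulfonic acid", round(result.stage2_predictions["S2"], 2))
```

prints

```
stage 1 (IS-RPLC): log D = +1.110(±0.079)·log_kw_is +1.647(±0.297)·n_e +0.603(±0.507)·a -1.244(±0.454)·b +0.025(±0.341)   (N=46, R²=0.9611)
stage 2 (IP-RPLC): log D = +1.090(±0.079)·log_kw_ip +2.373(±0.167)·n_e +0.197(±0.248)·a -1.566(±0.324)·b +0.080(±0.317)   (N=62, R²=0.9453)
benzenesulfonic acid    -2.2
1,5-naphthalenedisulfonic acid -4.71
```

The near-unit coefficient on log *k*_w confirms the Collander-type
retention–lipophilicity link; the large positive *n*_e coefficient captures
the extra electrostatic retention that dissociated silanols on a
silica-based column exert on charged solutes. Benzenesulfonic acid, fully
ionized at pH 7, comes out 2.2 log units more hydrophilic than its neutral
form would be; the disulfonic acid lands near −4.7. Held-out validation
(see `examples/04_external_validation.py`) predicts benzoic acid at −0.97
against a literature −0.93 — a 4% relative error.

The `examples/` directory holds one short narrative script per capability:
ionization correction, LSS extrapolation, the cascade, external validation,
and synthetic-data parameter recovery. A thin CLI mirrors the library:

```sh
chromlogd reproduce --out report/      # full pipeline + report bundle
chromlogd logd --logp 1.87 --pka 4.20  # -0.93
chromlogd cascade | head               # models + predictions as JSON
chromlogd simulate --n 50 --out sim/   # synthetic dataset + ground truth
```

### A note on rows N5/N6

The stored reference table keeps every value exactly as published, but the
log *k*_w entries of rows N5 (anisole) and N6 (benzyl chloride) are
mutually transposed — anisole (log *P* 2.11) cannot out-retain
pentabromotoluene on C18 — and only the exchanged pairing reproduces the
established regression models. Both rows carry data-quality notes, and the
cascade applies a documented, switch-off-able swap repair
(`CascadeConfig(repair_transposed_retention=False)` fits the table as
printed).

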