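# Methods

This note records the modelling conventions, numerical choices and known
limitations of `omstab`, in the order the pipeline runs.

## Characterization

**Regional integration.** An EEM is integrated zone by zone with a
rectangle rule: each grid point is the centre of a cell of area
Δex × Δem (central spacing inside the grid, one-sided at the edges, no
half-cell special-casing), and a cell belongs to a zone when its centre
lies inside the zone's rectangle (boundaries inclusive). The seven default
zone boundaries shipped in `data/default_zones.yaml` are a documented
regional-integration-style partition of Ex 200–450 × Em 280–600 nm; they
are ordinary configuration, every computation is boundary-agnostic, and
users should supply the zone table matching their instrument protocol.
Rayleigh/Raman scatter masking is available (`ScatterMask`) but off by
default — the package does not silently alter data.

**Normalization.** `Vf_i = Vf_raw_i / TOC_sample / (S_i/ΣS_i)` removes the
dependence on extracted-carbon concentration and on zone size;
`Pf_i = Vf_i/ΣVf × 100` closes each fraction's 7-zone block to 100%.
Proportions are undefined (and an error) when every zone volume is zero.

**Carbon apportionment.** `AC_f = C_f/OM_TC × 100` with measured residue
TC for NEOM; a by-difference NEOM mode exists behind a flag. The closure
(ΣAC) is always returned; values outside 90–110% are flagged as recovery
problems but do not abort a run.

**C_nm.** Net CO₂ is the elementwise difference of the cumulative amended
and control trap series on a shared day grid. Negative net values are kept
and warned about, consistent with the assumption that priming is absent or
comparable across substrates; clipping would hide a violated assumption.
C_nm is evaluated at the last sampling day present in the data (the day
grid is data-driven, not hard-coded).

## PLS engine

NIPALS with deterministic initialization (the current-residual Y column of
largest variance), convergence tolerance 1e-10 on the weight vector,
500-iteration cap, and a fixed sign convention (largest-magnitude weight
entry positive), so refits are bit-identical. X and Y are mean-centred and
unit-variance scaled by default; zero-variance columns get scale factor 1
with a warning. Components beyond the rank of the scaled X are refused.

Diagnostics follow the chemometric conventions: per-component
R²X/R²Y from the deflation sequence; RMSEE with the `n − A − 1`
denominator; RMSEcv as `sqrt(PRESS(A)/n)` on the original response scale.

**Cross-validation.** Seven groups by default, assigned by deterministic
row-order interleaving (a seeded random assignment is available). Column
scaling is treated as *fixed preprocessing*: the centring/scaling factors
come from the full training matrix, and each CV fold refits only the
centring and the latent components before predicting the left-out rows
component by component. `Q²` per component is `1 − PRESS_a/SS_{a−1}`
(SS from the full-model deflation sequence) and `Q²(cum)` multiplies the
ratios. Commercial chemometrics software does not document its exact
workset partitioning and rescaling, so third-decimal agreement with such
software is not claimed; the convention here is chosen for determinism and
internal consistency and can make individual late components carry
negative Q² when the full model overfits them.

At full rank (A close to p) NIPALS converges only to ~1e-3 in the worst
response — eigenvalue gaps of the deflated covariance shrink — so exact
identities should be asserted at low rank or on orthogonalized designs.

**PCA.** SVD on the scaled matrix; explained variance per component is the
squared singular value over the total sum of squares. Q² uses an
element-wise grouped scheme: rows are left out in folds, and each held-out
cell is predicted from its row's *other* variables through the
training-fold loadings (least squares on the truncated loading matrix).
Hotelling-T² flagging uses the `A(n−1)/(n−A)·F` limit; flags are advisory
and removal is always an explicit, recorded configuration choice.

**HCA.** Ward linkage on Euclidean distances of unit-variance-scaled
variables (the standard choice when carbon contents in mg g⁻¹ sit next to
percentage compositions); k = 5 flat groups by default, both configurable.

## Coupling

Sub-models train on paired samples only; a waste family (the waste and all
its treatment products, parsed from the `<family>[-D][-C]` id convention)
is the holdout unit, and a leakage check asserts that no holdout-family id
appears in any stage's training set. Durations enter only their stage
(HRT → AD, DC → composting). Component counts default to 3 per stage
(configurable; an automatic per-component Q² stopping rule is available
but off by default).

Between stages, predicted 34-vectors are **re-closed**: negatives clipped
to zero, the AC block and each 7-zone Pf block rescaled to 100%, carbon
content kept strictly positive. The L1 adjustment is logged so users can
audit chain degradation; re-closure is idempotent, and a block that clips
to all-zero is an error rather than a silent repair. Final C_nm
predictions are clipped to [0, 100] with a warning (percent semantics).

Chained performance is best measured by parameter recovery on a *large*
held-out set: the study-shaped two-family holdout yields only ~6 observed
C_nm values, so its RMSE is a high-variance statistic; the test suite and
the acceptance script therefore also evaluate the chain on ≥100 freshly
generated products against the generator's ground truth.

## Synthetic study generator

The generator emulates the statistical shape of a multi-waste treatment
study, not its chemistry:

* **Group structure.** Five waste groups whose mean profiles sit along a
  carbon-accessibility gradient (fresh/labile → stabilized/refractory).
  The fluorescence-complexity gradient is deliberately *not* collinear
  with it, and OM_TC varies independently across groups — multi-waste
  collections show correlated but not redundant blocks, and this gives
  the fitted models several genuinely predictable directions while
  keeping both variable blocks informative about stability (which is what
  makes the feature-block ablation discriminative).
* **Within-group dispersion.** Dirichlet draws around the group mean for
  the AC block (concentration 2500) and each Pf block (2200); lognormal
  OM_TC (σ = 0.05). Dirichlet sampling keeps every closure exact by
  construction — no negative-clipping artifacts enter training data.
* **Treatment operator.** Per-day exponential transfer: the labile AC pool
  (SPOM+REOM+SEOM) retains `(1−r)^t`, the transferred mass splitting
  40/60 between PEOM and NEOM; protein-like fluorescence (zones I–III)
  transfers likewise into zones IV–VII with a fixed humic signature
  (0.30/0.30/0.25/0.15); OM_TC decays as `exp(−kt)`. Default rates:
  AD 0.010 (AC) / 0.008 (Pf) / 0.004 (TC) per day, composting
  0.009 / 0.008 / 0.005. Process reproducibility noise is a Dirichlet
  redraw around the shifted composition (concentrations 5000/4000;
  `treatment_noise = 0` makes the operator exactly deterministic, and
  duration 0 is the identity).
* **Response.** `C_nm = clip(β₀ + βᵀz + ε, 0, 100)` with z standardized
  against a fixed reference scale derived from the group means (so the
  response model depends only on the parameters, never on a dataset),
  β₀ = 58, β loading negatively on accessible carbon and protein-like
  zones and positively on refractory carbon and humified zones, and
  ε ~ N(0, 2²).
* **Study shape.** 31 wastes; digestates for three wastes in four (HRT
  cycled over 20–75 d), composts for two in three (DC cycled over
  14–84 d), composts of digestate for every fifth waste's digestate;
  every seventh waste carries no measured C_nm (the analogue of material
  not allowed to be spread raw, hence never incubated). Families W01 and
  W26 — the two that carry a digestate, a compost and a
  compost-of-digestate — are the default holdout.

Dispersions, rates and β are calibration choices fixed once so that the
sub-model diagnostics land in the ranges typical of real studies of this
size (R²Y ≈ 0.85–0.95, Q² ≈ 0.4–0.75, soil Q² > 0.9); they are not
estimates of any particular dataset. What passing tests show is that the
pipeline recovers structure it is designed for at realistic noise; they do
not show that real wastes satisfy the generator's linear response or its
exponential transfer kinetics, and real EEM spectra, extraction chemistry
and incubation kinetics are outside the generator's scope (EEM math is
tested separately on explicit grids).

## Problem sizes

Default test and acceptance runs use the 31-waste study (≈82 samples),
20 replicate studies for pooled ablation comparisons, 120 fresh products
for parameter recovery, and 50 repeats for the permutation null — sizes
chosen to make the pooled statistics stable on a single CPU in seconds.

## Known limitations

* The multiplicative Q² convention with full-model SS denominators departs
  from any proprietary implementation in unknowable details; treat small
  Q² differences across software as convention, not signal.
* Re-closure is a pragmatic repair for chaining; it has no uncertainty
  model, and the logged adjustment is the only audit trail.
* The AD sub-model's Q² is the weakest link at study size (~22 training
  pairs, 35 predictors); it fluctuates roughly between 0.2 and 0.6 across
  generator seeds.
* Mechanistic process models (digestion kinetics, compost heat/moisture,
  priming effects in soil) are out of scope by design.
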