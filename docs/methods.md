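# Methods

## Prediction equations

The package's equation engine (`mfyeval.equations`) implements three
closed-form models for lactating dairy cows, with every coefficient a
named module-level constant:

**Milk fat yield** (g/d) is linear in seven predictors: days in milk
(DIM), *non-fat* dry matter intake (DMI minus dietary fatty-acid
intake, kg/d), digested palmitic (16:0) and alpha-linolenic (18:3) acid
intakes (kg/d, scaled by 1000 inside the equation so their coefficients
act on g/d), and absorbed isoleucine and methionine (g/d). The
intercept is 453 g/d and the DIM slope −1.42 g/d per day, so the
equation can go negative for extreme DIM at low intakes; predictions
are returned unclamped with a `PredictionWarning` and no record is ever
excluded downstream.

**DMI from animal factors** (kg/d) is the product of a base-intake term
(linear in parity class, milk net-energy output in Mcal/d, body weight
and BCS, with parity-specific BCS slope) and a days-in-milk adjustment
`1 − (0.212 + 0.136·(parity−1))·exp(−0.053·DIM)`. The adjustment lies
in (0, 1) for DIM ≥ 1 and rises monotonically to 1, which the test
suite asserts as a property. Parity is a two-class code (1 =
primiparous, 2 = multiparous) derived from the lactation number; at
equal inputs the multiparous base term exceeds the primiparous one by
exactly `5.7 − 1.87·BCS` kg/d.

**DMI from feed and animal factors** (kg/d) is a six-term sum in diet
forage NDF (% of DM), ADF/NDF ratio, 48-h in vitro forage NDF
digestibility (NDFD) and the milk production target, with two
interaction terms centered at ADF/NDF = 0.602, NDFD = 48.3 and milk =
33.1 kg/d. At the centering points the interactions vanish and the
milk slope is exactly 0.225 kg DMI per kg milk.

**Milk net energy** (Mcal/d), needed by the animal-factors intake
model, is milk yield times a linear function of fat, protein and
lactose concentrations. The coefficient set is deliberately *not*
hard-coded: it lives in `mfyeval.config.MILK_NE_COEFFICIENTS` with two
named entries — `nasem2021_true_protein` (9.29/5.85/3.95 Mcal per kg of
component, protein input read as true protein) and
`nasem2021_crude_protein` (protein coefficient scaled by 0.951 for
crude-protein inputs). Tests pin the contract (proportionality in
yield, a hand evaluation under the configured set), not the external
constants, so a user can swap in another convention via config.

Conventions applied throughout, as config-visible defaults: BCS is set
to 2.5 whenever not scored (commercial test-day data rarely score it);
the milk production/energy target is the observed milk yield; DIM is
accepted as integer days.

## Nutrient-supply resolution

Herd records carry diet *concentrations*, not daily amounts, so
`mfyeval.supply` resolves the MFY predictors as concentration × intake
products: FA and digested-FA intakes as `DMI × %DM/100`, absorbed amino
acids as `MP supply × %MP/100` (or a directly measured pair, passed
through). This replaces the full digestion and metabolizable-protein
sub-models of a complete nutrient-requirements system and is the
package's single largest simplification: it assumes the tabulated
digestible-FA and %-of-MP values already absorb digestibility, which is
exactly the resolution at which herd-level feed characterisation
operates. All derivations are homogeneous of degree one in intake.

Two inputs have no standard on-farm source and are therefore explicit
user/config choices rather than estimates: whether `fa_pct_dm` holds
crude fat or total FA (feed labs usually report crude fat, which
overstates FA slightly), and the per-cow MP supply. When no `mp_g`
column is present the pipeline falls back to a linear rule
`mp_g = 1200 + 45·milk_yield` — a plausibility default for Holstein
rations, labelled as such, not derived from any dataset.

## Agreement statistics

`mfyeval.stats` implements Lin's concordance correlation coefficient

    CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²),  r = s_xy/(s_x·s_y),  C_b = CCC/r

and the three-way MSE partition

    MSE = mean((pred − obs)²)
    ECT = (mean_pred − mean_obs)²      central tendency bias
    ER  = (s_pred − r·s_obs)²          regression (slope) bias
    ED  = (1 − r²)·s_obs²              disturbance bias

**Moment convention.** Population (1/n) variances and SDs are the
default everywhere in this module because they make `ECT + ER + ED =
MSE` an exact algebraic identity (verified property-based on random
vectors) and `CCC = r·C_b` exact by construction. The sample (n−1)
convention — used by some reference implementations — is available via
`convention="sample"`; at n in the hundreds the two differ far below
the 2-dp reporting precision, but small-n worked values do differ
(e.g. obs (1,2,3) vs pred (2,3,4): CCC = 4/7 population, 2/3 sample).
Degenerate inputs (n < 3, zero variance) raise structured errors;
MSE = 0 reports RMSE 0 with a null (NaN) partition. Report display
rounds CCC/r/C_b to 2 dp and everything else to 1 dp.

Per-herd and overall regressions of observed on predicted use ordinary
least squares (`scipy.stats.linregress`), cows equally weighted; herds
with < 3 cows or degenerate predictor variance are flagged and skipped,
never fatal.

## Synthetic herd generator

`mfyeval.simulate` emulates a 23-herd, 541-cow single-visit test-day
dataset of Holstein cows. Targets (mean, SD, min, max per variable;
herd-size distribution 44.8 ± 16.9, range 23–98) are the printed
descriptive statistics of that population; milk protein (3.3 ± 0.3%),
lactose (4.6 ± 0.15%), the forage fraction of diet DM (0.60) and the
MP-supply rule are plausibility defaults with no published target, and
are labelled as such in the config.

Numerical choices:

* **Moment-matched truncated normals.** For each bounded variable the
  underlying normal's (μ, σ) are solved (scipy root find on the
  truncated-moment equations) so the *truncated* distribution has the
  target mean and SD; naive truncation of N(mean, sd) would, e.g.,
  inflate the DIM mean by ~15 d. When the target SD exceeds the
  truncated-normal feasibility ceiling for the interval
  ((hi−lo)/√12 in the uniform limit — the published crude-fat SD of
  0.7 on [1.6, 4.0] is such a case) the fallback matches the mean
  exactly and takes the closest feasible SD.
* **Herd structure.** One diet per herd (a ration is a herd property);
  herd sizes are drawn from the herd-size distribution and the
  requested record total is allocated proportionally (largest
  remainder), preserving herd-size inequality while summing exactly to
  the configured cow count. Note the published herd-size row describes
  on-farm lactating herd size, which is larger than records retained
  per herd.
* **Parity** is a truncated-geometric draw on 1–8 with the decay rate
  bisected to hit the target mean (2.4); the resulting SD (~1.5) is
  approximate, and the draw is then binarized to the two-class code.
* **Independence.** Variables are drawn independently (the descriptive
  table publishes no correlations), so real-data covariance — heavier
  cows eating more, stage-of-lactation effects on composition — is
  absent. Passing tests therefore demonstrate pipeline correctness and
  statistical machinery, not biological realism of joint
  distributions. One visible artefact: back-computed fat % can exceed
  the plausible range when a low drawn milk yield meets a high observed
  fat yield.

**Observed-yield attachment.** `attach_observed_mfy` sets
`observed = prediction + mean_bias + herd_intercept + residual` (g/d)
and back-computes fat % so `milk_yield × fat% × 10` stays consistent.
Because the animal-factors DMI model feeds fat % back into the
prediction through milk energy, the attachment iterates predict →
noise → fat % to its fixed point with the noise draws held fixed (the
loop gain is < 0.1, so convergence to float precision takes ~a dozen
iterations); at zero noise the resulting dataset is exactly
self-consistent (CCC = 1, RMSE = 0, identity regression). Residuals
that would make a yield non-positive are redrawn, with a bounded
budget. Default noise — mean bias 44 g/d, herd-intercept SD 80 g/d,
residual SD 230 g/d, total error SD ≈ 247 g/d — reproduces the error
magnitude reported for animal-factors-based predictions of this
population; the herd/residual split is the package's own choice, as no
variance components are published.

All randomness flows from one integer seed through
`numpy.random.default_rng`; identical configs give bit-identical
datasets.

## Problem sizes and validation scope

The test suite exercises the equations against independently written
single-expression oracles (1,000 random valid inputs per operation, and
frozen hand-computed worked values), the statistics against pure-Python
direct-summation oracles (1,000 random pairs, 1e−10 relative), and the
full pipeline at the emulated population size (n = 541, 23 herds), with
stochastic recovery checks (disturbance-dominance of the partition,
RMSE recovery within 15% of a calibrated 241.6 g/d disturbance SD,
CCC monotone in residual noise) averaged over 20 seeds.

## Known limitations

* The concentration × intake supply layer ignores digestion dynamics;
  with measured duodenal flows or a full requirements model the MFY
  predictors would differ.
* Independent marginals in the generator (see above).
* No confidence intervals on CCC or the partition — point estimates
  only, matching the reporting convention of the validation literature
  this package mirrors.
* Single-breed, single-visit scope: no seasonal, heat-stress or breed
  effects, and no repeated-measures structure.
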