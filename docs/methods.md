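# Methods

## Scope and model

`feedval` implements the complete evaluation calculus for a three-trial
swine digestibility study of dehydrated food waste ingredients: an
energy-balance trial (diet and ingredient DE/ME), a phosphorus trial
(ATTD/STTD), an ileal amino-acid trial (AID/SID with a nitrogen-free
diet), a three-step in vitro digestion assay, a registry of published
DE/ME prediction equations, and a confidence-interval accuracy rule.
Treatment-comparison inference (mixed models, multiple-comparison
adjustment) is deliberately out of scope: the package computes the
quantities such models would consume, not the ANOVA itself.

## Composition and basis algebra

Compositions store concentrations in percent of mass, as printed in feed
tables, with an explicit basis tag (`as_fed` or `dm`). Conversion is an
exact linear scaling by the DM fraction, so round trips are identities to
machine precision. A nutrient that was not assayed is `None`, and any
computation needing it raises a `MissingInputError` naming the field.
This matters numerically: silently zeroing an absent NDF shifts the
chemical-composition DE equations by >100 kcal/kg DM. "Crude fat" and
"ether extract" in source tables are treated as the same EE field. The
proximate fractions are not forced to sum to 100% on a DM basis because
the detergent-fiber fractions overlap protein and ash residues; only the
per-component 0–100% bound is enforced.

## In vivo estimators

Two diet-level DE/ME estimators are provided and agree exactly on
mass-balanced records:

* *total collection*: DE = (GE intake − fecal GE)/DM intake, ME = DE −
  urinary GE/DM intake;
* *marker ratio* (default, since the trials added TiO2 to every diet):
  GE digestibility = 1 − (Ti_diet/Ti_feces)·(GE_feces/GE_diet).

Ingredient values use the difference method with the corn base credited
at 66.9/96.9 of the basal diet and the shared mineral/premix base
(3.1% of both diets) assumed energy-neutral. Energy is carried at full
precision per kg DM and rounded only in report writers.

Standardization is strictly additive: STTD = ATTD + 100·(loss/1000)/P
(g/kg DMI) with the basal endogenous phosphorus loss a *configurable*
parameter defaulting to 190 mg/kg DMI; SID = AID + 100·(endogenous
flow)/(diet AA, g/kg DM), with endogenous flows estimated as the
marker-corrected ileal flow in nitrogen-free-diet pigs. Endogenous flows
use the same per-kg-DM-intake normalization as the marker ratio, which
is what makes the correction exactly additive. Standardized values may
exceed 100% (proline, glycine) and apparent values may be negative
(fibrous, low-protein feeds); both pass through unclipped. Per-pig
coefficients are computed first and then averaged — the pig is the
experimental unit — and the between-pig SD of AID carries over to SID
unchanged because the correction is a per-diet constant.

## In vitro calculus

The printed form of the combined DM digestibility, (100 − IVHDMD) ×
IVFDMD + IVHDMD, lacks a /100 when the operands are percentages and
would exceed 100% for any nonzero inputs; the normalized form
IVHDMD + (100 − IVHDMD)·IVFDMD/100 is used, verified against the
endpoint identities (fermentation of nothing changes nothing;
fermentation of everything digests everything). The in vitro DE charges
the hydrolysis residue's energy density multiplied by its mass fraction
of the original sample, so all terms share per-kg-original-DM units, and
credits VFA combustion energy at 209, 365, 522, and 678 kcal/mol
(acetate, propionate, butyrate, valerate). The mapping from supernatant
VFA concentrations (mmol/L) to mol/kg sample DM takes the incubation
volume and substrate mass as explicit inputs rather than assuming a
bench geometry. Cumulative gas-production curves are stored as raw
(hour, mL) pairs; no kinetic model is fitted.

## Prediction-equation registry

Equations 1–7 (chemical composition) take g/kg DM; 8–15 (stepwise
proximate regressions) take % DM; 16–19 (in vitro OM digestibility,
OMdv) take g/kg DM, are evaluated in MJ/kg DM, and convert at 1 MJ =
238.834 kcal. The conventions were fixed by reproducing the published
prediction tables and are enforced per family. OMdv and crude fiber are
caller-supplied inputs because no proximate assay provides them.

Two reproduction caveats are documented rather than hidden:

* The published fish-waste rows of equations 1–4 are reproducible only
  with the NDF term at zero (e.g. 5,234 vs 5,065 kcal/kg DM for
  equation 1 with the analyzed 4.1% DM NDF). Default behavior uses the
  analyzed NDF for every ingredient; an explicit `zero_ndf` override
  reproduces the published animal-product rows and records itself in
  the outcome notes.
* A handful of published cells (equation 2 for SMW/FVW, equation 10 for
  SMW, equation 11 for FVW) differ from full-precision recomputation by
  up to ±0.7 kcal — intermediate rounding upstream — so table-reproduction
  tests assert agreement within 1 kcal of the printed integers.
  The published ME-equation-5/6 rows appear transposed relative to their
  DE(1)/DE(2) definitions, and the equation-7 values are not reproducible
  from DE(3) − 0.68·CP at all; the registry implements the equations as
  defined and those cells are not asserted.

## Accuracy rule

The margin of error is the Student-t 95% half-width t(0.975, n−1)·sd/√n
over per-pig estimates (n = 9 per treatment in the reference design);
published margins can also be supplied directly, since per-treatment SDs
are usually not printed alongside pooled SEMs. A prediction is "within"
iff |predicted − observed mean| ≤ margin. Verdicts are order-invariant
and monotone: shrinking the margin can only expel predictions.

## Synthetic trial generator

The generator inverts every estimator exactly: body weights are drawn
from N(16.37, 1.9²) kg, intake follows the 3 × 197 kcal ME/kg BW^0.60
allowance, and fecal/urinary energy, fecal marker, fecal phosphorus, and
ileal digesta concentrations are solved from the scenario's true DE, ME,
ATTD, AID, and endogenous flows by exact marker and energy mass balance.
Assay noise is multiplicative lognormal with unit mean (assays are
positive and CV-scaled), default CV 5% on marker, calorimetry, and
nutrient assays, applied only to assayed quantities; the underlying
normal deviates are always drawn, so the simulated animals are identical
across noise settings at a fixed seed, and each trial type consumes an
independent, documented substream. True diet energies are assembled from
ingredient truths through the same linear replacement structure the
difference method inverts, so ingredient recovery at zero noise is exact
by construction.

The default scenario uses the published in vivo means of the three food
waste sources as ground truth (including FVW's strongly negative
apparent amino-acid digestibilities, to −413% for proline) with the
analyzed diet tables for concentrations and markers; 9 pigs per diet.
Plausibility validation accepts apparent ileal coefficients in
[−500, 150]% for this reason, while total-tract coefficients are held to
[−100, 110]%. Basal endogenous amino-acid flows are backed out from the
fish-waste AID/SID pair, which makes the fish-waste SID truths exact and
leaves the other diets' implied SID within ~0.2 points of their
published values (the three diets imply slightly different endogenous
flows; a single basal flow per amino acid is the model's assumption).
Diet-level DM digestibilities (0.78–0.90) only size fecal bulk and do
not affect any estimator.

What passing recovery tests show — and what they do not: they verify the
estimation algebra and its noise behavior, not animal biology. The
generator has no between-day autocorrelation, no feed refusals, no
pig-level digestibility heterogeneity beyond assay noise, and no basis
mismatch errors; real trials have all of these, so real-data confidence
intervals will be wider than the simulated ones.

Monte Carlo sizes in the test suite (500 replicates of the full design
at CV 5%) keep the default run under a minute while bounding the DE
recovery bias well below 1% and mean AID recovery within 2 points.

## Numerical choices and degenerate inputs

Marker ratios raise on nonpositive marker or diet concentrations rather
than returning infinities; a fecal marker concentration below the
dietary level is a warning (data sanity), not an error. ME > DE, DE > GE,
and nonpositive ME are rejected at the diet level; ingredient-level
energies from the difference method may legitimately reach zero and are
not positivity-checked. Confidence levels are open-interval (0, 1);
margins of zero are valid (constant samples). Reports are plain CSV with
a provenance header (version, seed, configuration hash over the
scientific settings, excluding the output path) so identical runs are
byte-identical.

## Known limitations

* The in vitro module computes bookkeeping, not chemistry: enzyme
  activity, buffer composition, and inoculum biology are inputs'
  provenance, outside the model.
* Published in vivo tables for diets other than fish waste cannot be
  reproduced to the printed decimal from rounded table inputs (e.g. the
  SMW/FVW STTD differ by 0.6–0.9 points when recomputed from the printed
  ATTD, diet P, and the 190 mg/kg correction); the fish-waste column,
  which recomputes cleanly, anchors the tests.
* No net-energy system, nitrogen-balance calculus, true ileal
  digestibility, or diet-specific endogenous-loss modeling.
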