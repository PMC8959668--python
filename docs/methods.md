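# Methods

## Reaction model

The model is a lumped mass-action network over 14 species (concentrations
in mmol/L, time in minutes).  Each lumped reaction stands for a multistep
pathway: R3/R4 collapse the glycation cascade from lysine plus a
dicarbonyl to the stable end products CML/CEL; R5 collapses the
asparagine (Strecker-type) acrylamide route via glyoxal; R8 the acrolein
addition route; R9 the Pictet–Spengler condensation of tryptophan with
acetaldehyde followed by tetrahydro-β-carboline oxidation to harmane.
Intermediates that are not measured in such experiments (Schiff base,
Amadori products, tetrahydro-β-carbolines) are deliberately not tracked;
their dynamics are absorbed into the lumped constants.  Norharmane (R10)
is modelled first order in tryptophan because its one-carbon partner
(formaldehyde) is untracked.

Design choices that were genuinely open:

- **Bimolecular flux normalisation.**  Tabulated estimates for this kind
  of experiment are conventionally printed in min⁻¹ for all constants.
  We therefore write second-order fluxes as k·[A]·[B]/c_ref with
  c_ref = 100 mmol/L (the initial glucose concentration).  This keeps
  true mass-action structure while making every k a frequency.  Setting
  `dicarbonyl_ref_mmolL: null` in a config file switches to raw
  second-order units (L·mmol⁻¹·min⁻¹).
- **Melanoidin stoichiometry.**  Melanoidins are amino-carbonyl
  polymers, so R11 (first order in glucose; quantified via absorbance at
  470 nm) co-consumes free amino acid 1:1 with its flux.  The ideal 1:1
  coupling divides by the total free amino-acid pool and becomes 0/0 as
  the pool empties; we use flux·c_aa/(pool + K_sat) with
  K_sat = 0.1 mmol/L.  While the pool is large the coupling is exactly
  1:1; as the pool empties, consumption fades out smoothly (one cannot
  incorporate amino acid that is not there).  K_sat is small against
  every initial amino-acid pool (5–200 mmol/L) and is configurable.
- **Elimination constants.**  Measured intermediates and products decline
  late in heating (degradation, polymerisation, adduct formation).  Seven
  optional first-order sinks e12–e18 (on GO, MGO, ACH, ACR, AA, HAR,
  NOR) represent this; they default to zero and are freed on request.
  Only sinks of species the given system can produce are ever freed —
  e.g. the acrylamide sink is structurally unidentifiable in Lys/Glu,
  where acrylamide is identically zero.
- **Temperature** is a categorical condition (170 or 200 °C): each
  temperature gets its own constants and no Arrhenius coupling is
  imposed, because two temperatures cannot constrain an activation
  energy meaningfully.
- **Com/Glu lysine.**  The combined system defaults to Lys 30 mmol/L
  (the food-proportion design); a variant flag selects 100 mmol/L, since
  both compositions appear in descriptions of such designs.

## Forward simulation

The ODE system is integrated with LSODA (via `scipy.integrate.odeint`)
with an analytic Jacobian; default tolerances rtol = 1e-8,
atol = 1e-10 mmol/L.  A stiff-capable solver is required: the active
constants span 1e-6–2.5 min⁻¹ and the amino-acid co-consumption creates
a fast initial depletion layer (effective rates of order 1e3 min⁻¹ in
the lysine systems).  Trial states are clipped at zero inside the
right-hand side; outputs are clipped at zero, and the clip magnitude
(always at solver-tolerance level) is recorded on the trajectory.
Halving the tolerances changes no reported concentration by more than
1e-4 relative (tested).

Observation-model conversions: mass concentrations (μg/mL) divide by the
species molar mass to give mmol/L; melanoidins have no molar mass and
convert from absorbance at 470 nm by Lambert–Beer with
ε = 282 L·mol⁻¹·cm⁻¹ and a 1 cm path (the cuvette path length is not
stated for such measurements; both ε and path are configurable).

## Synthetic data

The generator emulates the experimental design: sampling at 3–21 min in
3-min steps plus a t = 0 anchor row (products zero, substrates at their
design values), triplicate measurements, and multiplicative Gaussian
noise — value = truth·(1 + ε), ε ~ N(0, cv), truncated at zero.  The
default cv = 0.05 reflects the typical 5–10% triplicate scatter of such
measurements; scatter grows with concentration, which is why the noise
is multiplicative rather than additive.  Truncation (not resampling)
keeps generation deterministic given a seed.  An optional detection
floor censors values below a threshold to zero (off by default).
Replicates are independent; real replicate-to-replicate correlation
(shared calibration, batch effects) is not emulated, so passing recovery
tests bound estimator behaviour under ideal independent noise only.
Every synthetic dataset records full provenance (system, truth
constants, noise model, seed) and can be regenerated exactly from it.

## Estimation

All observed responses are fitted jointly.  Residuals are
(observed − predicted)/w_i per (time, replicate, species) observation;
replicates enter individually unless a replicate-averaged fit is
requested (matching the mean-concentration convention some studies use).
Species observed as identically zero carry no information about their
(inactive) pathways and are excluded with a warning.

**Weighting.**  The default scheme is `relative`:
w_i = max(|obs_i|, 0.01·max_s), the observation's own magnitude floored
at 1% of the species maximum.  This matches the multiplicative error
structure and — decisively for this design — keeps small observations
informative.  With k11 ≈ 2 min⁻¹ the reaction is essentially complete
before the first 3-min sample; the only information about the *overall
rate scale* (as opposed to branching ratios, which the product plateaus
fix) is the small leftover glucose at 3 min.  Multiplicative noise
preserves the relative accuracy of that observation, and relative
weighting exploits it: noisy-recovery medians for k1/k2/k6/k11 are a
few percent.  Under per-species `max` weighting (also available, as is
`sd`) the same observation is down-weighted by ~1e3 and the rate scale
is nearly unidentified — measured seed-median errors of 25–40% at the
true optimum of that objective.  This estimability cliff is a property
of the sampling design, not of the optimizer.

**Optimization.**  Only the active constants of the system (plus
requested, identifiable eliminations) are free; all others are pinned at
zero.  Free constants are optimized as log k by Levenberg–Marquardt
(`scipy.optimize.least_squares`, `method="lm"`, finite-difference
Jacobian with a 1e-3 relative step — large enough to stand clear of
solver noise at the integration tolerances).  Log-parameterization
handles the four-decade spread of the constants and enforces
positivity without active bounds.

**Degeneracy safeguard.**  Scaling every rate constant by s maps the
solution to y(s·t); once the system has equilibrated before the first
sample, increasing s changes almost nothing and the cost surface has a
plateau at s → ∞.  From an overestimated start the optimizer can drift
onto it.  Fits whose largest constant exceeds 100 min⁻¹ (40× the
largest plausible value here) are therefore restarted from a contracted,
seed-perturbed start, and the basin with the lower cost is kept; the
global minimum always fits the leftover-substrate observations better,
so cost comparison resolves the ambiguity.  A result still on the
plateau after the retries is returned with a logged warning.
Non-convergence triggers the same seeded multistart.  A helper fits from
0.5× and 2× starts and flags multimodality when the final weighted
residual sums disagree by more than 1%.

**Goodness of fit.**  R² per response is 1 − SS_res/SS_tot about the
observed mean, computed on the same observations the fit used; it may be
negative for a bad fit and is undefined (flagged, not returned) for
constant observations.

## Recovery studies and problem sizes

The package's accuracy claims are self-consistency claims: simulate a
tabulated condition with its printed constants, refit, compare.

- *Noise-free*: all eight conditions, start at 2× truth, every active
  constant recovered within 1% relative (in practice to ~1e-12; the
  optimum is a zero-residual point).  Seconds per condition.
- *Noisy*: cv = 0.05, 3 replicates, 20 seeds per condition; the
  seed-median relative error of k1, k2, k6, k11 is required to stay
  within 15% (observed: 0.4–6%).  Integration tolerances are relaxed to
  rtol = 1e-6 for this study — solver error is then still three orders
  below the noise-driven estimate scatter.  The full sweep (160 fits)
  runs in about two minutes on one CPU.

The slow bimolecular constants (k9, k10 in particular, at 1e-6–1e-5
min⁻¹ natural scale) ride on product concentrations of order 1e-5
mmol/L; they are recovered exactly in the noise-free study and to
5–10% median under noise, but their real-world estimability would be
limited by detection floors, which the default noise model does not
impose.

## Known limitations

- The reaction list is a lumped reconstruction; alternative routings
  (e.g. acrylamide from asparagine + glucose directly) would fit plateau
  data similarly and are not distinguishable within this design.
- The preheating period of the vials is ignored: t = 0 is defined at
  oil-bath insertion with products at zero.
- No parameter confidence intervals are produced; replicate scatter in
  tabulated estimates of such experiments reflects experimental
  variation between refits, which can be mirrored here only via seeds.
- Evaporation, pH drift and buffer chemistry within a run are out of
  scope.
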