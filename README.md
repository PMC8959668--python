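# maillard-kinetics

Multiresponse kinetic modelling of the harmful products that form
simultaneously during the Maillard reaction in amino-acid/glucose model
systems: acrylamide, the advanced glycation end products
N^ε^-(carboxymethyl)lysine (CML) and N^ε^-(carboxyethyl)lysine (CEL), the
β-carboline heterocyclic amines harmane and norharmane, and melanoidins.

The package is for food chemists and kinetic modellers who want to
estimate — or study the estimability of — lumped mass-action rate
constants from heated-model-system concentration time series, where
several precursor amino acids (lysine, asparagine, tryptophan) compete
for glucose-derived carbonyl intermediates.

## The model

Fourteen species are tracked in mmol/L over a 0–21 min heating protocol.
Glucose (GLU) degrades to the α-dicarbonyls glyoxal (GO) and
methylglyoxal (MGO), to acetaldehyde (ACH), and to melanoidins (MEL);
acetaldehyde oxidises to acrolein (ACR); and the amino acids route these
intermediates into end products:

    R1   GLU → GO               k1      R7    ACH → ACR           k7
    R2   GLU → MGO              k2      R8    ASN + ACR → AA      k8
    R3   LYS + GO → CML         k3      R9    TRP + ACH → HAR     k9
    R4   LYS + MGO → CEL        k4      R10   TRP → NOR           k10
    R5   ASN + GO → AA          k5      R11   GLU → MEL           k11
    R6   GLU → ACH              k6

with optional first-order elimination sinks e12–e18 for GO, MGO, ACH,
ACR, AA, HAR and NOR (default zero).  Unimolecular steps are first order;
bimolecular fluxes are written k·[A]·[B]/c_ref with c_ref = 100 mmol/L
(the initial glucose concentration), so every constant carries the
min⁻¹ scale used in tabulated estimates.  Melanoidin formation (R11)
co-consumes free amino acids 1:1 with its flux, split across Lys/Asn/Trp
in proportion to their concentrations.

Four model systems are built in: Lys/Glu (30/100 mmol/L), Asn/Glu
(200/100), Trp/Glu (5/100) and the combined Com/Glu (30/200/5/100), each
at 170 or 200 °C, with the per-system *active set* of constants (the
reactions whose precursors are present).  Rate constants are estimated by
multiresponse non-linear least squares: one parameter vector fitted
jointly to all observed species, Levenberg–Marquardt on log-transformed
constants, residuals weighted by observation magnitude (multiplicative
measurement error), per-response R² reported.

## Worked example

Generate a synthetic triplicate dataset for the Asn/Glu system at 170 °C
(5% multiplicative noise), then fit it from a neutral start:

```sh
$ maillard-kinetics generate --scenario Asn-Glu-170 --cv 0.05 --reps 3 --seed 42 --out asn170.csv
wrote 3 replicates for Asn-Glu-170 (cv=0.05, seed=42) to asn170.csv

$ maillard-kinetics fit --data asn170.csv --out asn170_fit
fit converged; ssr=3.592e-01; report: asn170_fit.txt, asn170_fit.csv
```

The report (`asn170_fit.txt`) shows the fit converged in 9 iterations on
192 observations with per-response R² between 0.95 (asparagine) and
0.9996 (glucose); the estimates CSV holds both natural and printed
scales.  The truth behind this dataset was k1 = 0.257, k2 = 0.015,
k5 = 0.062, k6 = 0.197, k7 = 0.105, k8 = 0.103, k11 = 1.579 min⁻¹, and
the fit returns

```
k1,0.25389830014,...   k5,0.0630081570672,...   k11,1.56821199443,...
```

i.e. every constant within a few percent of truth at this noise level —
the glucose-channel constants are identified mostly by the product
plateaus (branching ratios) plus the leftover glucose at 3 min (overall
rate scale).

The recovery harness runs the same simulate-then-refit loop against the
built-in truth sets and prints a pass/fail table:

```sh
$ maillard-kinetics recover --scenario Trp-Glu-170 --noise-free
condition     k         truth    estimate  rel.err    tol  status
Trp-Glu-170   k1        0.172       0.172    0.00%     1%  PASS
...
all constants recovered within tolerance
```

## Library surface

```python
from maillard_kinetics import (
    build_model_system, table1_scenario,        # systems & truth sets
    integrate,                                  # stiff forward simulation
    generate_dataset, NoiseModel,               # synthetic design emulation
    fit_multiresponse, refit_from_simulation,   # estimation
    read_dataset, write_dataset,                # tidy CSV with provenance
)
```

See `docs/methods.md` for the model assumptions, the noise model, the
numerical choices (solver, weighting, log-parameterization, multistart
safeguards) and known limitations.
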