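# Methods

## Model

The package implements descriptor determination for the Abraham solvation
parameter model. For a solvent system indexed by its coefficient record
(c, e, s, a, b, v) or (c, e, s, a, b, l):

* water → solvent: `log Ps = c + e·E + s·S + a·A + b·B + v·V`
* gas → solvent: `log Ks = c + e·E + s·S + a·A + b·B + l·L`

with the bridges `Ps = Cs/Cw` (saturation solubilities) and `Ps = Ks/Kw`
(gas–water partition). All logarithms are base 10. Every observation
therefore yields two linear equations in the unknown descriptors: a P-form
and a K-form. Two gas→water "closure" correlations — one written in V, one
in L — constrain log Kw jointly with the other descriptors. Writing each
equation with all unknowns on the left, log Cw enters solubility equations
with coefficient +1, log Kw enters every gas-form equation with −1, and
the closure equations have response 0. Contributions of fixed descriptors
are folded into the response, and the stacked system is solved by ordinary
least squares (direct solve, deterministic; exact collinearity aborts with
the collinear unknowns named rather than silently pseudo-inverting). All
equations are weighted equally; the weight mechanism exists but defaults
to 1.

Key applicability assumptions: the solute has the same molecular form in
every phase of one fit (hence the monomer/dimer split below), dilute-limit
activity corrections are neglected, and ionisation in water is ignored
(log Cw refers to the neutral form).

## Structure-derived descriptors

**V (McGowan characteristic volume).** Sum of tabulated atomic volumes
(C 16.35, H 8.71, O 12.43 … cm³/mol, shipped in
`data/mcgowan_volumes.csv`) minus 6.56 cm³/mol per bond, with bonds =
atoms − 1 + rings, divided by 100. Ring count is explicit input; there is
no structure perception. For the hydrogen-bonded carboxylic acid dimer
treated as a single unit, the eight-membered ring closed by the two
hydrogen bonds counts as one ring and its hydrogen bonds as two bonds
(C18H16O4: 38 atoms, 40 bonds). This convention is validated by the exact
identity 2·V(monomer) − V(dimer) = 2 × 0.0656, the two extra bonds of the
dimer. Unknown elements fail loudly rather than defaulting.

**E (excess molar refractivity).** Estimated by fragment arithmetic: the
acid-vs-ethyl-ester E increment of a reference pair (benzoic acid 0.730
vs ethyl benzoate 0.689) is carried onto ethyl cinnamate (1.102), giving
1.143 → 1.14 for trans-cinnamic acid (E values are reported to
hundredths). The dimer's E follows the affine relation
`E_dimer = −0.418 + 1.839·E_monomer`, an empirical regression over liquid
aromatic carboxylic acids whose refractive indices probe the dimeric
form. The relation is specific to carboxylic acid dimers and should not
be applied to other solute classes.

## Data curation

* **Units.** Mole fraction, mass fraction and mass ratio solubilities are
  converted to molarity using pure-solvent density as a stand-in for
  solution density — a documented error source for very soluble systems.
* **Temperature.** Off-25 °C measurements are corrected to 298.15 K with
  the Buchowski λh relation `ln[1 + λ(1−x)/x] = λh(1/T − 1/Tm)` in
  mole-fraction space, with miscibility (x = 1) at the melting point built
  in. λ = 1 by default: one measured point plus the boundary condition
  identifies only one parameter, and λ = 1 makes h identifiable from that
  single point. This is an interpretive choice, not a uniquely determined
  procedure. Tm is a config input (default 406 K for trans-cinnamic
  acid). Replicates are averaged (mean and mean absolute deviation) after
  correction.
* **Speciation.** Saturation solubilities are classified by the solvent's
  Kamlet–Taft β: β > 0.35 → monomer-dominated, β < 0.35 →
  dimer-dominated, β missing or exactly 0.35 → unclassified (manual
  assignment required). Classification is by β only: trifluoroethanol
  (β = 0.00) fits on the dimer side although it is an alcohol. Direct
  log P values are monomer data regardless of solvent (dilute regime).
* **Exclusion.** Solvents lacking either coefficient record
  (water→solvent or gas→solvent) are excluded and reported; in the
  bundled case study these are pentachloroethane,
  1,1,2,2-tetrachloroethane, tetrachloroethylene and trichloroethylene.
  Water is the reference phase, not a fitted solvent.

## The bundled case study

`data/` ships the trans-cinnamic acid inputs: 30 replicate-averaged
molar solubilities at 25 °C, 5 direct log P values, solvent metadata and
a transcribed Abraham solvent-coefficient compilation (source DOI in the
file headers). The solubility source table lists the xylene entry as
m-xylene while the published fits use p-xylene; the fixture canonicalises
it to p-xylene to match the fits.

The **monomer fit** (16 polar-solvent solubilities + 5 direct partitions,
each contributing both equation forms, + 2 closures + 1 auxiliary slot =
45 equations) frees S, A, L and log Kw, fixing E = 1.14, V = 1.1705,
B = 0.50 and log Cw = −2.40 (the measured aqueous solubility, log10
0.004). B and log Cw are user-fixed config inputs; the provenance of the
fixed B in the original analysis is not recorded in the source, so it is
exposed as a parameter rather than hard-coded. The historical analysis
also included one gas-chromatographic retention correlation whose
coefficients are not publicly printed; the package carries it as a
zero-weight placeholder constraint so the equation count is preserved,
and reports the fit with and without it (the estimates are identical).

The **dimer fit** (9 non-polar-solvent solubilities + 2 closures = 20
equations) frees S, A, B, L, log Kw and log Cw, fixing E = 1.68 and
V = 2.2098.

Replication quality: the transcribed water→solvent coefficients reproduce
the published fitted log Ps columns exactly, and the solubility residual
statistics land within a few thousandths of the published AE/AAE/SD. The
gas-phase side of the compilation cannot be cross-checked against
published columns, and the retention-data equation is unavailable, so the
descriptors that lean on the K-form equations (L, log Kw, and through
them the dimer S and A) replicate to roughly 0.1–0.2 log units rather
than hundredths. The per-solvent reference tables and published
descriptor row ship in `data/` as test expectations, never as fit inputs.

## Synthetic data

`abrahamfit.synthetic` generates scenarios with known true descriptors:
per-solvent coefficient records drawn uniformly from realistic Abraham
ranges (c ∈ [−1, 1], a ∈ [−4, 4], v ∈ [3, 4.7], l ∈ [0.6, 1.1], …,
closure records drawn from water-like ranges), and measurements computed
from the forward model with centred Gaussian noise in log units —
matching the least-squares objective. The gas-record and closure
intercepts are calibrated so the thermodynamic cycle Ps = Ks/Kw closes
exactly at the true descriptors; without this the noiseless system would
be inconsistent and exact recovery impossible. Everything is
deterministic under the scenario seed; rank-deficient draws (possible
with collapsed ranges) are redrawn with a warning a bounded number of
times, then handed to the solver whose diagnostics name the deficiency.

The default scenario mirrors the hardest identifiability case of the
workflow: 9 solvents, 6 free unknowns, 20 equations, noise σ = 0.05 log
units (the scale of the case-study residuals). What the generator does
not emulate: correlated coefficient errors across solvents, heteroscedastic
measurement noise, speciation mixtures at intermediate β, or activity
effects at high solubility — so passing recovery tests demonstrate solver
correctness and identifiability, not robustness to those real-data
features.

Recovery experiments (200 replicates at σ = 0.05 by default in the tests)
report per-unknown bias and RMSE; solver failures are counted, never
swallowed. Problem sizes throughout the test suite (≤ 18 solvents,
≤ 200 replicates) keep the full suite in the seconds range while leaving
Monte-Carlo standard errors well below the asserted tolerances.

## Numerical choices

* Least squares via a rank-checked direct solve; condition number
  reported. Underdetermined or collinear systems raise named errors.
* SD of residuals uses the n − 1 divisor (validated against the published
  statistics, which discriminate 0.078 vs 0.075 and 0.084 vs 0.079).
* Zero-weight constraints are counted in the equation total but excluded
  from the solve and the residual statistics.
* Reported values round to 3 decimals (E to hundredths); internal
  computation is full precision.
* The β threshold is a strict inequality in both directions; the boundary
  value is deliberately unclassified.

## Limitations

* Descriptor accuracy is bounded by coefficient-compilation provenance;
  third-decimal differences between compilations propagate to the fits.
* No uncertainty quantification on the descriptor estimates (no
  bootstrap); no robust regression; no joint monomer/dimer fit linked by
  a dimerisation constant.
* The dimer E relation and the β-threshold rule are empirical and
  carboxylic-acid-specific.
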