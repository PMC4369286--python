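# abrahamfit

Determination of Abraham solvation-model solute descriptors from measured
saturation solubilities and water–solvent partition coefficients, with
explicit handling of the monomer/dimer speciation of carboxylic acids.

## The problem

The Abraham solvation parameter model writes the log10 partition
coefficient of a solute between two phases as a linear free-energy
relationship over six solute descriptors:

```
log Ps = c + e·E + s·S + a·A + b·B + v·V      (water → solvent)
log Ks = c + e·E + s·S + a·A + b·B + l·L      (gas → solvent)
```

where E is the excess molar refractivity ((cm³/mol)/10), S the
dipolarity/polarizability, A and B the hydrogen-bond acidity and basicity,
V the McGowan characteristic volume ((cm³/mol)/100), L the log10
gas–hexadecane partition coefficient at 298 K, and the lowercase
coefficients characterise each solvent system. Saturation solubilities
enter through `Ps = Cs/Cw` and gas-phase partitions through `Ps = Ks/Kw`.
With E and V computed from structure, the remaining descriptors are
determined by stacking the equations available for many solvents and
solving the over-determined linear system by least squares.

Carboxylic acids complicate this: at saturation they dimerise in solvents
of low hydrogen-bond basicity (Kamlet–Taft β < 0.35), so a single
descriptor set cannot describe all solvents. The package splits the
solvents at that threshold and fits the monomer (polar solvents plus
dilute-regime direct log P values) and the hydrogen-bonded dimer
(non-polar solvents) as two separate solutes — including the dimer's own
McGowan volume (the acid-bridge ring counts as a ring, its two hydrogen
bonds as bonds) and its E from an affine monomer→dimer relation
(E_dimer = −0.418 + 1.839·E_monomer).

The package is aimed at physical/analytical chemists curating solubility
compilations (e.g. Open Notebook data) into descriptor sets: it bundles
the complete trans-cinnamic acid case study — 30 replicate-averaged
solubilities, 5 direct log P values, a transcribed Abraham
solvent-coefficient table — and replicates the published monomer (45
equations) and dimer (20 equations) fits.

## Worked example

```
$ abrahamfit mcgowan --formula C9H8O2 --rings 1
1.1705
$ abrahamfit replicate --which dimer
== trans-cinnamic acid dimer ==
descriptors: E=1.68  S=1.146  A=0.1537  B=0.9719  V=2.21  L=10.32  log_kw=6.31  log_cw=-5.72
equations: 20   solubilities: 9   excluded solvents: 1,1,2,2-tetrachloroethane, pentachloroethane, tetrachloroethylene, trichloroethylene
solubility residuals: AE=0.002  AAE=0.043  SD=0.079
           solvent  calc_log_ps  obs_log_ps  calc_log_cs  obs_log_cs
       cyclohexane        4.303       4.152       -1.417      -1.569
tetrachloromethane        4.943       4.943       -0.778      -0.777
  trifluoroethanol        4.946       4.945       -0.775      -0.775
...
```

The first command is the McGowan volume of trans-cinnamic acid (19 atoms,
19 bonds). The second runs the dimer fit: E and V are fixed from
structure, and S, A, B, L, log Kw (gas–water partition) and log Cw
(aqueous solubility of the dimer) are estimated from 9 non-polar-solvent
solubilities plus the two gas–water closure equations. Each solvent row
compares fitted and observed water→solvent partition (log Ps) and molar
solubility (log Cs); the AE/AAE/SD line summarises the solubility
residuals (mean signed error, mean absolute error, n−1 standard
deviation, all in log units — about 0.08 here, i.e. solubilities in
non-polar solvents are reproduced to better than a factor of 1.3).

The same workflow is available as a library:

```python
from abrahamfit import ReplicationConfig, run_replication
report = run_replication(ReplicationConfig(which="monomer"))["monomer"]
print(report.descriptors, report.n_equations)   # 45 equations
```

and the estimator composes with scikit-learn
(`abrahamfit.DescriptorRegression`). Synthetic studies
(`abrahamfit.synthetic`) generate coefficient tables and noisy
measurements with known true descriptors for parameter-recovery
experiments.

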