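# kawcycle

Air/water partition coefficients (*K*<sub>aw</sub>) of per- and
polyfluoroalkyl substances (PFAS), determined indirectly through the
**hexadecane/air/water thermodynamic cycle**:

```
log K_aw = log K_Hxd/w − log K_Hxd/air
```

*K*<sub>aw</sub> controls how a contaminant moves between air and water and
is an essential input for environmental fate, exposure, and risk analysis —
yet direct measurement is notoriously hard for surface-active,
poorly volatile PFAS. Measuring the hexadecane/water coefficient
*K*<sub>Hxd/w</sub> instead (no gas-phase quantification needed) and dividing
by a known hexadecane/air coefficient *K*<sub>Hxd/air</sub> reaches
*K*<sub>aw</sub> values across 7 orders of magnitude.

The package is aimed at environmental chemists working with multiphase
equilibrium data. It implements:

- **Mass-balance estimators** for the batch (two-phase) and
  shared-headspace (three-phase) experiments, with Student-*t* replicate
  statistics and a configurable policy selecting the final value per
  compound.
- **Variable phase ratio headspace (VPR-HS) fits** — nonlinear least
  squares of peak-area series for both the modified design
  (PA = αm / (V<sub>tot</sub> + (K−1)V<sub>Hxd</sub>), yielding
  *K*<sub>Hxd/w</sub>) and the standard design
  (PA = αm / (V<sub>gas</sub> + V<sub>w</sub>/K<sub>aw</sub>)), with
  seeded bootstrap confidence intervals and a sorption-artifact residual
  diagnostic.
- **Measurement-artifact models**: hexadecane microdroplets entrained in
  sampled water (K<sub>app</sub> = K/(1 + fK), fraction estimation, and the
  method applicability limit it implies) and aqueous ionization of weakly
  acidic sulfonamides (neutral-fraction correction from pKa and pH).
- **Homologue-trend analysis**: per-CF₂/per-CH₂ increments by OLS within
  homologue groups, pooled across PFAS classes; structural substitution
  contrasts.
- **Prediction-model scoring**: RMSE / mean error / bias-corrected RMSE
  against experimental values, with pairwise exclusion of missing
  predictions.
- **A forward simulator** for every experiment type with multiplicative
  lognormal noise, droplet contamination, and sorptive-loss injection —
  the test surface for every estimator.

The measured 21-compound PFAS dataset (registry with SMILES, per-method
log *K*<sub>Hxd/w</sub> values with 95% CIs, derived log *K*<sub>aw</sub>)
ships with the package.

## Worked example

Quantifying the microdroplet artifact that caps the batch method
(`examples/droplet_artifact.py`):

```
compound      accurate  apparent  implied f (vol %)
4:2 FTI          4.93      4.13       0.0062
6:1 FTI          5.66      4.34       0.0044
6:1 FTI-7H       4.62      4.06       0.0063
6:2 FTAC         5.43      4.22       0.0057
4:2 FTMAC        4.65      4.02       0.0073

mean droplet fraction : 0.0060 vol %
batch applicability   : log K_Hxd/w up to 3.6 (bias <= 0.1 log units)
check: true 4.93 would appear as 4.15 (measured: 4.13)
```

Five hydrophobic PFAS measured both with phases in contact (batch,
"apparent") and with phases separated (shared-headspace, "accurate")
show gaps that a single entrained-hexadecane fraction of ~0.006 vol %
explains. Inverting the bias model shows the batch method is only
trustworthy up to log *K*<sub>Hxd/w</sub> ≈ 3.6 if errors above 0.1 log
units are unacceptable.

Pooling chain-length trends (`examples/homologue_increments.py`):

```
log K_aw per CF2:
  N-Me FASA  +0.420
  PFASA      +0.462
  X:1 FTOH   +0.408
  X:2 FTOH   +0.420
  pooled     +0.427 +/- 0.012 (4 groups)
```

Each line is the OLS slope of log *K*<sub>aw</sub> on the
perfluorinated-carbon count within one homologue class; the pooled
~0.43 log units per CF₂ is consistent across classes, supporting
extrapolation to longer homologues.

The other scripts in `examples/` walk through the full thermodynamic-cycle
pipeline, a VPR-HS fit on simulated data, and prediction-model scoring.

A thin CLI mirrors the library (`kawcycle --help`): `cycle`, `batch-k`,
`shared-k`, `fit-vprhs`, `droplet-fraction`, `applicability`, `trends`,
`eval`, `simulate`, `run`.

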