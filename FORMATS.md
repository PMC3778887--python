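# On-disk formats

## Time series (TSV)

Tab-separated text with a header row.  The first column is `time`
(seconds, strictly increasing with a constant step); remaining columns are
one series each (regions for BOLD, channels for inputs).  Decimal points
only (locale-independent); values are written at 17 significant digits so
doubles round-trip exactly.

```
time	region1	region2
1	0.0123456789	-0.987654321
2	...
```

Parse errors (ragged rows, non-monotone or non-uniform time, missing
header) report the offending line number.

## Model configuration (YAML, schema_version 1)

```yaml
schema_version: 1
label: linear_2r
regions: 2
inputs: 1
connectivity:
  A: [[-0.55, -0.25], [-0.25, -0.55]]
  A_mask: [[1, 1], [1, 1]]          # 1 = free parameter, 0 = fixed constant
  C: [[0.6], [0.0]]
  C_mask: [[1], [0]]
  B: []                             # optional: one n x n matrix per input
  D: []                             # optional: one n x n matrix per region
priors:
  evolution_variance: 0.1           # i.i.d. shrinkage prior on free entries
  hemodynamic_variance: 0.0         # 0 = fixed at defaults; 1e-2 = empirical
  noise:
    stochastic: false
    state_noise_prior: [1.0, 0.1]   # Gamma shape, rate on the precision
    measurement_noise_prior: [1.0e-8, 1.0e-8]   # Jeffreys limit
    neural_to_hemo_variance_ratio: 100.0
hemodynamics: {kappa_s: 0.65, kappa_f: 0.41, tau_0: 2.0, alpha: 0.32,
               E_0: 0.34, V_0: 4.0, nu_0: 40.3, TE: 0.04, r_0: 25.0,
               epsilon_0: 1.0}
basis: {kind: none, K: 0}           # basis sets are attached programmatically
family_tags: {}
```

Unknown keys are rejected; validation reports *all* violations, and
configs from other schema versions fail with an explicit message.

## Session bundle (directory)

`bold.tsv`, `input.tsv`, optional `fluctuations.tsv`, `model.yaml`, and
`provenance.json` (TR, seeds, config hash, simulation settings — enough
to replay a simulated session exactly).  Simulated bundles may add
`trajectory.npz` with micro-time states and the realized noise draws.

## Posterior archive (directory)

`posterior.npz` — keyed arrays `mu`, `Sigma`, `trace`, and for stochastic
inversions `w_mean` and the smoothed state trajectories — plus
`manifest.json` with the free energy, convergence flag, parameter names
and the Gamma precision posteriors.

## Study tables (TSV)

One row per (session, analysis) with the design-cell columns
(`snr_db`, `NL`, `du` / `network`), `rep`, `seed`, `dcm_type`, `basis`,
a `status` column (`ok` or the failure reason), the metric columns
`mse_*` / `mcb_*` for the groups `params`, `states`, `input` (accuracy
study) or `F_A`, `F_B`, `LBF_AB` (discrimination study), plus `F` and
`converged`.
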