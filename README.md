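# aneumech

Identification of isotropic hyperelastic material models (Neo-Hookean, Yeoh,
3- and 5-parameter Mooney-Rivlin) from uniaxial tensile tests of vascular
tissue, with:

- **`aneumech.io_tensile`** — raw machine-record parsing (force/displacement
  CSV), stage segmentation, preconditioning-cycle removal, stress–stretch
  conversion (nominal stress `F/S0`, stretch `λ = 1 + Δl/l0`) and plateau
  truncation;
- **`aneumech.constitutive`** — the four model stress/energy forms, the
  linear-energy-part expressions and the coefficient stability conditions;
- **`aneumech.fitting`** — deterministic inequality-constrained linear least
  squares (exact active-set enumeration) and NRMSE scoring;
- **`aneumech.applicability`** — maximum valid stretch per model via
  expanding-prefix refits, cohort five-number summaries, and the
  status/deformation-regime model recommendation (boundaries λ_a = 1.76,
  λ_b = 2.31);
- **`aneumech.cohort_stats`** — ultimate stress/strain extraction and an
  exact (complete-enumeration) Mann-Whitney U test for small cohorts;
- **`aneumech.synthetic_data`** — seeded generators for curves, multi-stage
  specimen series with preconditioning, and ruptured/unruptured cohorts;
- **`aneumech.tables`** — packaged reference values (specimen geometry and
  ultimates, published coefficients, published stretch windows).

## CLI

```sh
# materialize a synthetic cohort (raw CSVs + metadata sidecar)
aneumech simulate --out-dir run --seed 7 --mode cohort --n-ruptured 5 --n-unruptured 3

# fit all four models per specimen -> fits.csv / fits.json
aneumech fit --raw-dir run/raw --metadata run/metadata.csv --out-dir run/out

# applicability limits per specimen x model + per-status cohort summary
aneumech limits --raw-dir run/raw --metadata run/metadata.csv --out-dir run/out

# ruptured vs unruptured rank tests + model recommendations
aneumech compare --metadata run/metadata.csv --out-dir run/out --metadata-only
```

Exit codes: 0 success, 2 validation error, 3 I/O error.  A YAML file passed
via `--config-file` sets defaults (column names, plateau parameters, fit
constraints, NRMSE threshold, regime boundaries); CLI flags override it.

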