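# Configuration files

## dose_thresholds.yaml

Per-ingredient ICS daily-dose bounds in mcg/day, used to assign low /
medium / high dose levels. The packaged default covers six common
ingredients with GINA-2018 adult bounds; pass `--thresholds` / a path to
`load_dose_thresholds` to override.

```yaml
fluticasone propionate: {low_max: 250, medium_max: 500}
budesonide: {low_max: 400, medium_max: 800}
```

`dose <= low_max` → low, `<= medium_max` → medium, above → high. An
ingredient absent from the table makes the dose level unknown, which marks
the profile dose-indeterminate.

## medications.yaml

NDC → product crosswalk: identity, ingredient list, drug class, strength,
and the canonical sig used by the synthetic generator.

```yaml
"00002-0110":
  generic_name: fluticasone propionate HFA 110
  ingredients: [fluticasone propionate]
  drug_class: ICS
  strength_value: 110
  strength_unit: mcg
  frequency: 2
  dose_amount: 2
  dose_unit: puff
```

## Simulation config (asthmactl synth --config sim.yaml)

All keys optional; omitted keys use the documented defaults.

```yaml
n_patients: 5000
seed: 11
step_probs: [0.345, 0.241, 0.140, 0.251, 0.011, 0.012]  # Steps 1-5, Undefined
missing_sig_fraction: 0.10
exclusion_noise:          # fraction of patients planted per violation
  no_asthma_dx: 0.02
  no_valid_act: 0.02
  untreated: 0.02
  insufficient_activity: 0.02
  copd: 0.02
  missing_birth_year: 0.02
outcome_model:
  intercept: -1.3862943611198906     # log 0.25
  step: {"2": -0.1543, "3": -0.0387, "4": 0.1484, "5": 0.4246, "undefined": 0.1070}
  age_per_year: 0.004                # centered at 44 years
  smoking: {former: 0.10, current: 0.30}
  bmi_category: {underweight: 0.10, overweight: 0.05, obese: 0.20, unknown: -0.05}
```

The config is validated before anything is generated: `step_probs` must sum
to 1, noise fractions must be non-negative and sum ≤ 1, and the outcome
model must keep every reachable probability ≤ 1 (otherwise the run aborts
with an error — probabilities are never clamped).
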