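# Exchange-format column dictionary

All six tables are UTF-8, comma-separated CSV with a header row, ISO-8601
dates (`YYYY-MM-DD`), and the empty string for a missing cell. Files are
written sorted by `patient_id`, then `date` (stable), so writes are
deterministic. Readers are strict: a cell that is neither empty nor
parseable aborts the load with the table and row index.

## patients.csv

| column | type | notes |
|---|---|---|
| patient_id | string | non-empty, unique |
| birth_year | int or empty | calendar year of birth |
| sex | enum | `male`, `female`, `unknown` |
| race_entries | packed list | `date:value` pairs joined by `\|`, e.g. `2016-01-02:white\|2017-03-04:asian`; free-text race strings |
| ethnicity_entries | packed list | same packing; values `hispanic` or `non_hispanic` |

## encounters.csv

| column | type | notes |
|---|---|---|
| patient_id | string | |
| date | date | |
| provider_specialty | string or empty | free text, e.g. `Family Medicine` |

## diagnoses.csv

| column | type | notes |
|---|---|---|
| patient_id | string | |
| date | date | |
| code_system | enum | `ICD9`, `ICD10`, `SNOMED` |
| code | string | non-empty; matched by prefix (e.g. `J45`) |

## prescriptions.csv

| column | type | notes |
|---|---|---|
| patient_id | string | |
| date | date | prescription written date |
| ndc | string | product identifier; grouping key for mode imputation |
| generic_name | string | |
| ingredients | packed list | ingredient names joined by `\|` |
| drug_class | enum | `SABA`, `SAMA`, `SABA_SAMA`, `ICS`, `ICS_LABA`, `LABA`, `LAMA`, `LTRA`, `MAST_CELL`, `METHYLXANTHINE`, `BIOLOGIC`, `OCS`, `OTHER` |
| strength_value | number > 0 or empty | per-actuation strength |
| strength_unit | enum or empty | `mcg` or `mg` |
| sig_frequency_per_day | number > 0 or empty | NLP-extracted |
| sig_dose_amount | number > 0 or empty | NLP-extracted (e.g. `2` in "2 puffs") |
| sig_dose_unit | string or empty | NLP-extracted (e.g. `puff`) |

The drug class is carried as an explicit column rather than inferred from
text; `medications.yaml` supplies an NDC → class/ingredient crosswalk for
populating it from external sources.

## act_records.csv

| column | type | notes |
|---|---|---|
| patient_id | string | |
| date | date | |
| item1..item5 | int 1–5 or empty | the five questionnaire responses |

## observations.csv

| column | type | notes |
|---|---|---|
| patient_id | string | |
| date | date | |
| kind | enum | `smoking_status` or `bmi` |
| value | mixed | smoking: `current smoker`, `former smoker`, `non-smoker`; bmi: number in kg/m², plausible range (5, 150) |

## ground_truth.csv (generator output, not a pipeline input)

`patient_id, planted_step, planted_control_status, planted_act_score,
age_years, sex, race, ethnicity, smoking, bmi_category, visit_type,
planted_exclusion_reason` — the planted exclusion reason is `none` for
patients intended to survive every filter.
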