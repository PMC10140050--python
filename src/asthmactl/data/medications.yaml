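# Drug-product catalog: NDC -> identity, ingredient list, class, strength and
# canonical sig (frequency/day, dose amount, dose unit).  This is the closed
# product vocabulary used by the synthetic generator and the default
# NDC -> class crosswalk for external data; replace or extend per dataset.
"00001-0001": {generic_name: albuterol sulfate HFA, ingredients: [albuterol], drug_class: SABA, strength_value: 90, strength_unit: mcg, frequency: 2, dose_amount: 2, dose_unit: puff}
"00001-0002": {generic_name: ipratropium bromide HFA, ingredients: [ipratropium], drug_class: SAMA, strength_value: 17, strength_unit: mcg, frequency: 4, dose_amount: 2, dose_unit: puff}
"00001-0003": {generic_name: albuterol-ipratropium, ingredients: [albuterol, ipratropium], drug_class: SABA_SAMA, strength_value: 103, strength_unit: mcg, frequency: 4, dose_amount: 1, dose_unit: puff}
"00002-0044": {generic_name: fluticasone propionate HFA 44, ingredients: [fluticasone propionate], drug_class: ICS, strength_value: 44, strength_unit: mcg, frequency: 2, dose_amount: 2, dose_unit: puff}
"00002-0110": {generic_name: fluticasone propionate HFA 110, ingredients: [fluticasone propionate], drug_class: ICS, strength_value: 110, strength_unit: mcg, frequency: 2, dose_amount: 2, dose_unit: puff}
"00002-0220": {generic_name: fluticasone propionate HFA 220, ingredients: [fluticasone propionate], drug_class: ICS, strength_value: 220, strength_unit: mcg, frequency: 2, dose_amount: 2, dose_unit: puff}
"00002-0090": {generic_name: budesonide DPI 90, ingredients: [budesonide], drug_class: ICS, strength_value: 90, strength_unit: mcg, frequency: 2, dose_amount: 2, dose_unit: inhalation}
"00002-0180": {generic_name: budesonide DPI 180, ingredients: [budesonide], drug_class: ICS, strength_value: 180, strength_unit: mcg, frequency: 2, dose_amount: 2, dose_unit: inhalation}
"00002-0500": {generic_name: budesonide inhalation suspension 0.25mg, ingredients: [budesonide], drug_class: ICS, strength_value: 0.25, strength_unit: mg, frequency: 2, dose_amount: 1, dose_unit: ampule}
"00003-0100": {generic_name: fluticasone-salmeterol 100/50, ingredients: [fluticasone propionate, salmeterol], drug_class: ICS_LABA, strength_value: 100, strength_unit: mcg, frequency: 2, dose_amount: 1, dose_unit: inhalation}
"00003-0250": {generic_name: fluticasone-salmeterol 250/50, ingredients: [fluticasone propionate, salmeterol], drug_class: ICS_LABA, strength_value: 250, strength_unit: mcg, frequency: 2, dose_amount: 1, dose_unit: inhalation}
"00003-0500": {generic_name: fluticasone-salmeterol 500/50, ingredients: [fluticasone propionate, salmeterol], drug_class: ICS_LABA, strength_value: 500, strength_unit: mcg, frequency: 2, dose_amount: 1, dose_unit: inhalation}
"00003-0080": {generic_name: budesonide-formoterol 80/4.5, ingredients: [budesonide, formoterol], drug_class: ICS_LABA, strength_value: 80, strength_unit: mcg, frequency: 2, dose_amount: 2, dose_unit: puff}
"00003-0160": {generic_name: budesonide-formoterol 160/4.5, ingredients: [budesonide, formoterol], drug_class: ICS_LABA, strength_value: 160, strength_unit: mcg, frequency: 2, dose_amount: 2, dose_unit: puff}
"00004-0050": {generic_name: salmeterol DPI, ingredients: [salmeterol], drug_class: LABA, strength_value: 50, strength_unit: mcg, frequency: 2, dose_amount: 1, dose_unit: inhalation}
"00005-0018": {generic_name: tiotropium bromide, ingredients: [tiotropium], drug_class: LAMA, strength_value: 18, strength_unit: mcg, frequency: 1, dose_amount: 1, dose_unit: capsule}
"00006-0010": {generic_name: montelukast sodium 10mg, ingredients: [montelukast], drug_class: LTRA, strength_value: 10, strength_unit: mg, frequency: 1, dose_amount: 1, dose_unit: tablet}
"00007-0800": {generic_name: cromolyn sodium nebulizer, ingredients: [cromolyn], drug_class: MAST_CELL, strength_value: 20, strength_unit: mg, frequency: 4, dose_amount: 1, dose_unit: ampule}
"00008-0300": {generic_name: theophylline ER 300mg, ingredients: [theophylline], drug_class: METHYLXANTHINE, strength_value: 300, strength_unit: mg, frequency: 1, dose_amount: 1, dose_unit: tablet}
"00009-0100": {generic_name: mepolizumab 100mg, ingredients: [mepolizumab], drug_class: BIOLOGIC, strength_value: 100, strength_unit: mg, frequency: 1, dose_amount: 1, dose_unit: vial}
"00010-0010": {generic_name: prednisone 10mg, ingredients: [prednisone], drug_class: OCS, strength_value: 10, strength_unit: mg, frequency: 1, dose_amount: 1, dose_unit: tablet}
"00011-0500": {generic_name: amoxicillin 500mg, ingredients: [amoxicillin], drug_class: OTHER, strength_value: 500, strength_unit: mg, frequency: 3, dose_amount: 1, dose_unit: capsule}
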