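# Total daily-dose upper bounds (mcg/day) per ICS ingredient, adults/adolescents.
# dose <= low_max -> low; dose <= medium_max -> medium; above -> high.
# Fully overridable; keys are lower-case ingredient names.
fluticasone propionate: {low_max: 250, medium_max: 500}
budesonide: {low_max: 400, medium_max: 800}
beclometasone: {low_max: 200, medium_max: 400}
mometasone: {low_max: 220, medium_max: 440}
ciclesonide: {low_max: 160, medium_max: 320}
fluticasone furoate: {low_max: 100, medium_max: 100}
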