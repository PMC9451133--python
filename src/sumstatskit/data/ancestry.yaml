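# Controlled vocabulary for sample ancestry categories, seeded from the
# standardized ancestry framework used by the major GWAS deposition resource.
# Editable configuration: unknown tokens are a WARNING, not an ERROR.
categories:
  - African American or Afro-Caribbean
  - African unspecified
  - Asian unspecified
  - Central Asian
  - East Asian
  - European
  - Greater Middle Eastern (Middle Eastern, North African, or Persian)
  - Hispanic or Latin American
  - Native American
  - Oceanian
  - Other
  - Other admixed ancestry
  - South Asian
  - South East Asian
  - Sub-Saharan African
  - NR
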