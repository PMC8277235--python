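# Information-model profiles for the expressiveness comparison, expressed as
# attribute subsets of the 12-attribute schema. The CEM and FHIR inventories
# here are approximations restricted to the attributes those EMR-oriented
# models share with guideline language (severity and laterality, plus CEM's
# assertion/uncertainty); extra config slots can be added freely.
profiles:
  - name: phenossu
    attributes: [assertion, frequency, age_specificity, sex_specificity,
                 severity_of_illness_specificity, temporal_pattern, severity,
                 appearance_color, sensation, laterality, spatial_pattern,
                 quadrant_pattern]
  - name: cem
    attributes: [assertion, severity, laterality]
  - name: fhir
    attributes: [severity, laterality]
  - name: concept_only
    attributes: []
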