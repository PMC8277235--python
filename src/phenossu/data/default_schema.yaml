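# Default 12-attribute schema: 5 presence + 4 manifestation + 3 spatial.
#
# Attribute and value codes are SNOMED-CT concept identifiers. Codes marked
# "best-effort" are plausible qualifier-value picks for sets whose exact
# composition is an editorial choice; the schema is fully config-driven, so a
# corrected value set drops in without any code change. Defaults ("present"
# for assertion, "none" elsewhere) are schema-level sentinels, not SNOMED
# annotations. Trigger terms are user-extensible surface cues; the shipped
# lists are deliberately disjoint across attributes.
version: "1.0"
attributes:
  # -------- presence: details about the presence of the phenotype --------
  - name: assertion
    code: "408729009"          # finding context (best-effort)
    category: presence
    default: present
    values:
      - {label: absent, code: "2667000", triggers: ["no", "without", "absence of", "denies"]}
      - {label: possible, code: "60022001", triggers: ["may", "might", "possibly", "include"]}
  - name: frequency
    code: "260864003"          # frequency qualifier (best-effort)
    category: presence
    default: none
    values:
      - {label: frequent, code: "70775006", triggers: ["common", "commonly", "often", "frequently"]}
      - {label: occasional, code: "84638005", triggers: ["sometimes", "occasionally"]}
      - {label: rare, code: "89292003", triggers: ["rare", "rarely", "uncommon"]}
  - name: age_specificity
    code: "424144002"          # current chronological age (best-effort)
    category: presence
    default: none
    values:
      - {label: child, code: "67822003", triggers: ["children", "infants", "pediatric patients"]}
      - {label: adult, code: "133936004", triggers: ["adults", "young adults"]}
      - {label: elderly, code: "105436006", triggers: ["elderly", "older people"]}
  - name: sex_specificity
    code: "263495000"          # gender (best-effort)
    category: presence
    default: none
    values:
      - {label: male, code: "248153007", triggers: ["men", "males"]}
      - {label: female, code: "248152002", triggers: ["women", "females"]}
  - name: severity_of_illness_specificity
    code: "246112005"          # severity context (best-effort)
    category: presence
    default: none
    values:
      - {label: mild_illness, code: "255604002", triggers: ["in uncomplicated cases"]}
      - {label: severe_illness, code: "24484000", triggers: ["in critical cases", "in complicated cases"]}
  # -------- manifestation: details about how the phenotype manifests --------
  - name: temporal_pattern
    code: "370134009"          # time aspect (best-effort)
    category: manifestation
    default: none
    values:
      - {label: acute, code: "373933003", triggers: ["sudden onset", "abrupt onset", "acute"]}
      - {label: chronic, code: "90734009", triggers: ["chronic", "long-lasting", "persistent"]}
      - {label: intermittent, code: "7087005", triggers: ["intermittent", "relapsing"]}
  - name: severity
    code: "272141005"          # severity
    category: manifestation
    default: none
    values:
      - {label: mild, code: "255604002", triggers: ["mild", "slight"]}
      - {label: moderate, code: "6736007", triggers: ["moderate"]}
      - {label: severe, code: "24484000", triggers: ["severe", "intense"]}
  - name: appearance_color
    code: "263714004"          # color (best-effort)
    category: manifestation
    default: none
    values:
      - {label: red, code: "386713009", triggers: ["red", "reddish"]}
      - {label: yellow, code: "371244009", triggers: ["yellow", "yellowish"]}
      - {label: pale, code: "398979000", triggers: ["pale", "whitish"]}
  - name: sensation
    code: "276435006"          # pain / sensation quality (best-effort)
    category: manifestation
    default: none
    values:
      - {label: painful, code: "22253000", triggers: ["painful", "tender"]}
      - {label: itchy, code: "418290006", triggers: ["itchy", "itching"]}
      - {label: burning, code: "90673000", triggers: ["burning"]}
  # -------- spatial: details about the spatial distribution --------
  - name: laterality
    code: "272741003"          # laterality
    category: spatial
    default: none
    values:
      - {label: unilateral, code: "66459002", triggers: ["unilateral", "one-sided", "on one side"]}
      - {label: bilateral, code: "51440002", triggers: ["bilateral", "on both sides"]}
  - name: spatial_pattern
    code: "372433007"          # spatial qualifier (best-effort)
    category: spatial
    default: none
    values:
      - {label: localized, code: "255470008", triggers: ["localized", "well-demarcated"]}
      - {label: generalized, code: "60132005", triggers: ["generalized", "widespread", "diffuse"]}
  - name: quadrant_pattern
    code: "255549009"          # anatomical quadrant (best-effort)
    category: spatial
    default: none
    values:
      - {label: upper_right, code: "255497008", triggers: ["upper right"]}
      - {label: lower_right, code: "255498003", triggers: ["lower right"]}
      - {label: upper_left, code: "255499006", triggers: ["upper left"]}
      - {label: lower_left, code: "255500002", triggers: ["lower left"]}
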