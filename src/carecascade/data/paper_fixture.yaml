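# Printed summary counts of the 2020 Cambodian T2D cascade-of-care survey
# (5 operational districts, adults aged >=40). Used by reconstruct_fixture
# to build a deterministic individual-level dataset that reproduces every
# count below exactly.
total_n: 5072
raised_fbg: 614
cascade:
  cases: 560
  tested: 353
  diagnosed: 309
  in_care: 279
  in_treatment: 273
  under_control: 60
advice_bundle: 130
# Each covariate table: level -> [diagnosed cases, undiagnosed cases]
covariate_tables:
  age_group:
    "40-49": [29, 55]
    "50-59": [125, 94]
    "60+": [155, 102]
  sex:
    male: [67, 75]
    female: [242, 176]
  marital:
    married_or_with_spouse: [204, 169]
    widowed_or_not_with_spouse: [102, 77]
    never: [3, 5]
  education:
    none_or_less_than_primary: [95, 69]
    primary: [179, 147]
    secondary_or_higher: [35, 35]
  wealth_quintile:
    1: [48, 52]
    2: [54, 48]
    3: [67, 47]
    4: [67, 46]
    5: [73, 58]
  setting:
    coexistence: [51, 51]
    community_based: [58, 54]
    health_center_based: [60, 57]
    health_center_with_context: [62, 41]
    hospital_based: [78, 48]
# Diagnosing provider among the diagnosed, by setting: [public, private, other]
provider_counts:
  coexistence: [26, 22, 3]
  community_based: [16, 41, 1]
  health_center_based: [22, 37, 1]
  health_center_with_context: [27, 35, 0]
  hospital_based: [30, 42, 6]
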