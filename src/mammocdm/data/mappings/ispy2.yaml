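# ISPY2 — I-SPY 2 breast DCE-MRI trial clinical table.
# 9 source concepts feed 12 CDM fields: detailed+generic retention
# (neoadjuvant chemotherapy yes/no AND the medication list from "ARM"),
# plus study-design constants (every subject is female and received
# neoadjuvant chemotherapy; cyclophosphamide was given in every arm on
# top of the arm-specific agent).
dataset: ISPY2
subject_column: SUBJECTID
skip_rows: 0
source_concept_count: 9
exclusion: blank_id
rules:
  - field: age
    kind: parser
    derivation: numeric
    source: [AGE]
  - field: race
    kind: direct_recode
    source: [RACE]
    map:
      "white": 8527
      "black": 8516
      "asian": 8515
      "native american": 8657
      "pacific islander": 8557
  - field: hr_status
    kind: direct_recode
    source: [HR]
    map: {"1": 9191, "0": 9189}
  - field: her2_status
    kind: direct_recode
    source: [HER2]
    map: {"1": 9191, "0": 9189}
  - field: laterality
    kind: direct_recode
    source: [LATERALITY]
    map: {"l": 4300877, "r": 4229870, "bilateral": 4141849}
  - field: menopausal_status
    kind: direct_recode
    source: [MENOPAUSE]
    map: {"pre": 4072263, "post": 4087171, "peri": 4150052}
  - field: treatment_response_pcr
    kind: direct_recode
    source: [PCR]
    map: {"1": 36769180, "0": 36769181}
  - field: response_category
    kind: direct_recode
    source: [PCR]
    map: {"1": 4122371, "0": 763013}
  - field: rcb_class
    kind: direct_recode
    source: [RCB]
    map: {"0": 1633050, "1": 1633051, "2": 1633052, "3": 1633053}
  - field: neoadjuvant_chemotherapy
    kind: constant
    value: 4188539
  - field: gender
    kind: constant
    value: 8532
  - field: neoadjuvant_chemo_medication
    kind: derived
    derivation: map_multi_always
    source: [ARM]
    params:
      always: [1310317]   # cyclophosphamide, administered in every arm
    map:
      "paclitaxel": 1378382
      "ganitumab": [40239056, 1378382]
      "neratinib": [35606533, 1378382]
      "veliparib": [42900250, 1344905, 1378382]
      "trastuzumab": [1387104, 1378382]
      "pertuzumab": [40244266, 1387104, 1378382]
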