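# ISPY1 — I-SPY 1/ACRIN 6657 trial clinical table.
# 17 source concepts feed 14 CDM fields. Hormone-receptor status is given
# directly ("HR Pos"); neoadjuvant chemotherapy and gender are study-design
# constants (a neoadjuvant trial of women with breast cancer).
dataset: ISPY1
subject_column: SUBJECTID
skip_rows: 0
source_concept_count: 17
exclusion: blank_id
rules:
  - field: age
    kind: parser
    derivation: numeric
    source: [AGE]
  - field: race
    kind: direct_recode
    source: [RACE_ID]
    map: {"1": 8527, "3": 8516, "4": 8515, "5": 8657, "6": 8557}
  - field: er_status
    kind: direct_recode
    source: [ERpos]
    map: {"1": 4167696, "0": 4261933}
  - field: pr_status
    kind: direct_recode
    source: [PgRpos]
    map: {"1": 4085345, "0": 4078166}
  - field: hr_status
    kind: direct_recode
    source: ["HR Pos"]
    map: {"1": 9191, "0": 9189}
  - field: her2_status
    kind: direct_recode
    source: [HER2MostPos]
    map: {"1": 9191, "0": 9189}
  - field: laterality
    kind: direct_recode
    source: [Laterality]
    map: {"l": 4300877, "r": 4229870}
  - field: menopausal_status
    kind: direct_recode
    source: [MENO]
    map: {"1": 4072263, "2": 4150052, "3": 4087171}
  - field: treatment_response_pcr
    kind: direct_recode
    source: [PCR]
    map: {"1": 36769180, "0": 36769181}
  - field: rcb_class
    kind: direct_recode
    source: [RCB]
    map: {"0": 1633050, "1": 1633051, "2": 1633052, "3": 1633053}
  - field: vital_status
    kind: direct_recode
    source: [SURVSTAT]
    map: {"7": 4230556, "8": 4306655}
  - field: followup_months
    kind: parser
    derivation: numeric
    source: [FU_MONTHS]
  - field: neoadjuvant_chemotherapy
    kind: constant
    value: 4188539
  - field: gender
    kind: constant
    value: 8532
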