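# NACT — Breast-MRI-NACT-Pilot clinical table.
# 41 source concepts feed 23 CDM fields. Study-design constants: every
# subject received neoadjuvant chemotherapy and, per protocol, adjuvant
# radiotherapy. The comment field of subject 27 ("declined standard-of-care
# post-surgery radiation and hormonal treatments") is encoded as explicit
# per-subject overrides applied after all rules.
dataset: NACT
subject_column: PatientID
skip_rows: 0
source_concept_count: 41
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
      "american indian": 8657
      "pacific islander": 8557
  - field: er_status
    kind: direct_recode
    source: [ER]
    map: {"pos": 4167696, "neg": 4261933}
  - field: pr_status
    kind: direct_recode
    source: [PR]
    map: {"pos": 4085345, "neg": 4078166}
  - field: hr_status
    kind: direct_recode
    source: [HR]
    map: {"pos": 9191, "neg": 9189}
  - field: her2_status
    kind: direct_recode
    source: [HER2]
    map: {"pos": 9191, "neg": 9189}
  - field: menopausal_status
    kind: direct_recode
    source: [MENO]
    map: {"pre": 4072263, "peri": 4150052, "post": 4087171}
  - field: laterality
    kind: direct_recode
    source: [LATERALITY]
    map: {"l": 4300877, "r": 4229870}
  - field: tumor_size_mm
    kind: parser
    derivation: numeric
    source: ["TUMOR SIZE (mm)"]
  - field: tumor_grade
    kind: direct_recode
    source: [SBR_GRADE]
    map: {"i": 1634371, "ii": 1634752, "iii": 1635326}
  - field: clinical_stage
    kind: direct_recode
    source: [STAGE]
    map:
      "i": 1634319
      "ii": 1634104
      "iia": 1635656
      "iib": 1633483
      "iii": 1634949
      "iiia": 1633570
      "iiib": 1635785
      "iv": 1635910
  - field: treatment_response_pcr
    kind: direct_recode
    source: [PCR]
    map: {"1": 36769180, "0": 36769181}
  - field: response_category
    kind: direct_recode
    source: [RESPONSE]
    map:
      "cr": 4122371
      "pr": 4121623
      "sd": 4252777
      "pd": 4216866
  - field: surgery
    kind: direct_recode
    source: [SURGERY]
    map: {"1": 4188539, "0": 4188540}
  - field: surgery_type
    kind: direct_recode
    source: [SURGERY_TYPE]
    map: {"mastectomy": 4181323, "lumpectomy": 4129190}
  - field: recurrence
    kind: direct_recode
    source: [RECURRENCE]
    map: {"1": 4188539, "0": 4188540}
  - field: vital_status
    kind: direct_recode
    source: [VITAL]
    map: {"alive": 4230556, "dead": 4306655}
  - field: followup_months
    kind: parser
    derivation: numeric
    source: [FU_MONTHS]
  - field: chemo_regimen
    kind: direct_recode
    source: [CHEMO_REGIMEN]
    map:
      "ac": 35804771
      "ac-t": 35804772
      "cmf": 35804776
      "fec": 35804777
      "fac": 35804778
  - field: adjuvant_hormone_therapy
    kind: direct_recode
    source: [HORMONE_THERAPY]
    map: {"1": 4188539, "0": 4188540}
  - field: neoadjuvant_chemotherapy
    kind: constant
    value: 4188539
  - field: adjuvant_radiotherapy
    kind: constant
    value: 4188539    # per study protocol, all subjects
  - field: gender
    kind: constant
    value: 8532
overrides:
  - subject: "27"
    field: adjuvant_hormone_therapy
    value: 4188540
    note: "comment: declined standard-of-care post-surgery hormonal treatment"
  - subject: "27"
    field: adjuvant_radiotherapy
    value: 4188540
    note: "comment: declined standard-of-care post-surgery radiation"
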