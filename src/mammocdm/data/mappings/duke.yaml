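# DUKE — Duke-Breast-Cancer-MRI clinical spreadsheet.
# The distributed file carries one decorative header row above the real
# column names (skip_rows: 1). 74 source concepts feed 36 CDM fields.
# Notable rules: hormone-receptor status is derived from the ER/PR
# binaries; the free-text "Tumor Location" clock position ("L 2 with
# calcs", "R4-5", "L 11:30") is parsed to an ICD-O-3 quadrant; the
# numeric pathological T/N/M staging uses -1 for the X category.
dataset: DUKE
subject_column: "Patient ID"
skip_rows: 1
source_concept_count: 74
exclusion: blank_id
rules:
  - field: age
    kind: parser
    derivation: numeric
    source: [Age]
  - field: gender
    kind: constant
    value: 8532
  - field: race
    kind: direct_recode
    source: [Race]
    map:
      "white": 8527
      "black": 8516
      "asian": 8515
      "american indian": 8657
      "pacific islander": 8557
  - field: ethnicity
    kind: direct_recode
    source: [Ethnicity]
    map:
      "hispanic": 38003563
      "not hispanic": 38003564
  - field: menopausal_status
    kind: direct_recode
    source: ["Menopause (at diagnosis)"]
    map: {"0": 4072263, "1": 4087171}
  - field: er_status
    kind: direct_recode
    source: [ER]
    map: {"1": 4167696, "0": 4261933}
  - field: pr_status
    kind: direct_recode
    source: [PR]
    map: {"1": 4085345, "0": 4078166}
  - field: hr_status
    kind: derived
    derivation: hr_from_er_pr
    source: [ER, PR]
  - field: her2_status
    kind: direct_recode
    source: [HER2]
    map: {"1": 9191, "0": 9189, "2": 45879592}
  - field: ki67_percent
    kind: parser
    derivation: numeric
    source: ["Ki67 (percent)"]
  - field: tumor_position
    kind: parser
    derivation: tumor_position
    source: ["Tumor Location"]
  - field: laterality
    kind: parser
    derivation: laterality_from_position
    source: ["Tumor Location"]
  - field: histologic_type
    kind: direct_recode
    source: ["Histologic type"]
    map:
      "ductal": 36403105
      "lobular": 36403118
      "mixed": 36403127
      "mucinous": 36403092
      "tubular": 36403061
  - field: tumor_grade
    kind: direct_recode
    source: ["Nottingham grade"]
    map: {"1": 1634371, "2": 1634752, "3": 1635326}
  - field: tumor_size_mm
    kind: parser
    derivation: numeric
    source: ["Tumor Size (mm)"]
  - field: pt_category
    kind: direct_recode
    source: ["Staging(Tumor Size)#(Tx replaced by -1)[T]"]
    map:
      "-1": 1635956
      "0": 1633327
      "1": 1634447
      "2": 1634209
      "3": 1635562
      "4": 1634654
  - field: pn_category
    kind: direct_recode
    source: ["Staging(Nodes)#(Nx replaced by -1)[N]"]
    map:
      "-1": 1633440
      "0": 1634200
      "1": 1634434
      "2": 1634119
      "3": 1635420
      "4": 1635420
  - field: pm_category
    kind: direct_recode
    source: ["Staging(Metastasis)#(Mx -replaced by -1)[M]"]
    map:
      "-1": 1633547
      "0": 1634006
      "1": 1635142
  - field: cn_category
    kind: direct_recode
    source: ["Clinical Nodal Status"]
    map: {"0": 1634720, "1": 1633823, "2": 1635233, "3": 1634301}
  - field: clinical_stage
    kind: direct_recode
    source: ["Overall Stage"]
    map:
      "0": 1633861
      "i": 1634319
      "ia": 1635458
      "ib": 1633720
      "ii": 1634104
      "iia": 1635656
      "iib": 1633483
      "iii": 1634949
      "iiia": 1633570
      "iiib": 1635785
      "iiic": 1634038
      "iv": 1635910
  - field: surgical_margin
    kind: direct_recode
    source: ["Surgical Margin"]
    map: {"negative": 35918585, "positive": 35918586}
  - field: neoadjuvant_chemotherapy
    kind: direct_recode
    source: ["Neoadjuvant Chemotherapy"]
    map: {"1": 4188539, "0": 4188540}
  - field: neoadjuvant_chemo_medication
    kind: derived
    derivation: meds_from_flags
    source:
      - "NAC Paclitaxel"
      - "NAC Cyclophosphamide"
      - "NAC Doxorubicin"
      - "NAC Carboplatin"
      - "NAC Trastuzumab"
    map:
      "nac paclitaxel": 1378382
      "nac cyclophosphamide": 1310317
      "nac doxorubicin": 1338512
      "nac carboplatin": 1344905
      "nac trastuzumab": 1387104
  - field: adjuvant_chemotherapy
    kind: direct_recode
    source: ["Adjuvant Chemotherapy"]
    map: {"1": 4188539, "0": 4188540}
  - field: adjuvant_radiotherapy
    kind: direct_recode
    source: ["Adjuvant Radiation Therapy"]
    map: {"1": 4188539, "0": 4188540}
  - field: adjuvant_hormone_therapy
    kind: direct_recode
    source: ["Adjuvant Endocrine Therapy"]
    map: {"1": 4188539, "0": 4188540}
  - field: hormone_therapy_medication
    kind: derived
    derivation: meds_from_flags
    source:
      - "Endocrine Tamoxifen"
      - "Endocrine Anastrozole"
      - "Endocrine Letrozole"
    map:
      "endocrine tamoxifen": 1436678
      "endocrine anastrozole": 1348265
      "endocrine letrozole": 1347387
  - field: anti_her2_therapy
    kind: direct_recode
    source: ["Anti-Her2 Neu Therapy"]
    map: {"1": 4188539, "0": 4188540}
  - field: surgery
    kind: direct_recode
    source: [Surgery]
    map: {"1": 4188539, "0": 4188540}
  - field: surgery_type
    kind: direct_recode
    source: ["Type of Surgery"]
    map:
      "mastectomy": 4181323
      "lumpectomy": 4129190
      "none": 4140805
  - field: recurrence
    kind: direct_recode
    source: ["Recurrence event(s)"]
    map: {"1": 4188539, "0": 4188540}
  - field: recurrence_site
    kind: direct_recode
    source: ["Recurrence Location"]
    map:
      "local": 4139011
      "regional": 4146252
      "distant": 4194252
  - field: vital_status
    kind: direct_recode
    source: ["Vital Status"]
    map: {"alive": 4230556, "dead": 4306655}
  - field: followup_months
    kind: parser
    derivation: numeric
    source: ["Follow Up (months)"]
  - field: treatment_response_pcr
    kind: direct_recode
    source: ["Pathologic response to Neoadjuvant Therapy"]
    map: {"1": 36769180, "0": 36769181}
  - field: response_category
    kind: direct_recode
    source: ["Clinical Response"]
    map:
      "cr": 4122371
      "pr": 4121623
      "sd": 4252777
      "pd": 4216866
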