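# TCGA_BRCA — The Cancer Genome Atlas breast invasive carcinoma clinical
# table. 110 source concepts feed 27 CDM fields. Tumor site arrives as
# ICD-O-3 topography codes directly; pathological N carries detailed
# subcategories ("N1a", "N0 (i-)") which are retained as detailed codes;
# follow-up arrives in days and is converted to months.
dataset: TCGA_BRCA
subject_column: bcr_patient_barcode
skip_rows: 0
source_concept_count: 110
exclusion: blank_id
rules:
  - field: age
    kind: parser
    derivation: numeric
    source: [age_at_initial_pathologic_diagnosis]
  - field: gender
    kind: direct_recode
    source: [gender]
    map: {"female": 8532, "male": 8507}
  - field: race
    kind: direct_recode
    source: [race]
    map:
      "white": 8527
      "black or african american": 8516
      "asian": 8515
      "american indian or alaska native": 8657
      "native hawaiian or other pacific islander": 8557
  - field: ethnicity
    kind: direct_recode
    source: [ethnicity]
    map:
      "hispanic or latino": 38003563
      "not hispanic or latino": 38003564
  - field: menopausal_status
    kind: direct_recode
    source: [menopause_status]
    map:
      "pre": 4072263
      "peri": 4150052
      "post": 4087171
      "indeterminate": 763013
  - field: er_status
    kind: direct_recode
    source: [er_status_by_ihc]
    map: {"positive": 4167696, "negative": 4261933, "indeterminate": 763013}
  - field: pr_status
    kind: direct_recode
    source: [pr_status_by_ihc]
    map: {"positive": 4085345, "negative": 4078166, "indeterminate": 763013}
  - field: hr_status
    kind: derived
    derivation: hr_from_er_pr
    source: [er_status_by_ihc, pr_status_by_ihc]
  - field: her2_status
    kind: direct_recode
    source: [her2_status_by_ihc]
    map: {"positive": 9191, "negative": 9189, "equivocal": 45879592}
  - field: tumor_position
    kind: direct_recode
    source: [icd_o_3_site]
    map:
      "c50.0": 36402331
      "c50.1": 36402332
      "c50.2": 36402333
      "c50.3": 36402334
      "c50.4": 36402335
      "c50.5": 36402336
      "c50.6": 36402337
      "c50.8": 36402338
      "c50.9": 36402339
  - field: histologic_type
    kind: direct_recode
    source: [icd_o_3_histology]
    map:
      "8500/3": 36403105
      "8520/3": 36403118
      "8522/3": 36403127
      "8480/3": 36403092
      "8211/3": 36403061
  - field: laterality
    kind: direct_recode
    source: [laterality]
    map: {"left": 4300877, "right": 4229870, "bilateral": 4141849}
  - field: pt_category
    kind: direct_recode
    source: [pathologic_T]
    map:
      "tx": 1635956
      "t0": 1633327
      "tis": 1633672
      "t1": 1634447
      "t1mi": 1635524
      "t1a": 1633310
      "t1b": 1634512
      "t1c": 1635131
      "t2": 1634209
      "t3": 1635562
      "t4": 1634654
      "t4a": 1633357
      "t4b": 1634747
      "t4c": 1633591
      "t4d": 1635843
  - field: pn_category
    kind: direct_recode
    source: [pathologic_N]
    map:
      "nx": 1633440
      "n0": 1634200
      "n0 (i-)": 1635020
      "n0 (i+)": 1635064
      "n0 (mol-)": 1633272
      "n1": 1634434
      "n1mi": 1635102
      "n1a": 1633982
      "n1b": 1634619
      "n1c": 1635320
      "n2": 1634119
      "n2a": 1633401
      "n2b": 1635704
      "n3": 1635420
      "n3a": 1633235
      "n3b": 1634877
      "n3c": 1635618
  - field: pm_category
    kind: direct_recode
    source: [pathologic_M]
    map: {"mx": 1633547, "m0": 1634006, "m1": 1635142}
  - field: clinical_stage
    kind: direct_recode
    source: [pathologic_stage]
    map:
      "stage 0": 1633861
      "stage i": 1634319
      "stage ia": 1635458
      "stage ib": 1633720
      "stage ii": 1634104
      "stage iia": 1635656
      "stage iib": 1633483
      "stage iii": 1634949
      "stage iiia": 1633570
      "stage iiib": 1635785
      "stage iiic": 1634038
      "stage iv": 1635910
      "stage x": 1633149
  - field: surgical_margin
    kind: direct_recode
    source: [margin_status]
    map: {"negative": 35918585, "positive": 35918586, "close": 763013}
  - field: surgery
    kind: direct_recode
    source: [surgical_procedure_first]
    map:
      "mastectomy": 4188539
      "lumpectomy": 4188539
      "other": 4188539
  - field: surgery_type
    kind: direct_recode
    source: [surgical_procedure_first]
    map:
      "mastectomy": 4181323
      "lumpectomy": 4129190
      "other": 763013
  - field: adjuvant_radiotherapy
    kind: direct_recode
    source: [radiation_therapy]
    map: {"yes": 4188539, "no": 4188540}
  - field: adjuvant_chemotherapy
    kind: direct_recode
    source: [pharmaceutical_tx_adjuvant]
    map: {"yes": 4188539, "no": 4188540}
  - field: adjuvant_hormone_therapy
    kind: direct_recode
    source: [hormone_therapy]
    map: {"yes": 4188539, "no": 4188540}
  - field: recurrence
    kind: direct_recode
    source: [new_tumor_event_after_initial_treatment]
    map: {"yes": 4188539, "no": 4188540}
  - field: recurrence_site
    kind: direct_recode
    source: [new_neoplasm_event_type]
    map:
      "local recurrence": 4139011
      "locoregional recurrence": 4146252
      "distant metastasis": 4194252
  - field: vital_status
    kind: direct_recode
    source: [vital_status]
    map: {"alive": 4230556, "dead": 4306655}
  - field: followup_months
    kind: derived
    derivation: months_from_days
    source: [days_to_last_followup]
  - field: neoadjuvant_chemotherapy
    kind: direct_recode
    source: [history_of_neoadjuvant_treatment]
    map: {"yes": 4188539, "no": 4188540}
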