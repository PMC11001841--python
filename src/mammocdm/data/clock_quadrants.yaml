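# Breast clock-face position -> ICD-O-3 topography quadrant mapping.
#
# Convention: patient-facing clock. On the LEFT breast the outer (lateral)
# half spans 12 -> 6 going clockwise, so sectors [12,3) upper-outer,
# [3,6) lower-outer, [6,9) lower-inner, [9,12) upper-inner. The RIGHT
# breast is the mirror image. Boundary hours (12, 3, 6, 9) belong to the
# clockwise-following sector, which the half-open intervals encode.
# Hours are taken modulo 12 (12:00 -> 0.0, 11:30 -> 11.5, range "4-5" ->
# midpoint 4.5).
quadrant_codes:
  UOQ: 36402335   # C50.4 Upper-outer quadrant of breast
  LOQ: 36402336   # C50.5 Lower-outer quadrant of breast
  LIQ: 36402334   # C50.3 Lower-inner quadrant of breast
  UIQ: 36402333   # C50.2 Upper-inner quadrant of breast
  NOS: 36402339   # C50.9 Breast, NOS (laterality known, no parsable clock)
# sector order = [0,3), [3,6), [6,9), [9,12) on the hour-mod-12 axis
sectors:
  left: [UOQ, LOQ, LIQ, UIQ]
  right: [UIQ, LIQ, LOQ, UOQ]
laterality_codes:
  left: 4300877
  right: 4229870
  bilateral: 4141849
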