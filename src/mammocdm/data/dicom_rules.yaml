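# Series-classification rule configuration.
#
# The tag combinations are a reconstruction of how breast-MRI series can
# be told apart from header metadata alone; they are configuration, not
# hard-coded truth, because series descriptions are free text and
# site-dependent and anonymization removes tags unevenly across
# collections.
dce_flip_angle_threshold: 20.0   # degrees; gradient-echo 3D below this reads as DCE
obliquity_threshold: 0.8         # min |largest normal component| before OBLIQUE
diffusion_description_patterns:
  - "dwi"
  - "diffusion"
  - "adc"
  - "trace"
  - "\\bdif\\b"
t2_description_patterns:
  - "t2"
  - "stir"
  - "tirm"
t1_description_patterns:
  - "t1"
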