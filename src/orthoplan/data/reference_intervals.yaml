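# Default reference intervals for the cephalometric battery, per sex.
# Values follow standard Chinese-population adult cephalometric norms
# (angles in degrees, distances in mm, ratios in percent).  Midpoints are
# the planner's default targets; edit freely for a different population.
SNA:
  female: [79.0, 86.0]
  male: [79.8, 86.2]
SNB:
  female: [75.9, 83.1]
  male: [76.2, 83.4]
ANB:
  female: [0.5, 5.5]
  male: [0.3, 5.3]
SNPog:
  female: [76.0, 84.0]
  male: [76.5, 84.5]
OP_FHP_pitch:
  female: [5.5, 12.5]
  male: [5.0, 12.0]
OP_FHP_roll:
  female: [-2.0, 2.0]
  male: [-2.0, 2.0]
OrU6_ratio:
  female: [95.0, 105.0]
  male: [95.0, 105.0]
GoMe_ratio:
  female: [95.0, 105.0]
  male: [95.0, 105.0]
Pog_MSP:
  female: [-2.0, 2.0]
  male: [-2.0, 2.0]
NANS_ANSMe:
  female: [77.0, 87.0]
  male: [77.0, 87.0]
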