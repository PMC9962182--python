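# Default fall-detection skeleton: five IMU placements joined by the
# anatomical chain through the trunk. S1..S5 ordering matches the sensor
# numbering on the body (left ankle, right trouser pocket, waist, neck,
# left wrist); the waist serves as the gravity-centre proxy.
nodes:
  - left_ankle    # S1
  - right_pocket  # S2
  - waist         # S3
  - neck          # S4
  - left_wrist    # S5
edges:
  - [left_ankle, right_pocket]
  - [right_pocket, waist]
  - [waist, neck]
  - [neck, left_wrist]
center: waist
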