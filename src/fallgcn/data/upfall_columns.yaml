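# Column mapping for per-frame sensor CSV files.
#
# The reader is dialect-agnostic: this file names the timestamp, label and
# metadata columns, and lists the six channel columns of each sensor node in
# skeleton order. Point --column-map at an edited copy to ingest a different
# CSV export (e.g. the consolidated UP-Fall download) without code changes.
time_column: timestamp
label_column: label
subject_column: subject
activity_column: activity
trial_column: trial
sensors:
  - node: left_ankle
    columns: [s1_acc_x, s1_acc_y, s1_acc_z, s1_gyro_x, s1_gyro_y, s1_gyro_z]
  - node: right_pocket
    columns: [s2_acc_x, s2_acc_y, s2_acc_z, s2_gyro_x, s2_gyro_y, s2_gyro_z]
  - node: waist
    columns: [s3_acc_x, s3_acc_y, s3_acc_z, s3_gyro_x, s3_gyro_y, s3_gyro_z]
  - node: neck
    columns: [s4_acc_x, s4_acc_y, s4_acc_z, s4_gyro_x, s4_gyro_y, s4_gyro_z]
  - node: left_wrist
    columns: [s5_acc_x, s5_acc_y, s5_acc_z, s5_gyro_x, s5_gyro_y, s5_gyro_z]
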