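# Walking back and forth with roll variation, degraded IMU stream included.
geometry:
  span_l_mm: 1726.0
  spring_length_mm: 200.0
  sensor_section_end_mm: 163.0
  tape_width_mm: 200.0
model:
  segment_ratio: 0.85
  spring_coeff: 2.0
  small_angle_deg: 0.1
spring_coeff: 2.0
rate_hz: 200.0
lift_mm: 150.0
drift:
  pitch_drift_rate: -0.05   # deg/s, one-sided
  yaw_drift_rate: 0.02      # deg/sqrt(s) random-walk step scale
  roll_drift_rate: 0.0
  noise_sigma: 0.05         # deg white noise
  seed: 0
keyframes:
  - {t: 0.0, x: -300.0, depth: 60.0, y: 10.0, roll: 0.0}
  - {t: 1.0, x: -150.0, depth: 220.0, y: 20.0, roll: 6.0}
  - {t: 2.0, airborne: true}
  - {t: 2.4, x: 150.0, depth: 180.0, y: -15.0, roll: -4.0}
  - {t: 3.5, x: 300.0, depth: 260.0, y: -25.0, roll: -9.0}
  - {t: 4.5, airborne: true}
  - {t: 5.0, x: 0.0, depth: 120.0, y: 0.0, roll: 0.0}
  - {t: 6.0, x: -250.0, depth: 240.0, y: 15.0, roll: 7.0}
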