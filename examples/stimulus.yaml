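# A rigid sphere of 10 cm diameter approaching at 2 m/s, contact after 3 s.
pipeline: kinematics
stimulus:
  diameter_m: 0.10
  speed_m_s: 2.0
  ttc_s: 3.0
  dt_s: 0.001
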