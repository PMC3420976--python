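# Corrected m-Tau observer used for simulating psychometric curves.
xi_params:
  mu: 0.5          # leakage, rad/s
  w: 1.0           # correction weight (0 -> m-Tau, 1 -> tau-like)
  xi_theta: 0.9    # filter memory, angular size
  xi_theta_dot: 0.9
  kappa: 0.0       # offset, s
noise:
  p_theta: 0.1
  p_theta_dot: 0.1
  noise_mode: relative
trial:
  tp_s: 1.0
  n_avg: 50        # averaging window, samples (50 ms at dt = 1 ms)
  n_trials: 200
  dt_s: 0.001
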