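# Constant-step grid over a subset of the eight observer parameters
# (mu, w, xi_theta, xi_theta_dot, kappa, p_theta, p_theta_dot, n_avg);
# parameters not listed stay at their base values.
grid:
  xi_theta_dot: [0.0, 0.6, 0.9]
  kappa: [-0.05, 0.0, 0.05]
  p_theta: [0.1, 0.2, 0.4]
trial:
  tp_s: 1.0
  n_avg: 10
  n_trials: 100
  dt_s: 0.005
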