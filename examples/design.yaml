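# Before/after discrimination design: seven ttc levels, two disc sizes,
# five presentation times, reference beep at 2.75 s.  Starting distances
# are drawn per condition from the given interval with v = d0 / ttc.
ttc_levels_s: [2.0, 2.25, 2.5, 2.75, 3.0, 3.25, 3.5]   # default: invented magnitude, overridable
diameters_m: [0.04, 0.08]                              # default: invented magnitude, overridable
presentation_times_s: [0.5, 1.0, 1.5, 2.0, 2.5]        # default: invented magnitude, overridable
t_ref_s: 2.75                                          # default: invented magnitude, overridable
d0_interval_m: [10.0, 25.0]                            # default: invented magnitude, overridable
d0_seed: 12345
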