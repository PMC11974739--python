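# synthetic center-out session, desk scale
n_neurons: 30
T: 55
prep_bins: 25
bin_width: 0.01
n_targets: 8
trials_per_epoch: {BL: 8, AD: 8, WO: 8}
osc_freq: 5.0
osc_amplitude: 34.0
feedback_lag: 0.090
feedback_gain: 0.055
base_rate: 45.0
seed: 1
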