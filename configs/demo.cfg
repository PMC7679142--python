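# Demo pipeline configuration: a small recall session that runs the whole
# chain (simulate -> bin -> behavior -> decode -> te -> sfc -> report) in a
# few minutes on one CPU.
seed = 7
session_length = 420
n_trials_per_cs = 4
n_aIC = 12
n_pIC = 12
n_CE_SST = 8
n_CE_PKCd = 8
n_CEm = 6
baseline_rate = 0.2
cs_amp = 3.0
behavior_correct_prob = 0.8
coupling_excess = 0.35
lfp_freq = 33
lfp_amp = 1.0
lfp_kappa = 4.0
motion_threshold = 0.5
decode_n_neurons = 10
decode_repeats = 2
te_n_draw = 30
te_n_surr = 60
te_alpha = 0.05
sfc_window = 0.2
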