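# Fidelity-sweep configuration at full scale.
# Parameter provenance: paper = printed in the source publication,
# prior-work = standard dyad-model literature value, chosen = this
# package's calibrated default (see docs/methods.md).

[transport]
i_ryr_pA = 0.16      # paper
i_ip3r_pA = 0.05     # paper
v_ds_uL = 1.8e-14    # paper
ca_nsr = 850.0       # paper
tau_refill = 8.0     # paper
d_myo = 0.08         # prior-work
d_jsr = 0.08         # chosen
beta = 0.05          # chosen
c_rest = 0.1         # prior-work

[ryr]
k_r_max = 400.0      # chosen (calibrated)
alpha_r = 0.376      # chosen (calibrated)
kplus_max = 0.7      # chosen
hill = 2.2           # prior-work
kminus = 1.0         # chosen
ej = 0.2             # chosen

[protocol]
n_trials = 100       # paper (sweep protocol)
duration = 200.0     # paper
n_ryr = 50           # paper
n_ip3r_values = [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]   # paper
ip3_values = [0.0, 0.1, 1.0, 10.0]                   # paper grid endpoints; interior chosen
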