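# p53-like fixture: output-activation design (C = p53, R = Mdm2), no
# auto-inhibition; tau in hours. tau_m = 0.353, so tau = 1.37 oscillates.
model_id: 3
I: 0.48
alpha: 0.14
beta: 0.44
delta: 83.71
tau: 1.37
n: 10.0
K_m: 0.9
nu: 1.0
kappa: 0.0
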