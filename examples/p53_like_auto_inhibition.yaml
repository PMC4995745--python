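# Same fixture with a synthetically activated auto-inhibitory feedback
# (nu = 3, kappa = 1.73): raises the marginal delay tau_m.
model_id: 3
I: 0.48
alpha: 0.14
beta: 0.44
delta: 83.71
tau: 1.37
n: 10.0
K_m: 0.9
nu: 3.0
kappa: 1.73
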