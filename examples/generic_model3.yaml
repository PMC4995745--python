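# Generic parameter set under which all four designs share tau_m ~ 1.2-1.3;
# tau = 2.5 exceeds every marginal delay, giving sustained oscillations.
model_id: 3
I: 0.87
alpha: 0.11
beta: 0.17
delta: 58.2
tau: 2.5
n: 12.77
K_m: 0.23
nu: 1.0
kappa: 0.0
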