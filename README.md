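# delayfb

Stability, bifurcation and response analysis of two-dimensional **delayed
negative feedback (DNF)** models of biochemical signal-response networks,
with the p53–Mdm2 oscillator as the motivating application.

## The problem

Many cellular networks respond to a constant stimulus through a negative
feedback loop that acts only after a time delay τ (transcription,
translation, transport). Depending on the delay and on the network
design, the response either adapts to a new steady state or breaks into
sustained oscillations — p53 pulsing after DNA damage being the textbook
example. `delayfb` answers, for a family of four generic designs: *for
which delays is the equilibrium stable, and how do design features —
the feedback mechanism and strength, mass conservation, and a nested
auto-inhibitory feedback — move that boundary and shape the oscillatory
response?*

## The models

All four designs are delay differential equations in a driven component
C and a delayed response R:

    dC/dt = production(C, R) − loss(C, R)
    dR/dt = C(t − τ) − β R

| id | DNF mechanism | mass conservation | dC/dt |
|----|---------------|-------------------|-------|
| 1 | input-inhibition | no  | I·S₁(R)·F(C) − αC |
| 2 | input-inhibition | yes | I·S₁(R)·F(C)·(1−C) − αC |
| 3 | output-activation | no  | I·F(C) − αC − δ·C·S₂(R) |
| 4 | output-activation | yes | I·F(C)·(1−C) − αC − δ·C·S₂(R) |

with Hill-type feedback functions S₁(R) = Kₘⁿ/(Kₘⁿ+Rⁿ),
S₂(R) = Rⁿ/(Kₘⁿ+Rⁿ) and an optional instantaneous auto-inhibition
F(C) = 1/(1+(κC)^ν) (κ=0 disables it). The p53 system maps onto
Model 3 with F ≡ 1 (C = p53, R = Mdm2, I = DNA-damage signal).

Linearizing about the equilibrium E = (C_s, R_s) gives coefficients
x (self-damping of C) and y (delayed loop gain) and the characteristic
equation (λ+x)(λ+β) + y·e^(−λτ) = 0. The central result implemented
here:

* **xβ ≥ y** — the equilibrium is *absolutely stable* (stable for every
  τ ≥ 0);
* **xβ < y** — a Hopf bifurcation occurs at the *marginal delay*
  τ_m = arccos((ω² − xβ)/y) / ω, where
  ω² = [−(x²+β²) + √((x²+β²)² + 4(y²−x²β²))]/2
  is the critical frequency; the response oscillates for τ ≥ τ_m.

Around this core the package provides: a method-of-steps DDE integrator,
Monte-Carlo stability surveys over design scenarios, τ_m sensitivity
sweeps and Hopf curves τ_m(I), least-squares parameter fitting
(Nelder–Mead with a differential-evolution fallback), robustness of the
fitted transient (CV under ±10 % parameter noise), amplitude/period
curves versus τ, On/Off pulse durations, and a synthetic p53-like
dataset generator with known ground truth.

## Worked example

Classify the first generic design and the p53-like model (configs are
shipped under `examples/`):

```text
$ delayfb stability examples/generic_model1.yaml
model 1: conditionally_stable (C_s=0.0574657, R_s=0.338033, x=0.11, y=0.237064, tau_m=1.25057)

$ delayfb stability examples/p53_like.yaml
model 3: conditionally_stable (C_s=0.267958, R_s=0.608995, x=1.79133, y=7.12251, tau_m=0.352674)

$ delayfb stability examples/p53_like_auto_inhibition.yaml
model 3: conditionally_stable (C_s=0.265494, R_s=0.603395, x=2.08504, y=6.51671, tau_m=0.45658)
```

Reading: Model 1 with the generic parameter set is stable for delays
below τ_m ≈ 1.25 and oscillates beyond it — so the configured τ = 2.5
produces sustained oscillations. The p53-like model has τ_m ≈ 0.35 h;
its delay of 1.37 h puts it deep in the pulsing regime, and switching on
the auto-inhibitory feedback (ν = 3, κ = 1.73) widens the stable range
to τ_m ≈ 0.46 h. Other subcommands (`sweep`, `bifurcation`, `simulate`,
`mc-survey`, `fit`, `osc-curve`, `pulses`, `synth`) expose the remaining
analyses; `delayfb --help` lists them.

The same pipeline from Python:

```python
from delayfb import ModelSpec, classify_stability
from delayfb.presets import PRIMARY_SET, params_for_model

spec = ModelSpec(1)
res = classify_stability(spec, params_for_model(spec, PRIMARY_SET))
print(res.classification, res.tau_m)   # conditionally_stable 1.2505694288345741
```

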