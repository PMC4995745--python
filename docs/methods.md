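# Methods

## Model family and assumptions

The package analyses four deterministic two-variable delay differential
equation (DDE) models of a signal-response network driven by a constant
stimulus I. The component C is produced (or activated) by the stimulus
and, after a discrete delay τ, activates the response R with unit rate;
R decays at rate β and closes a delayed negative feedback (DNF) on C by
one of two mechanisms: *input-inhibition* (a reverse Hill function
S₁(R) multiplying the production of C) or *output-activation* (a Hill
function S₂(R) scaling an extra degradation path δ·C·S₂(R)). Two
optional design features modify the loop: *mass conservation* (C
interconverts with an inactive pool of conserved total 1, contributing a
factor (1−C) to production) and a nested *auto-inhibition*
F(C) = 1/(1+(κC)^ν) acting instantaneously on production. All
parameters are lumped rates in arbitrary units (read as hours for the
p53 application); the models are not meant to resolve mechanistic
kinetics. With shared (n, Kₘ), S₁ + S₂ = 1, which makes the two
mechanisms directly comparable.

Assumptions worth keeping in mind: a single discrete delay (no
distributed delays), deterministic dynamics (no molecular noise), and a
hardwired unit coupling C(t−τ) → R, which fixes the time and
concentration scales (rescaling time requires rescaling Kₘ along with
the rates).

## Equilibrium and stability

Setting dR/dt = 0 gives R_s = C_s/β; the delay drops out, so the
steady state never depends on τ. The remaining scalar equation
G(C) = production − loss is strictly decreasing on the admissible
interval (production non-increasing in C, loss strictly increasing), so
the root is unique; it is bracketed on [0, 1) for mass-conservation
designs and [0, I/α·(1+10⁻⁶)] otherwise and solved by Brent's method to
machine precision, with a residual check against the full right-hand
side (default tolerance 10⁻¹²) and an optional 1000-point sign-change
scan as a uniqueness diagnostic.

Linearization about E yields dC/dt = −xC − yR, dR/dt = C(t−τ) − βR,
with x, y evaluated per design from the analytic derivatives of S₁, S₂
and F. The characteristic equation (λ+x)(λ+β) + y·e^(−λτ) = 0 gives
the dichotomy: absolute stability iff xβ ≥ y (the boundary is
classified absolutely stable, exactly matching the criterion), and
otherwise a Hopf bifurcation at

    ω² = [−(x²+β²) + √((x²+β²)² + 4(y² − x²β²))]/2,
    τ_m = arccos((ω² − xβ)/y) / ω.

The arccos argument is clamped into [−1, 1] only when it strays within
10⁻¹² of the boundary; larger violations raise, so floating-point
safety cannot mask an algebraic error. Tests verify that (iω, τ_m) is
an exact root of the characteristic equation (residual < 10⁻⁹ over
randomized coefficients), that τ_m increases with x and decreases with
y, and that τ_m diverges as y ↓ xβ. Only the first crossing is
computed; higher Hopf branches and the full spectrum are out of scope.

The stabilizing role of the auto-inhibition is demonstrated
numerically: steepening F at the equilibrium (raising κ or ν) increases
x and raises τ_m; closed-form bounds for x and y are not reproduced.

## DDE integration

The integrator uses the method of steps: on each interval
[kτ, (k+1)τ] the delayed term is a known function — the initial history
for k = 0, the previous segment's dense interpolant otherwise — and the
resulting ODE is solved with LSODA (stiff-capable; δ can be O(100) and
n up to 20) with dense output, default rtol 10⁻⁸ / atol 10⁻¹⁰.
Segment boundaries coincide with the propagated derivative
discontinuities of the DDE, which keeps the interpolation smooth where
it is used. For τ = 0 the system is integrated as a plain ODE. The
default history is the unstimulated state (C, R) = (0, 0) on [−τ, 0]:
the history only shapes the transient, never the stability class or the
settled cycle. Default horizon max(50τ, 200/β); analysis routines pass
shorter, purpose-sized horizons.

Measured accuracy: the global error tracks the requested tolerance with
an amplification factor of roughly 30–60 over ~12 delay intervals
(LSODA and RK45 alike), i.e. ~4·10⁻⁷ relative at rtol 10⁻⁸. The
convergence test therefore asserts proportional error decay per
tolerance decade rather than an absolute one-digit bound. Negative
solver excursions are clamped to zero inside the Hill terms only;
trajectories leaving the non-negative orthant by more than 10⁻⁸ raise.

## Monte-Carlo survey

For a base parameter vector, rates (α, β, δ) are drawn uniformly (on
the linear scale — the protocol names multiplicative ranges with no log
qualifier) on 0.1–10× base; weak-DNF scenarios draw n on 0.1–1× and Kₘ
on 10–20× base, strong-DNF scenarios n on 1–2× and Kₘ on 0.1–10×;
scenarios with auto-inhibition add κ ~ U[0.1, 10] and ν ~ U[1, 20]
(absolute intervals), sampled jointly per draw. I stays fixed. Each
draw is classified; the survey reports the percentage of absolutely
stable draws and the mean τ_m over the conditionally stable remainder.
Scenarios sharing a seed consume a common uniform matrix in a fixed
column order, so paired comparisons (with/without auto-inhibition,
model 2 vs 1, 4 vs 3) use common random numbers. The full survey uses
10000 draws per cell; the test suite runs 2000, at which every direction
claim (auto-inhibition, weak feedback and mass conservation all raise
both metrics) holds with margin. Weak-DNF draws take the Hill exponent
n below 1; the parameter container accepts n > 0 and warns below 1.

## Fitting and robustness

The objective is SSR(p) = Σᵢ (x(tᵢ, p) − xᵢ)², with the simulated
observable (C by default) evaluated at the data times through the dense
trajectory. Integration failures inside the objective return a penalty
of 10⁶ × the flat-zero SSR, keeping simplex searches finite.
Optimization runs Nelder–Mead first (xatol = fatol = 10⁻⁸, the declared
convergence tolerance on both the objective and the parameter step);
if it terminates without converging, a seeded differential-evolution
global search restarts it, followed by a Nelder–Mead polish. Bounds are
box constraints supplied per free parameter.

Robustness of a fitted solution is the coefficient of variation (in %)
of the integral of the first transient — the trapezoidal integral of
the observable from t = 0 to the first local minimum after the first
maximum — under 100 draws in which every positive kinetic parameter is
multiplied by an independent uniform factor in [0.9, 1.1]. "Relative
variation" is implemented as the CV (std/mean), the standard reading;
(κ, ν) are perturbed only when the auto-inhibition is active, with ν
floored at its admissible minimum of 1.

## Oscillation metrics

After discarding the first half of the trajectory as transient (the
horizon auto-extends until at least 5 post-transient peaks exist),
peaks and troughs are located by discrete extremum detection with
three-point parabolic refinement. Amplitude is peak-to-trough
(mean peak − mean trough) — robust to baseline shifts, since the
settled cycles of these models are strongly asymmetric; period is the
mean successive-peak spacing; the oscillation counts as sustained when
the last cycle amplitude is within 1 % of the preceding one and above
10⁻⁶ of the signal scale (the floor keeps converged equilibria from
reading as micro-oscillations). On/Off pulse durations use the
midrange (max+min)/2 of the settled cycle as threshold, with crossings
located by linear interpolation and only complete cycles averaged; on +
off reproduces the period to within twice the output grid spacing.

A caveat established while validating: with the midrange threshold and
durations measured in absolute time, the Off duration lengthens with τ
but the On duration lengthens as well (the pulse width scales with the
growing period) for both generic parameter sets; only the On duty cycle
shrinks, and not monotonically across the whole τ ∈ [1, 8] grid. The
direction test for shrinking absolute On durations is retained and
documents this as a failing expectation rather than being weakened.

## Synthetic data

The generator emulates an idealized undamped pulsatile p53 time series:
it simulates a ground-truth model from rest, samples C on a regular
grid and adds independent Gaussian observation noise. The default
ground truth is the package's p53-like fixture — Model 3 without
auto-inhibition using the second generic parameter vector (I = 0.48,
α = 0.14, β = 0.44, δ = 83.71, n = 10, Kₘ = 0.9), whose period at the
p53-scale delay of 1.37 h is ≈ 5.9 h — with τ = 0.64, about 1.8× its
marginal delay τ_m = 0.353, mirroring the ratio of the fitted p53 delay
to its Hopf point. Defaults: 200 points at Δt = 0.25, noise sd 0.05
(≈ 6 % of the pulse amplitude). What it does not emulate: cell-to-cell
variability, damped population-average artefacts, multiplicative or
autocorrelated noise — so passing recovery tests demonstrate
identifiability under idealized sampling, not performance on raw
single-cell data.

## Problem sizes used in the test suite

Monte-Carlo surveys at 2000 draws per scenario; simulation-vs-theory
envelope checks on 20 conditionally stable draws (horizon 300 time
units, restricted to draws whose dominant characteristic root moves the
envelope measurably within it, |Re λ| ≥ 0.02); parameter recovery on 60
samples of the generic Model 3 fixture with 3 free parameters;
amplitude/period curves over τ = 1–8 step 0.2. These sizes give
reproducible outcomes with comfortable statistical margin.

## Known limitations

* Only the first Hopf crossing is computed; no Floquet analysis of the
  periodic orbits and no continuation of the cycle branch.
* Uniqueness of the equilibrium for κ > 0 with very steep ν is checked
  numerically (grid scan), not proven.
* The marginal delays computed for the two printed generic parameter
  sets differ from the published rounded values by 2–4.5 %, consistent
  with the published parameters themselves being rounded to 2–3
  significant digits; the characteristic-equation residual confirms the
  computed values are exact for the printed inputs.
* The three-variable ATM-extended p53 model and stochastic variants are
  out of scope.
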