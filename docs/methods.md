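# Methods

## The extended S-System model

The package's core object is a power-law ODE system for `n` circadian
components (mRNAs, proteins, complexes):

```
dX_i/dt =  α_i ∏_{j=1..n_i^P} ( Σ_k b_ijk X_k )^{g_ij}
         − Σ_{j=1..n_i^D} β_ij X_i ∏_k X_k^{h_ijk}
         + Σ_{j=1..n_i^L} γ_ij U_ij(X_1..X_n, L(t)) .
```

Relative to the classical S-System (one production and one degradation
power-law product per species), three extensions matter for clock
modelling: (i) groups of co-regulators can be *summed* inside a power-law
base (the continuous analogue of a multi-input OR gate; the bare product is
an AND gate), (ii) a species may have several degradation processes, with
negative rates representing protein stabilisation, and (iii) additive
light-regulated terms couple the network to the photic environment. Each
`U_ij` is a single monomial — an optional factor of the light signal times
integer species powers with total order ≤ 2 — with `γ_ij` its only
coefficient; a polynomial is expressed as several light processes. The
light signal itself carries no exponent.

Setting `n_i^P = n` with singleton memberships, a single bare degradation
term and `n_i^L = 0` recovers the classical form, and
`ESSModel.reduce_to_original()` performs that reduction explicitly (or
reports which structural condition fails). This doubles as a correctness
oracle: on reducible models the two evaluators must agree to floating
precision, which the test suite checks on randomised systems.

Regulation-type inference is the formalism's main practical advantage: a
production exponent `g > 0` is an activator, `g < 0` an inhibitor, so the
regulation type is estimated *with* the parameters instead of being chosen
a priori as in Hill-type models (which need structurally different terms
for activation and inhibition). Exponents are left unconstrained during
fitting; `constrain_signs_and_refit` supports the follow-up step of
flipping and pinning any signs that contradict prior knowledge.

**Numerical floor.** Power-law bases are undefined at zero with negative
exponents, and integrators can undershoot zero, so every base is clamped to
`ε = 1e-9` before exponentiation. Classical-form models that place the
light signal inside a power law additionally use a light floor of 0.001
instead of 0 in darkness; the extended form, where light enters additively,
uses a floor of 0.

## Light protocols and simulation

`L(t)` is a square wave with dawn at `t = 0`: 1 on `0 ≤ t mod 24 < P`
(photoperiod `P` hours) and the floor otherwise, so `P = 24` is constant
light (LL), `P = 0` constant dark (DD) and `P = 12` the symmetric 12L:12D
cycle. A protocol entrains for a number of cycles and then releases into LL
or DD. Release is placed at a dawn boundary by default (configurable via
`release_time`); the dusk sample itself returns the dark value (half-open
`[dawn, dusk)` convention).

Integration uses `scipy.integrate.solve_ivp` with LSODA (stiff-capable) at
`rtol 1e-6 / atol 1e-9` by default, restarted at every light discontinuity
with the light level held constant inside each segment, so the forcing
jumps are handled exactly rather than smeared by step-size control. A
refinement check in the suite verifies that halving the tolerances changes
fixture trajectories by < 1e-5 relative. The default initial state is 0.1
model units for every species and simulations start at the first dawn;
recorded windows follow a burn-in through the entrainment cycles. The
derivative evaluator is compiled to flat Python tuples because at fixture
size (4–5 species) interpreter-level arithmetic outruns vectorised numpy
calls inside the integrator by roughly an order of magnitude.

## Fitting

The cost is the weighted mean squared error: per component
`W_i = (1/N_T) Σ_j ((X_i(t_j) − X̂_i(t_j))/A_i)²` with `A_i = max_j X_i(t_j)`,
and `W = (1/N_G) Σ_i W_i`. Normalising by each component's maximum stops
high-amplitude components from dominating the fit; `W` is invariant to
rescaling any component jointly with its simulation and to component order
(both property-tested).

Minimisation uses the Nelder–Mead simplex (`scipy.optimize.minimize`).
A run restarts the simplex from the incumbent until one restart improves
`W` by less than `1e-6` absolute — a quantitative version of terminating
"when no further improvement is observed", indicating a local minimum. The
evaluation budget per restart defaults to `400 × K_Θ` (with `K_Θ` the
number of free parameters). Production rate constants are kept
non-negative by a graded finite penalty rather than a hard bound, and any
candidate whose simulation fails is scored `1e6`, keeping the simplex
finite and mobile. Exponent magnitudes are unbounded by default; a box
constraint can be imposed through sign constraints where needed.

Multistart variability follows the standard protocol: after an initial
run, further runs start from draws of a multivariate normal centred on the
first optimum with identity covariance (on the natural parameter axis);
draws with a negative production rate are rejected and redrawn (≤ 100
attempts). Per-parameter spread across the run optima is summarised by the
normalised median absolute deviation, `nMAD(θ) = median(|θ_i − θ̃|)/|θ̃|`
with `θ̃` the median optimum; a zero median is flagged degenerate rather
than divided by.

## Model ranking

For weighted least-squares fits the maximised log-likelihood is an affine
function of `ln W`, so AIC *differences* across models sharing the data,
grid and weights can be computed from the simplified criterion
`AIC = N_G·N_T·ln W + 2(K_Θ + 1)`; the full-likelihood form is also
provided and the suite checks that the two give identical differences.
Akaike weights are the softmax of `−Δ/2`, computed after subtracting the
minimum AIC so that enormous differences underflow cleanly to a weight of
0; evidence ratios `w_i/w_j` with an underflowed denominator are reported
as infinite with a flag. Reported precision follows convention: 2 decimals
for Δ, 5 for weights.

## Sine-sweep frequency response

To ask whether a cytoplasm/nucleus protein-shuttling pair genuinely needs
two state variables, the subsystem is treated as an input–output system
(mRNA in, nuclear protein out) and swept with
`u(t) = baseline + amplitude·sin(ωt)` over `ω ∈ [0.01, 2]` rad/h. After
discarding transients, the output is correlated with `sin ωt` and `cos ωt`
over a whole number of periods to extract gain and phase; the residual
after removing the fitted fundamental and mean gives a harmonic-distortion
diagnostic, and the method is only trusted when the response is
sinusoid-dominated (threshold 5% of the output amplitude).

Choices the analysis leaves open, fixed here as follows:

- **Operating point**: the input baseline defaults to the mean level of the
  driven species (1.0 in normalised sweeps) with amplitude 10% of baseline —
  small enough for linear-dominant behaviour around a positive operating
  point.
- **Transients**: 5 forcing periods are discarded, but never less than
  150 h, because at the top of the band five short periods elapse before
  the *system's* own modes have decayed; correlation then runs over 4 whole
  periods.
- **Corner frequency**: the −3 dB (10·log₁₀2) crossing below the
  low-frequency plateau, log-interpolated between sweep points.
- **Slope window**: the magnitude slope used for order estimation is the
  least-squares slope of dB versus log₁₀ω over the decade `[3ω_c, 30ω_c]`
  (clipped to the swept band). The window sits on the asymptote
  deliberately: the local slope *at* the corner of an N-th order low-pass
  is only about −10·N dB/decade, and a decade starting at the corner still
  averages ≈ −17 dB/decade for N = 1, whereas the asymptotic figure the
  order rule needs is −20·N.
- **Order**: `N` is the rounded average of phase-based (`phase/−45°`) and
  slope-based (`slope/−20 dB·dec⁻¹`) estimates; whole-order disagreement is
  flagged ambiguous.

Closed-form Bode curves of rational transfer functions
(`linear_tf_bode`) serve as the independent oracle: the sweep must match
them within 0.5 dB / 3° on linear systems, and halving the input amplitude
must leave the curve unchanged to < 0.2 dB (both tested). The headline
result this machinery supports: a two-compartment shuttling system whose
poles are separated by a factor ≈ 30 sweeps as first-order (phase ≈ −45°,
slope ≈ −20 dB/decade at the corner), which is why a single aggregated
protein equation loses essentially nothing.

## Mutant phenotyping

Knockout/knockdown multiplies the target's transcription rate constant by
0.2 (80% reduction); overexpression multiplies the translation rate by 2.0;
when a species has no transcription term the designated production rate is
scaled instead. Free-running period is estimated after release into
constant conditions: per component, local maxima are detected
(`scipy.signal.find_peaks`) with prominence 1% of the component's range in
the window and minimum spacing 6 h; the component period is the mean gap
between successive maxima (gaps averaged within a component first, then
across components). Components with fewer than three peaks, or whose final
complete cycle has collapsed below 10% of the first post-release cycle's
amplitude, are excluded; if none qualify the trace is classified
arrhythmic. The phenotype is the sign of `δτ = τ_mut − τ_wt`, with
`|δτ| < 0.05 h` reported as "0" (sign-only reporting needs a numeric tie
rule) and "arr." for arrhythmic mutants.

## Synthetic fixtures: what they emulate and what they don't

The bundled circuits realise the train/validate workflow at a deliberately
small scale — two genes, four or five states — so that every test runs on a
desk machine:

- `mm_two_gene`: Hill activation of gene 1 by protein 2, an additive light
  drive on gene 1 at dawn, explicit cytoplasm/nucleus shuttling of
  protein 1, Hill inhibition of gene 2 by nuclear protein 1, and an
  aggregated protein 2 — a delayed negative-feedback loop.
- `ess_two_gene`: the extended S-System mirror with aggregated proteins,
  one positive and one negative kinetic order, one light term, and 12 free
  parameters (the four α, four β, both regulatory exponents, the G1→P1
  translation exponent and the light gain; the G2→P2 translation exponent
  is fixed at 1).

Parameter values were chosen once to satisfy the qualitative study
conditions and then frozen: both circuits entrain to 24 h under 12L:12D
(±0.2 h) and free-run in the low-to-mid 20s of hours after release (the
exponent loop gain of the power-law fixture exceeds the secant-condition
threshold for a four-stage negative feedback loop, and degradation rates
near 0.25–0.35 h⁻¹ set the timescale). A hand-computed derivative sheet at
a reference state is shipped with the fixture and asserted in the suite.
Datasets are generated with 4 entrainment cycles of burn-in and a recorded
window of 24 h before to 72 h after release at 1 h sampling (97 points);
they are noiseless by default, with optional seeded multiplicative Gaussian
observation noise. When the Michaelis–Menten circuit provides training
data for the power-law model, its five states are projected onto the four
power-law components by taking the *nuclear* protein as the active pool.

Passing tests on these fixtures demonstrate self-consistency (recovering a
generator's own parameters from noiseless data), cross-formalism
flexibility (a power-law model reproducing Hill-type dynamics to small
WMSE), and correctness of the surrounding machinery. They do not
demonstrate performance on real expression data: experimental noise,
missing components, model misspecification at realistic network sizes
(tens of components, ~100 parameters) and optimiser behaviour in those
larger spaces are all outside what the fixtures probe.

## Known limitations

- No stochastic or delay-differential simulation; no steady-state or
  bifurcation analysis; no symbolic manipulation.
- The optimiser is local (Nelder–Mead with restarts); global search and
  Bayesian uncertainty quantification are out of scope, with nMAD as the
  only variability measure.
- Sine-sweeping nonlinear subsystems relies on the linear-dominant
  assumption; the distortion diagnostic flags violations but no describing-
  function analysis is attempted.
- Generalised mass-action (signed sums of power-law monomials) is
  documented context only; the evaluator implements the extended S-System
  form.
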