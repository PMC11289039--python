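# Methods

## Model structure

The muscle is a lumped Hill-type model: a contractile element (CE) in
series with a linear spring (SEE), both in parallel with a passive
elastic element (PE). Forces are normalized by the peak active isometric
force `F_mto`, lengths and velocities by the optimal length `L_mto`;
shortening CE velocity is positive. At every instant the SEE carries the
CE force, so with the inverse force–velocity map IFV the state
(pre-scaling activation a′, normalized CE length l_m) evolves as

    da′/dt = (u_f − [β + (1−β) u_f] a′) / τ
    dl_m/dt = −IFV( f_SEE / (a · LT(l_m)) )

and the observable force is `F_mto (f_PE(l_mt) + K_t (l_mt − l_m))`.
The drive u_f comes from the stimulation frequency through a 4-parameter
sigmoid; the output activation is `a = clip(g (a′ − a₀), 0, 1)`.

Key parameters of the shipped model (best-median individual): τ = 0.60 s
(excitation), τ/β = 4.0 s (relaxation — the muscle is smooth-muscle-like
and relaxes an order of magnitude more slowly than vertebrate striated
muscle), a₀ = 0.74, g = 3.82, K_t = 11.95 F_mto/L_mto, passive threshold
0.87 L_mto, F_mto = 1.61 N, L_mto = 18.03 mm, rest length L₀ = 16.02 mm
(0.89 L_mto). The SEE slack length is unknown for this muscle and fixed
at zero.

### Internal consistencies and their limits

The shipped coefficient families come from different individuals (each
family's best-median animal), so they are not mutually consistent in two
places, both documented rather than hidden:

* **D vs E.** The forward force–velocity hyperbolas (D) and the
  double-exponential inverse (E) do not invert each other. The simulator
  runs entirely on E; experiments that need a self-consistent model
  (parameter recovery, loop closure) refit E to the inverse of the
  D-curve (`fitting.refit_inverse_fv_from_forward`). That refit samples
  the forward curve densely near zero velocity and weights residuals by
  |dFV/dv|, because the hyperbola corner at the isometric point is where
  an unweighted fit leaks the most force-ratio error.
* **Sigmoid vs activation map.** The drive sigmoid was fitted to
  measured normalized forces, but the model's steady-state output is the
  sigmoid *composed with* the activation fixed point and the g/a₀
  threshold map. The measured force–frequency relation of the model is
  therefore `model_core.isometric_steady_activation`, not the sigmoid
  alone; recovery comparisons use the composed curve.

## Simulator

Adaptive implicit integration (BDF; max step 50 ms by default, rtol
1e-6, atol 1e-8). The drive is zero-order-held, the length linearly
interpolated; integration is split at every drive/length knot so the
solver never steps across a discontinuity. The algebraic force ratio
r = f_SEE/(a·LT) is guarded: denominator floored at 1e-6, LT floored at
1e-3, r clamped to [0, (1+D₃)(1−1e-3)] so the lengthening asymptote is
never crossed. With zero activation the guards make the CE track the
imposed length (the spring stays slack to < 1e-3), at the cost of a
stiff quasi-equilibrium that is why the default solver is implicit.
Initial conditions default to an unstretched spring (l_m = l_mt) and
a′ = a₀ (zero output activation); both are modeling conventions, not
measured facts.

Isometric episodes with held drives admit a fast path
(`simulate_isometric_force`): the activation ODE is solved analytically
segment by segment, and only the spring force needs a 1-D ODE, and only
over the spans where a > 0. It matches the general path to < 1 mN and
is what the activation-parameter fit evaluates hundreds of times.

## Feature extraction

All averaging windows are anchored to declared episode metadata:

* force–frequency: baseline = mean force over [onset−20 s, onset−5 s];
  active force = 2 s window centered on the in-stimulation peak of the
  baseline-subtracted force; per-muscle normalization by the maximum.
* length–tension: passive = mean over [onset−10 s, onset−2 s] (the more
  specific of the two windows the source protocols state); active = 1 s
  peak-centered window minus passive; second pass normalizes by the
  per-muscle peak so it maps to (1, 1) exactly. The first two protocol
  episodes are muscle conditioning and excluded from fits.
* force–velocity: ramp endpoint forces use 1 ms sample windows; the
  CE force during a ramp is the measured force minus the passive-ramp
  force at the matching *length* (not time). A quartic in time is fitted
  to the CE force and differentiated analytically. Because the force
  transient steepens as the spring unloads (time constants from ~1 s
  down to ~40 ms), a single quartic over a long ramp biases endpoint
  derivatives 15–20% low; the fit is therefore windowed around the
  evaluation time (last max(T/2, 0.1 s) of the ramp for the end slope).

Two deliberate refinements over the plain textbook estimators, both
verified against simulation ground truth:

* **Stiffness slopes at ramp onset.** The spring-rate relation
  dF_CE/dt = K_t (V_mt − V_m) collapses to K_t·V_mt only while the CE
  has not yet accelerated. For this muscle's steep force–velocity curve
  the CE carries 60–85% of the imposed velocity by ramp end, so
  end-evaluation underestimates K_t by ~3×; the regression therefore
  uses slopes at t_ramp_start. The ordinary-least-squares intercept is
  reported as a diagnostic, not constrained to zero.
* **Capacity at the CE length.** The FV denominator evaluates the
  isometric-capacity curve at the series-elasticity-corrected CE length
  (inverting l_m = l_mt − B(l_mt)/K_t) rather than at the total length:
  right after a ramp the spring force differs from its isometric value,
  and the plain evaluation misattributes capacity by up to 13% at the
  fastest ramps. The plain behavior is available via
  `capacity_at_ce_length=False`.

## Fitting

The active length–tension cubic is a linearly-constrained linear least
squares (equalities: value 1 and zero slope at l = 1; inequalities:
concavity at both ends of the data range), solved exactly by active-set
enumeration over the two inequalities; KKT residuals are reported. The
re-fit in CE coordinates (after the l_m = l_mt − f_CE/K_t shift, with
f_CE in normalized force units) is *unconstrained*: after the shift the
peak no longer sits at exactly 1.

Sigmoid, exponential and hyperbola families use deterministic
multi-start nonlinear least squares (fixed start grids, no randomness);
4- and 5-parameter families are locally non-identifiable, so curve
agreement, not coefficient agreement, is the contract. The passive
exponential is fitted in a 3-parameter form (its amplitude pair is
redundant) over points above the zero-force regime; the zero threshold
is the largest zero crossing of the fitted curve, clipped to the data
range (default 0.87 when there is no crossing).

In the assembled pipeline the inverse-FV map is fitted to the forward
fit's own curve rather than independently to the scattered points: the
protocols give no samples between the slowest shortening and lengthening
ramps, and a free double exponential extrapolates its isometric zero
crossing badly there (with 10 mN noise it landed at 0.86 instead of ~1,
breaking the simulated plateau by 14%). The forward hyperbolas pass
through (0, 1) structurally, which pins the inverse.

Activation parameters (τ, β, a₀, g) minimize the mean squared error
between simulated and measured isometric force. The simplex search is
preceded by a deterministic 65-point coarse grid (a lone simplex from a
fixed start stalls at τ/β ≈ 1.7 instead of 4) and restarted once from
its optimum. By default the fit uses the episode closest to 26 Hz — the
protocol's working saturation frequency — where the drive is ~1
regardless of sigmoid misfit at intermediate frequencies; the measured
trace is decimated to 10 Hz for the error. β is identifiable only if a
relaxation phase is present (warned otherwise).

### Force-scale fixed point

The measured peak active force is not the CE's peak capacity: at
isometric equilibrium the spring displaces the CE off its optimum, so a
model whose F_mto equals the measured peak under-predicts the very
forces it was fitted to (by ~7% for this stiffness and LT shape — the
same under-prediction the original validation experiments show). The
assembled model therefore divides the measured peak by
f\* = Y(1 − f\*/K_t) and rescales the dimensionless stiffness by f\*,
making the fitted model reproduce its own source data. The reported
K_t *estimate* remains the plain regression value.

## Cohort median selection

Each individual's fitted curve is evaluated on a shared grid (lengths at
0.001, velocities at 0.0005 L_mto/s; force–frequency uses the shared
measured frequencies directly), the pointwise median is taken (even
cohorts: midpoint of the central pair), the family is refitted to the
median values, and the individual with the lowest sum of squared error
to the median fit on the grid wins (ties: lowest index). Population
means of nonlinear parameters can land outside any functional parameter
set; selecting a real individual avoids that.

## Synthetic experiments

The generator reproduces the rig protocols from a ground-truth model:
isometric 5 s trains at 2–38 Hz in 6 Hz steps; length–tension ramps of
20 s through offsets (0, −1, −1, 0, 1, …, 8) mm around the rest length
with stimulation ≥ 26 Hz (the first two episodes tagged as
conditioning); paired passive/active ±0.5 mm isokinetic ramps at
±{0.25, 0.5, 1, 2, 4, 8} mm/s, shortening first, with a 5 s isometric
stimulation hold before each active ramp. Desk-scale defaults: 500 Hz
sampling (the rig's 5 kHz is available by setting `fs`) and compressed
inter-episode rests — the model is memoryless once activation decays,
so the 180 s rests are realized as state resets; pre-stimulation
plateaus stay long enough for every extraction window. Unstimulated
episodes are evaluated analytically (zero activation ⇒ the force is the
passive curve), stimulated ones through the ODE simulator. Noise is
additive Gaussian on the force channel (seed mandatory); an optional
stretched-exponential stress-relaxation transient (≤ 0.35 N, off by
default) exists only to probe extractor robustness — the model itself
deliberately excludes passive transients, and the protocols' long rests
exist to let them decay in the real preparation.

What passing recovery tests do **not** show about real data: the
generator has no electrode movement, no fatigue or history dependence,
no stress relaxation (unless enabled), and its noise is white — so the
recovery tolerances measure the pipeline's methodological bias, not its
robustness to every rig artifact.

The EMG surrogate is a burst-envelope-modulated Gaussian carrier with
the true envelope returned for oracle testing; the envelope extractor
(rectify, normalize, linear interpolation across peaks with a minimum
separation in samples — 1000 samples ≡ 0.2 s at 5 kHz) and a bounded 1-D
search for the EMG-to-frequency scale close the validation loop. Any
alignment shift between measured and simulated force is estimated by
plain cross-correlation (no demeaning, which biases transient pulses
toward zero lag) and reported, never silently applied.

## Numerical choices and degenerate inputs

* Solver failures raise errors carrying the failing time; the guards
  above make the velocity map total, so failures are step-size collapse
  only.
* The inverse-FV round trip is bounded by the double-exponential
  family's cross-fit residual (~0.01 velocity units over the working
  range; larger near a lengthening pole as extreme as D₄ = 0.01, where
  the inverse is near-degenerate).
* All-zero passive data → degenerate flat fit, threshold at the data
  edge. All-identical cohort values → the t-test refuses (sd = 0).
  Single-sided FV data → partial fit with the missing branch flagged.
* Recovery experiments run at desk scale: 43 episodes total, 500 Hz,
  about one minute per full characterization on one CPU.

## Known limitations

No pennation, no nonlinear SEE, no force depression after shortening,
no fatigue, no neuromodulation of the neuromuscular transform: steady
shortening force after a ramp is under-predicted, as expected for this
model class. The activation threshold/gain map makes the model not a
fixed point of its own characterization (the composed force–frequency
response differs from the input sigmoid); this is inherent to the
family, handled explicitly in the recovery criteria, and the force-scale
fixed-point correction above removes its largest practical consequence.
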