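# Methods

This note documents the models implemented in `cacomplex`, the default
parameter values and how they were chosen, the numerical methods, and the
known limitations.  Units throughout: mV, ms, µM, nm, pA, pS, pF, fC
(= pA·ms); conversions are centralized in `cacomplex.constants`.

## Ca²⁺ nanodomains (`nanodomain`)

An open CaV is treated as a point source of Ca²⁺ in a medium with an
unsaturable mobile buffer.  The steady-state excess-buffer approximation
gives

    Ca(r) = |ḡ_Ca (V − V_Ca)| / (8π r D_Ca F) · exp(−r/λ),
    λ = sqrt(D_Ca / (k_B⁺ [B]_total)),

where the divalent charge of Ca²⁺ is folded into the 8π denominator (the
molar source strength is i/(2F), spread over 4π D r).  Nanodomains of
several open channels superpose linearly on the background concentration
Cac (linear buffer approximation); the profile equilibrates effectively
instantaneously on gating timescales, so channel state changes switch the
sensor concentration in zero time.

Defaults: D_Ca = 0.22 µm²/ms, ḡ_Ca = 2.8 pS, V_Ca = 60 mV, Cac = Cab =
0.2 µM.  The buffer product k_B⁺[B]_total is not set directly: it is
calibrated (once, in closed form) so that a single open CaV produces
19 µM at r = 13 nm and V = 0 mV — the physiologically anchored value for
the BK sensor in a channel complex.  That pins λ ≈ 53.5 nm and
k_B⁺[B]_total ≈ 77 ms⁻¹; the split [B]_total = 100 µM is arbitrary
because only the product enters the formula.  An outward driving force
(V > V_Ca) raises an error rather than being clamped: the formula models
influx only.

## CaV gating (`cav`)

A CaV is a 3-state chain C ⇌ O → B → C.  Activation is parameterized by a
Boltzmann steady state m∞(V) = 1/(1+exp(−(V−V_half)/s)) and a constant
time constant τ_m, from which α = m∞/τ_m and β = 1/τ_m − α.  Inactivation
is Ca²⁺-dependent: δ = δ_coeff · Ca(r_inact) with the channel's own sensor
at r_inact = 7 nm seeing its own open-channel nanodomain; reactivation
B → C at constant γ.  Activation (ms) is far faster than inactivation
(~100 ms), which justifies the separated two-ODE reduction (m_CaV plus
inactivated fraction b, with the activatable-fraction weighting m∞δ in
the b-equation) and, further, the instantaneous-activation limit
m_CaV = m∞.

Defaults: V_half = −18 mV, s = 8 mV, τ_m = 1 ms, γ = 0.002 ms⁻¹,
δ_coeff = 2.5·10⁻⁴ µM⁻¹ms⁻¹, N_CaV = 1000.  The steep slope keeps the
resting open probability below 1% at −60 mV, as single-channel recordings
of high-voltage-activated CaVs show.  This matters downstream: a shallow
activation curve puts percent-level channel openings at hyperpolarized
potentials, where the driving force — and hence the local Ca²⁺ per
opening — is maximal, and that spurious background influx measurably
distorts the exocytosis efficiency comparisons.  γ and δ_coeff give slow
inactivation (τ ≈ 100 ms scale at 0 mV), preserving the time-scale
separation; they only matter for the inactivating (6-state and 15-state)
chains, not for the whole-cell model, where CaVs do not inactivate.

## BK_Ca rates and complexes (`bk`)

The BK channel is a 2-state unit X ⇌ Y with separable rates

    k± = w±(V) f±(Ca),  w±(V) = ω·exp(±V/(2 s_V)),
    f₊ = floor + (1−floor)·Ca^e/(Ca^e + Ca_half^e),  f₋ mirrored,

so the steady open probability is a Boltzmann in V with Ca-independent
slope s_V and half-activation V½(Ca) = s_V ln(f₋/f₊) that shifts leftward
with Ca.  Defaults: ω = 0.2 ms⁻¹, s_V = 8 mV, Ca_half = 100 µM, e = 3,
floor = 10⁻⁶.  These were calibrated once against three anchors: (a) the
opening rate at background Ca (0.2 µM) must be < 10⁻³ of the rate at the
single-open-channel level (19 µM), so a complex with closed CaVs is
effectively silent; (b) the Ca dependence should resemble the α-subunit
BK channel, which at ~20 µM local Ca half-activates only at strongly
depolarized potentials (V½(19 µM) ≈ +70 mV here, dropping to ≈ +12 mV at
four open CaVs); and (c) the whole-cell behavioral anchor below.  With
these rates τ_BK at depolarized potentials is 1.5–8 ms.

Complex chains: the 1:1 inactivating complex is the 6-state product
{C,O,B}×{X,Y} with CaV rates identical in both BK rows and BK rates
switching between Cac (C and B columns) and the one-open nanodomain level
(O column).  The 1:k non-inactivating complex has states (i open CaVs,
X/Y), i = 0..k, with binomial horizontal rates (k−i)α / iβ and vertical BK
rates evaluated at Cac + i·(single-channel nanodomain at 13 nm).

Reductions: eliminating the open-BK occupancies below the top level by a
quasi-steady-state (QSS) linear solve at each (V, m_CaV) collapses the
chain to a single relaxation ODE dm_BK/dt = (m_BK,∞ − m_BK)/τ_BK.  For
k = 1 the coefficients have the printed closed form, which neglects the
(negligible) closed-complex opening rate; the general linear solve adopts
the same convention so the two agree to machine precision.  In the
instantaneous-CaV limit the open-CaV count is binomial(k, m∞) and the
coefficients are binomial averages of the vertical rates in closed form.
With inactivating CaVs the open probability is the binomial mixture
pY(n) = Σ_k C(n,k) h^k (1−h)^(n−k) m_BK(k) over the non-inactivated count.

## Markov-chain engine (`markov`)

* Master equation: exact matrix-exponential stepping between grid points
  (constant or piecewise-constant drivers; kernels cached per (V, Δt)); a
  stiff LSODA path exists for continuously varying drivers.  Tolerances
  rtol 10⁻⁸ / atol 10⁻¹⁰.
* Gillespie: statistically exact for piecewise-constant drivers; waiting
  times are truncated at driver discontinuities and redrawn, which is
  exact by memorylessness.  Ensembles draw per-path child seeds from a
  `SeedSequence`, so results are order-independent and reproducible.
* Fixed-step SSA for continuously varying drivers, with a hard validity
  bound max(exit rate)·dt < 0.05 checked up front.
* Skeleton sampler: for long periodic piecewise-constant drivers the
  state at consecutive output times is a Markov chain whose kernel is the
  product of segment matrix exponentials; sampling those compound kernels
  is exact at the output grid and orders of magnitude faster than event-
  by-event simulation over hundreds of seconds.  Used for the N = 1000
  exocytosis ensembles.
* Phase-type absorption: P(absorbed by t) = 1 − p₀ᵀ exp(T t) 1 over the
  transient block, plus the mean first-passage time −p₀ᵀT⁻¹1.
* Monte-Carlo acceptance bands: ensemble means are compared with exact
  probabilities via two-sided binomial quantile bands at per-point level
  10⁻⁶ (`mc_comparison_band`).  This is the operational form of a
  "within 4 SE" check: a Gaussian ±4σ band is mis-calibrated in the
  skewed few-counts regime, where a pointwise check on a fine grid would
  false-alarm.

## Whole-cell lactotroph model (`wholecell`)

C dV/dt = −(I_Ca + I_K + I_SK + I_BK + I_leak) with instantaneous Ca²⁺
current activation, first-order delayed-rectifier gating n_K, an SK
current gated by cytosolic Ca²⁺ c through c²/(c²+k_s²), a passive leak,
and I_BK = N_BK·ḡ_BK·m_BK(n)·(V−V_K) from the complex model (CaVs do not
inactivate here, h ≡ 1).  Ca²⁺ handling: dc/dt = −f_c(κ·I_Ca + k_c·c).

Defaults: C = 10 pF, g_Ca = N_CaV·ḡ_Ca = 2.8 nS, g_K = 4 nS, g_SK = 2 nS,
g_leak = 0.2 nS, V_K = −75, V_Ca = 60, V_leak = −50 mV, n-gating
(−5 mV, 10 mV, τ = 30 ms), k_s = 0.4 µM, f_c = 0.01, κ = 0.0015 µM/fC,
k_c = 0.12 ms⁻¹, ḡ_BK = 100 pS with N_BK = 1000 (n = 1) or 700 (n ≥ 2).
The base conductances are the standard lactotroph set, with g_K and g_SK
adjusted once so that the calibrated model satisfies the behavioral
anchor: continuous spiking at 1:1 stoichiometry, pseudo-plateau bursting
at 1:2 and 1:4, identically under the fullODE and qss BK descriptions
(and in this calibration also under the instantaneous-CaV variant), with
the number of within-burst oscillations increasing with n.

The qss/instant BK coefficients are precomputed on a (V, m_CaV) grid
(0.5 mV × 0.025, exact linear solves at the nodes) and interpolated
bilinearly inside the right-hand side; direct per-evaluation solves would
dominate the integration cost.  Output grid 0.05 ms by default, 2 s
transient discarded.  Pattern classification: maximal intervals with
V > −35 mV lasting ≥ 60 ms and containing ≥ 2 local maxima are bursts;
events are prominence-filtered local maxima above −20 mV; a trace with
≥ 2 bursts is "bursting", otherwise with ≥ 2 events "spiking", else
"quiescent".  Thresholds are reported with every classification.

## Granule exocytosis (`exocytosis`)

The granule sensor binds three Ca²⁺ ions sequentially (forward 3k_Ca,
2k_Ca, k_Ca with k_Ca = k⁺·Ca at the sensor; backward k⁻, 2k⁻, 3k⁻) and
fuses irreversibly from the triply-bound state at rate u.  Coupled to n
non-inactivating CaVs this gives a product chain over (granule state,
open count); all fused states are merged into one absorbing state, giving
4(n+1)+1 states — results are identical to the unmerged product because
fusion is irreversible (verified in tests).  With one inactivating CaV
the full 15-state product is kept.

Defaults: k⁺ = 0.01 µM⁻¹ms⁻¹, k⁻ = 0.3 ms⁻¹, u = 3 ms⁻¹, giving the
fast-fusion regime u/k⁻ = 10, a sigmoidal (zero-initial-slope) release
onset, and a mean fusion latency of 27 ms at a sustained 20 µM step —
the tens-of-ms scale of flash-release experiments at comparable Ca²⁺.
A slower sensor was considered and rejected: pushing the 20-µM latency
into the hundreds of milliseconds makes the sensor either too insensitive
to resolve burst/spike differences at 100 nm coupling within any
reasonable observation window, or (with slow unbinding) lets it integrate
the sparse background openings that the charge normalization then
mis-prices.

Q_Ca(t) integrates |n·ḡ_Ca·m(t)·(V−V_Ca)| with the expected open fraction
m(t); within each constant-voltage segment m relaxes exponentially and
the integral is evaluated in closed form, so Q_Ca is exact and
independent of the output grid (a quadrature on a coarse grid aliases
periodic waveforms badly).  The efficiency fit P_exo = 1 − exp(−q·Q_Ca)
is nonlinear least squares with a linearized-covariance 95% CI, applied
to the rising phase of the curve (P_exo ≤ 0.95) to avoid the fit being
dominated by the saturated tail.

## Synthetic data (`calibration`)

Gating fixtures apply multiplicative log-normal noise to the underlying
opening/closing rates (keeping p∞ inside (0,1)); the separable-rate fit
works in log-rate space (rates span orders of magnitude in V) with
data-driven initialization and multi-start Levenberg–Marquardt, and
reports a separability score: the variance fraction of the log-rate table
explained by an additive V + Ca decomposition (warning below 0.9).

Voltage fixtures are piecewise-constant idealizations of the two
pituitary patterns: spiking = 4 Hz, 10-ms square depolarizations to
−10 mV from −60 mV (4% of time above −35 mV); bursting = 0.5 Hz, 800-ms
plateaus alternating −20/−30 mV with the same −60 mV baseline (40% above
−35 mV).  They emulate the duty-cycle contrast of the two patterns, not
the detailed spike shape: square pulses have no upstroke/downstroke
flanks, and the plateau ripple is a square wave rather than damped
oscillations.  The piecewise-constant form is what makes exact
(truncation-free) stochastic simulation and closed-form charge integrals
possible.  The calibrated whole-cell model can substitute real waveforms
(`experiments.wholecell_pattern_cycles` extracts and quantizes one period
of each regime), but in the default calibration the bursting regime's
plateau fraction (~0.11) barely exceeds the spiking regime's time above
threshold (~0.10), so the two waveforms drive exocytosis almost
identically and the canned fixtures are used for the pattern comparison.

## Frozen experiment protocols (`experiments`)

* Reduction ladder: hold −80 mV (10 ms), 150-ms steps; 150 ms rather than
  a shorter step so that the instantaneous-CaV comparison window —
  everything after t_step + 5(τ_m + τ_BK), five time constants of both
  fast processes the reduction removes or relaxes through — is non-empty
  even where τ_BK ≈ 17 ms.
* Exocytosis observation windows scale with the coupling distance
  (10/20/50/100 nm → 10/30/120/600 s), long enough for the slowest curve
  to develop.
* Monte-Carlo significance windows: 3 s at 50 nm and 120 s at 100 nm,
  chosen from the master-equation curves as times where the burst–spike
  difference exceeds four binomial standard errors at N = 1000 for every
  stoichiometry simultaneously (close/fast combinations saturate early —
  both patterns reach P_exo = 1 and the difference vanishes; distant/slow
  ones resolve late).
* The close-coupling burst–spike gap is compared across n at the matched
  time where the slowest response (spiking, n = 1) reaches half-maximum;
  later, saturation collapses all gaps to zero.

## Findings and limitations

* The reduction ladder is essentially exact under the default kinetics:
  QSS sup-norm deviations from the full ODE are < 10⁻³ and the
  instantaneous-CaV variant is within 10⁻³ after its transient, because
  BK relaxation is slow compared with CaV activation at these parameters.
* Bursting robustly evokes release faster than spiking in wall-clock
  time at every coupling distance and stoichiometry, with the advantage
  shrinking at close coupling as more CaVs saturate the sensor.
* Normalized to Ca²⁺ entry, the two patterns are equally efficient at
  close coupling (|q_burst − q_spike|/q_spike < 0.1 at 10–20 nm for all
  n here).  At 100 nm with one or two CaVs, however, this implementation
  finds spiking slightly *more* efficient per unit charge (q_burst/q_spike
  ≈ 0.67 at n = 1, ≈ 0.84 at n = 2): brief depolarizations run the CaVs
  at higher open probability than the −25 mV plateau, so spiking wastes
  less charge per unit of local-Ca exposure, and a lone distant CaV has
  no channel-overlap supralinearity for bursting to exploit.  This
  per-charge sign at loose coupling is sensitive to the spike waveform
  (flanks), the CaV activation curve and the sensor kinetics, and should
  not be over-interpreted; the wall-clock-rate conclusion is robust.
* Not modeled: time-dependent reaction–diffusion of the nanodomain
  (profiles are instantaneous steady states), buffer saturation, granule
  pool dynamics and resupply, feedback of exocytosis on the membrane
  potential, multiple granules sharing nanodomains, and BK β-subunit
  modulation.  The whole-cell default parameter set is one calibrated
  point, not a fit to a specific cell's recordings; conclusions that
  depend on its waveform details (e.g. plateau duty cycle) should be
  re-examined with recorded or re-calibrated waveforms.
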