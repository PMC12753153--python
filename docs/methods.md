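# Methods

`gdrelax` models the phase relaxation (decoherence) of high-spin Gd(III)
spin labels as probed by W-band pulsed EPR, and provides the analysis
machinery to decompose it into mechanisms.  This note documents the models,
their assumptions, the numerical choices, and what the synthetic data do
and do not emulate.

## Spin system and ED-EPR simulation

The electron spin is S = 7/2 with an isotropic g (default 1.992) and the
conventional zero-field-splitting Hamiltonian

    H/h = g μB B (n·S)/h + D [Sz² − S(S+1)/3] + E (Sx² − Sy²),

with energies in MHz, fields in mT, and n the field direction in the ZFS
principal frame.  D and E carry independent Gaussian distributions
("strain"); the widths are interpreted as FWHM by default
(`strain_is_fwhm=False` switches to standard deviations), matching the
convention of the simulation packages commonly used for such spectra.
Higher-rank ZFS terms, g anisotropy, and hyperfine terms in the electron
Hamiltonian are out of scope.

An echo-detected field sweep is simulated by locating, for every molecular
orientation, the field at which each |mS⟩↔|mS+1⟩ level splitting equals the
microwave quantum.  Levels are labelled by sorted eigenvalue order, valid
in the high-field regime (Zeeman ≈ 95 GHz vs D ≤ ~4.2 GHz).  The splitting
curves are sampled on a 9-point coarse field mesh, interpolated linearly,
and refined with one secant step using an exact diagonalization at the
estimate; the residual position error is far below the 0.1 mT detection
line width.  Each line is weighted by the Boltzmann population difference
of the connected levels (temperature-dependent, evaluated at the resonance
field), the squared transverse transition moment |⟨u|S_perp|l⟩|², and the
pulse-turning-angle renormalization sin³(πα/2)/α with

    α = √[(S(S+1) − mS(mS+1)) / (S(S+1) + 0.25)],

which equals 1 for the central transition (CT), the reference the detection
pulses are calibrated on.  Differences in phase memory time between
transitions during the short detection interpulse delay are deliberately
ignored.  The spectrum is finally convolved with a 0.1 mT FWHM Gaussian.

Orientation averaging uses a deterministic equal-area spiral over the
powder fundamental domain (θ, φ ∈ [0, π/2]; the ZFS Hamiltonian has D2h
symmetry).  Each azimuth is paired with its mirror π/2 − φ, which makes the
grid exactly invariant under the E → −E equivalence, so that symmetry holds
to round-off at any orientation count.  The default is 3000 orientations;
doubling changes the spectrum by < 2 % RMS for the large-ZFS test case.

Strain averaging defaults to first-order propagation: the derivative of
each resonance field with respect to D and E is estimated by a symmetric
difference across one strain standard deviation, and the line is deposited
as a Gaussian of width σ_B = √[(∂B/∂D σ_D)² + (∂B/∂E σ_E)²] (the
distributions are uncorrelated).  This is the standard strain-broadening
treatment in solid-state EPR simulators; it is deterministic, smooth in
the parameters (important for least-squares fitting), and conserves
integrated intensity exactly.  Explicit Gauss–Hermite quadrature and seeded
Monte-Carlo averaging over (D, E) draws are retained as cross-validation
modes; the quadrature spectrum is a sum of sharp powder patterns and needs
far more orientations for the same smoothness, which is why it is not the
default.  The linearization assumes the resonance position responds
approximately linearly to D and E across one σ; for the central transition,
whose field depends on the ZFS only at second order, the symmetric
difference captures the leading curvature term.

ZFS fitting minimizes the sum of squares between unit-maximum-normalized
spectra (overall amplitude is a nuisance scale).  Because the discretized
powder sum retains sub-mT jaggedness, a naive finite-difference
trust-region optimizer stalls; the fit therefore anneals through stages of
(extra Gaussian smoothing applied identically to both spectra, relative
finite-difference step), by default (5 mT, 0.05) then (1 mT, 0.005).
Convolution commutes with the comparison, so the smoothed problem has the
same optimum.  Uncertainties come from the Jacobian at the optimum;
parameters within 0.1 % of a bound are flagged.

## Relaxation models

Hahn-echo decays are fitted with a single stretched exponential (SE),
y = A exp[−(2τ/Tm)^β]; the time axis used throughout is the total evolution
time (2τ for Hahn echoes; traces recorded versus τ are doubled on
ingestion).  Full Carr–Purcell-train echo decays are fitted with a sum of
two stretched exponentials (SSE),

    y = A exp[−(t/Tm,f)^βf] + (1−A) exp[−(t/Tm,s)^βs],

with t the time from the first π/2 pulse, plus one overall amplitude scale
(the data are not assumed normalized to exactly 1 at t = 0).  Bounds:
β ∈ [0.3, 3.5] and Tm ∈ [0.1, 500] µs, bracketing every value the study
conditions produce with margin.  Fits are multi-start (5 log-spaced Tm
initials × β initials {0.7, 1.0, 1.8}; pairs thereof for the SSE), the best
sum of squares wins, and SSE components are relabelled so Tm,f < Tm,s.
A fast fraction pinned within 0.02 of 0 or 1 is reported as "effectively
SE".  Inversion recovery is fitted with y = y0 − 2A exp[−(t/T1)^s]; a fit
is flagged low-confidence when the trace spans less than twice the fitted
T1 or the relative T1 uncertainty exceeds 10 %.

Model selection between SE and SSE uses the corrected Akaike criterion on
the unweighted sum of squares; the two-component model is accepted only on
strong evidence (ΔAICc > 10).  This threshold is this package's choice —
the selection rule behind "could not be fitted satisfactorily" in the
original analyses is not specified — and is deliberately conservative so
that single-population (nitroxide-like) trains are never split into two
components.  Fits are unweighted by default (no noise model is given for
the source data); a per-point σ column is honoured when present.

## Mechanism decomposition

The concentration series 1/Tm = slope·C + intercept is fitted by weighted
linear least squares (weights from σ_rate = Tm_err/Tm² when supplied,
ordinary least squares otherwise).  Tm(0) = 1/intercept with first-order
error propagation.  The rate budget assigns direct spin–lattice relaxation
1/(2T1) (the Tm ≤ 2T1 ceiling), instantaneous diffusion (ID), indirect-T1
spectral diffusion (SD-T1 = the concentration-dependent remainder), and a
concentration-independent residual (transient-ZFS fluctuations plus
residual nuclear spin diffusion) obtained by elimination.  No quantitative
transient-ZFS model is attempted.

Both dipolar rate predictions share the statistical (dilute-bath)
Lorentzian half-width constant

    A_dd = (4π²/9√3)(μ0/4π) g²μB²/ħ · n  ≈ 4.94·10⁻⁴ rad µs⁻¹ µM⁻¹ (g = 1.992),

with n the spin number density.  Instantaneous diffusion is the classic
excitation-weighted form 1/T_ID = A_dd · C · ⟨sin²(θ₂/2)⟩; for the narrow
CT of a broad Gd(III) spectrum the excitation fraction is a few percent,
which makes ID negligible against SD-T1 — the package reproduces this
elimination argument numerically.

For the indirect-T1 spectral diffusion rate the same dipolar constant is
gated by the probability that a neighbouring (B) spin flips during the
echo observation window:

    1/T_SD,T1 = A_dd · C · f_eq · [1 − exp(−t_obs/T1)] · η ,

where f_eq = 2S/(2S+1) is the equilibrium probability that an 8-level
high-spin B spin is found away from its initial level (7/8 for S = 7/2;
1/2 would apply to an S = 1/2 bath — the high-spin factor is switchable),
t_obs is the observation window (default 40 µs, about twice the
zero-concentration phase memory time of the Hahn measurements), and
η = 1/2 is the mean refocusing loss of a single sudden flip occurring at a
random time within the sequence.  The expression is strictly linear in
concentration, as required of the dilute regime.  With T1 = 45.5 µs it
predicts a slope of 1.26·10⁻⁴ µs⁻¹µM⁻¹.  Several standard readings of the
"T1-gated dipolar width" idea differ in these prefactors; all of them are
exposed as arguments, and the agreement of the default combination with
the independently published theoretical slope for these conditions
(1.2·10⁻⁴ µs⁻¹µM⁻¹, to ~5 %) is what validates the chosen form.  The exact
sudden-jump (Klauder–Anderson-type) treatment yields a √C dependence in
the slow-flip limit and is intentionally not used: the quantity being
reproduced is defined as a linear-in-C slope.

The 1/Tm-versus-1/T1 correlation is a linear fit with two nonlinearity
diagnostics: global R² < 0.98, or a disagreement larger than 30 % of the
global slope between lines fitted on the lower and upper halves of the
1/T1 range.  The second test is what detects the low-temperature plateau
(1/Tm constant below ~5 K), which occupies only a small part of the 1/T1
range and barely moves R².

## Pulse-sequence simulation

The observed central transition is propagated as a two-level system in the
rotating frame (Bloch vector per offset packet).  Pulses are exact
rotations about the tilted effective field (ω₁ cos φ, ω₁ sin φ, Δω)/Ω by
angle Ω·t_p, so finite bandwidth and off-resonance tilt are captured;
sequence timing is counted between pulse centers and relaxation during the
15–30 ns pulses is neglected (< 10⁻⁴ amplitude error against µs-scale
relaxation times).  During free delays the transverse components precess
and decay and the longitudinal component recovers toward equilibrium; the
transverse kernel may be stretched, exp[−(t/T2)^β], accumulated on the
global sequence clock so that an uninterrupted transverse interval of
length t decays by exactly that factor (with ideal pulses the full CP train
reproduces exp[−(t/T2)^β] to round-off).  Because the full magnetization
vector is carried, all coherence pathways — including z-stored
stimulated-echo pathways that decay with T1 — are implicit.  Echo intensity
is the in-phase component at the echo center (point detection), with the
sign convention that an ideal refocused echo reads +1.

The optional scaling of the nutation frequency by the CT transition-moment
enhancement (S + 1/2 = 4) is a configuration of the pulse objects (scale
ω₁ or flip angle); the default simulates the calibrated CT directly, since
all sequences under study are calibrated on the CT itself.

Phase cycles are data (packaged JSON, replaceable by a spectrometer's own
tables): the 2ⁿ-step nested ±x cycle on the n refocusing pulses of CPn —
the fully refocused pathway is invariant under a π phase shift of a π
pulse, while pathways stored along z across it change sign, so the plain
average cancels them — and the two-step ±x cycle on the first π/2 of the
full train.  Validation uses exact constructions: on an offset comb whose
free-precession phases tile [0, 2π) uniformly, every phase-carrying
pathway cancels in the ensemble average and the propagator reproduces the
hard-pulse pathway amplitudes sin θ₁ sin²(θ₂/2) (primary echo) and
½ sin θ₁ sin θ₂ sin θ₃ (stimulated echo) to machine precision; for 30 ns
pulses on a broad Gaussian ensemble it matches the tilted-frame
refocused-pathway formula (ω₁/Ω) sin Ωt₉₀ · [(ω₁/Ω) sin(Ωt₁₈₀/2)]².

The stimulated-echo bias experiment propagates the full CP train
(τ = 290 ns, 140 echoes, π = 30 ns, offsets Gaussian with σ = 100 MHz —
several times the ~17 MHz pulse excitation bandwidth, emulating selective
excitation of a broad line) with T2 = 18 µs and T1 = 45.5 µs, fits the echo
decay with the SE model, and reports (Tm_fit − T2)/T2.  Across offset
seeds the bias is a few to ~13 %, within the expected ≤ 20 % bound, and the
decay never warrants a second component by the AICc rule ("a single
stretched exponential fits").  With 512 random offsets the echo train
carries visible sampling granularity; residual-based adequacy judgments
would confound that granularity with model misfit, which is why adequacy
is judged by model comparison instead.

## Mims ENDOR and distances

The Mims response is ¼[1 − cos(2π a τ)]: blind spots at aτ ∈ ℤ, maxima of
½ at half-integers.  Powder doublets for axial hyperfine tensors
a(θ) = a∥cos²θ + a⊥sin²θ (pure point dipole: a∥ = −2a⊥) are accumulated
with sin θ weights and the Mims response evaluated at the local coupling;
the τ choices of the study emerge naturally: τ = 280 ns keeps the MHz-range
couplings near their response maximum (τ = 600 ns blind-spots them) while
τ = 600 ns more than triples the response of the 0.14–0.17 MHz couplings.
Peak amplitudes between different τ are not normalized to each other.
Electron–proton distances use the point-dipole relation
a⊥ = K(g)/r³ with K(g_e) ≈ 79 MHz·Å³; the 440 kHz pyridine-proton coupling
maps to 5.6 Å, consistent with the ~5.5 Å structural distance to within a
few percent.

## Synthetic data

The generators encode the study conditions as defaults: W-band (94.9 GHz;
the exact spectrometer frequencies are not published, so this default is
always configurable and recorded in outputs), 10 K, two complexes —
moderate ZFS (D = 1200 MHz, broad strain; concentration law
1/Tm = 9.07·10⁻⁵·C + 0.05 µs⁻¹, β → 1 as C → 0) and large ZFS (D = 4200,
ΔD = 390, E = 440, ΔE = 370 MHz; 1/Tm = 7.79·10⁻⁵·C + 0.100 µs⁻¹,
β → 0.8).  Full-train truths use the two-component reference set
(fast 3.3 µs / β 1.85 / fraction 0.25; slow 29.6 µs / β 0.78) on a 140-echo
τ = 290 ns grid; inversion recovery uses T1 = 45.5 µs with stretch 0.75.
The moderate-ZFS strain values (ΔD = 500, ΔE = 300 MHz about E = 300 MHz)
are this package's choice of a realistic broad distribution for a
seven-coordinate chelate whose background is featureless; they are not
fitted quantities.

Noise is i.i.d. Gaussian with a fractional-of-maximum σ; concentration
series carry a 1 % relative rate noise by default, the typical
stretched-exponential fit uncertainty for such data.  Every generator is
bit-reproducible for a fixed seed.  Not emulated: instrument deadtime,
phase drift, nuclear modulation (ESEEM), baseline artifacts, and any
correlation structure in the noise.  Passing recovery tests therefore
demonstrates correctness and statistical calibration of the estimators
under clean noise, not robustness to instrumental artifacts.

## Problem sizes

Default problem sizes are chosen so every analysis runs on a laptop core in
seconds to tens of seconds: 3000 powder orientations (spectra), 400 for
fitting loops, 512 offset packets for CP-train ensembles, 500 replicates
for coverage studies, 20 seeds for median recovery.  All are arguments.

## Known limitations

* The two-level CT model ignores simultaneous multi-transition excitation
  and transfer between manifolds during pulses.
* Linearized strain is first-order; for strains approaching the parameter
  itself (σ_D ~ D) explicit quadrature/Monte-Carlo modes should be used.
* The SD-T1 expression is a rate model with exposed prefactors, not a
  microscopic cluster simulation; nuclear-spin-diffusion dynamics
  (pair-product methods) are out of scope.
* The AICc threshold of 10, the 0.98 R² threshold, and the 30 % split-slope
  threshold are calibrated for the clean synthetic conditions above.
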