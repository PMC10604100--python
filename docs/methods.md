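# Methods

This note documents the models behind `zmwell`, the choices made where
the design was genuinely open, and what the synthetic-data tests do and
do not demonstrate about real nanowell experiments.

## Geometry and axis convention

A nanowell is described by the aperture diameter `d`, the metal film
thickness `t_m` (default 100 nm Pd) and the overmill depth `h` milled
into the glass.  One axis convention is used everywhere: `z = 0` at the
lower (glass-side) metal surface, `z` increasing from the nanowell
toward the metal and the aqueous reservoir.  The nanowell occupies
`[-h, 0]`, the aperture `[0, t_m]`; the objective collects from
`z < 0`.  Signal-weighted averages (enhancement, lifetime) run from the
bottom of the well to 200 nm beyond the reference plane, `[-h, +200]`
nm, matching the axial range over which the detected signal is
non-negligible.

## Optical calculus

**Cutoff and evanescent decay.**  A circular aperture blocks
propagation of in-medium wavelengths above `lambda_c = 1.7 d`.  Below
cutoff the intensity decays as `exp(-z / Lambda)` with the first-order
decay length `Lambda = [4 pi sqrt(1/lambda_c^2 - 1/lambda_m^2)]^{-1}`,
`lambda_m = lambda / n`.  For d = 100 nm at 488 nm in water this gives
15.3 nm.  Apertures above cutoff (d ≳ 216 nm at 488 nm in water) have
no finite decay length; the profile generator refuses to stitch an
evanescent tail there unless the caller explicitly requests a uniform
(unattenuated) aperture profile.

**Excitation.**  The excitation profile below the film is the exact
1-D transfer-matrix solution for the layer stack (default water /
100 nm Pd / water), solved for s or p polarization at any incidence
angle.  Interference of the incident and reflected wave forms a
standing wave; with the bundled Pd optical constants the peak at 488 nm
is ≈ 3.2× the incident intensity, and at oblique (TIRF-like) incidence
the first maximum moves away from the surface because only `k_z` enters
the interference phase.  Internal fields give per-layer absorption, so
`R + T + A = 1` is verified to 1e-10 rather than imposed.  The Pd
complex refractive index is a bundled visible-range tabulation for
evaporated films (Johnson & Christy 1974 dataset), log-interpolated in
wavelength; the table is a configuration item and can be replaced.

**Emission.**  A full-wave solver is out of scope.  Instead the metal
above the emitter is treated as a laterally infinite planar reflector
and the emission is computed from the classical angular-spectrum
(Chance–Prock–Silbey) integrals: total dissipated power `P_r/P_r0`
(including near-field quenching, via the evanescent part of the
integral), the far field radiated into the detection half-space, and
the leakage transmitted through the finite film.  Parallel and
perpendicular dipoles are averaged 2/3 : 1/3 for isotropic emission.
Lateral dependence is ignored (axial profiles only).  Inside the
aperture the planar model has no meaning, so the emitter–mirror
distance is floored at 10 nm; this yields the strong quenching expected
next to the metal and is a stated approximation, not a fitted value.

**Photophysics.**  With rates normalized to the intrinsic radiative
rate `gamma_r0 = Phi_0/tau_0`, the escaping far-field power maps to the
radiative rate (`gamma_r/gamma_r0 = P_ff/P_r0`) and the absorbed
remainder to the loss rate (`gamma_loss/gamma_r0 = (P_r - P_ff)/P_r0`).
Then

* quantum yield `Phi = gamma_r / (gamma_r + gamma_loss + gamma_nr0)`,
* lifetime `tau = Phi / gamma_r`  (equal to the inverse total rate),
* detection efficiency `eta = P_ff_down / P_ff`,
* detected signal `S(z) = I_ex(z) eta(z) Phi(z)`,
* enhancement `zeta(z) = S(z) / (I_ex0 * eta0 * Phi0)` with
  `eta0 = 0.5` (an isotropic emitter in homogeneous medium radiates
  half its far field into the detection half-space — verified by the
  same integrals with an index-matched "reflector").

This mapping keeps all identities exact in the free-space limit
(`Phi -> Phi0`, `tau -> tau0`, `zeta -> 1`).  The signal-averaged
lifetime uses the same `S(z)` weight as the average enhancement, since
both describe what a detected photon samples.  Quadrature is
trapezoidal on the native grid; grids must be strictly increasing and
are never resampled silently.

Reference fluorophores: Alexa488 (`Phi0 = 0.8`, `tau0 = 4.0` ns,
488/525 nm) and JFX650 (`Phi0 = 0.53`, `tau0 = 3.9` ns, 640/670 nm).

## Brownian-dynamics photon traces

Point particles diffuse in the union of the pore cylinder (radius
`d/2`, depth `h + t_m`) and a reservoir slab above the metal (default
500 × 500 × 250 nm), connected only through the aperture.  Defaults are
the in-vitro measurement conditions: 500 nM dye, `D = 400 µm²/s`
(free small dye), 0.4 µs time step (RMS step 17.9 nm; a warning or
error is raised when the step exceeds `d/10`), 2 µs photon bins.
Run duration defaults to 1 s; the test suites use 0.25–0.5 s, which is
sufficient because the pore-count correlation time is tens of
microseconds.

Boundaries use Metropolis-style move rejection (a proposed position
outside the domain is rejected), which satisfies detailed balance with
symmetric Gaussian proposals and therefore preserves the uniform
equilibrium density *exactly* — the grand-canonical contract that the
mean count in any subvolume equals `c N_A V`.  The cost is slightly
slowed dynamics within one step of a wall.  Particles crossing the
reservoir top are re-injected at a uniform lateral position with
reflected `z`; the lateral reservoir boundary wraps periodically.
Because re-injection conserves the particle number, each run holds the
initially Poisson-drawn count for its whole duration; per-run estimates
are therefore normalized by the run's *realized* concentration
(`DiffusionRun.realized_concentration_molar`) where the nominal
concentration would add pure finite-bath shot noise between seeds.

Photon counts per bin are Poisson with rate
`brightness * sum_i S(z_i)` over in-pore particles (brightness default
30 counts/ms per molecule), with axial-only `S` consistent with the
optics module; reservoir molecules can contribute a configurable
leak-through brightness to emulate background from the far side of the
ZMW.  Positions are recorded once per bin; at 2 µs bins versus ≥ 40 µs
diffusion times this sampling is far inside the correlation time.

## FCS analysis

The correlator is a multi-tau scheme with m = 16 channels per octave
and symmetric normalization (`G -> 0` at long lags); it is held equal
to the direct O(T²) estimator at every shared lag to 1e-10 in the
tests.  The zero-lag bin (shot-noise dominated) is never used; the
amplitude is read from the model fit.  Fits use the standard 3-D
diffusion model with the axial factor fixed at p = 3.4 and
inverse-variance weights from 8 block-averaged segment curves when
available, falling back to plain least squares.  For nanowell
geometries the model is an effective-parameter description: N and t_D
summarize amplitude and decay time and make no geometric claim.
Derived quantities: `eps = <I>/N`, `V_FCS = N/(N_A c)`,
`eps_ZMW/eps_0`.  Scaling analysis regresses `log N` on `log d` at
fixed `h` (cylinders give slope 2) and `N` on `h` at fixed `d` (affine,
intercept set by the aperture volume), with 95 % CIs from the
regression.

## TCSPC lifetime fitting

The decay model is `A * (IRF ⊛ sum_i a_i exp(-t/tau_i)) + bg`,
evaluated by discrete linear convolution on the histogram grid and
fitted by Poisson maximum likelihood (Nelder–Mead then BFGS), which
remains correct at low counts; goodness of fit is the reduced Pearson
chi-square.  A sub-bin IRF time shift is fitted by default as a
nuisance parameter — it absorbs the half-bin centering ambiguity of the
discrete convolution, which otherwise biases lifetimes of order the bin
width (≈ +2 % at tau = 0.5 ns with 25 ps bins).  Standard errors come
from a finite-difference Fisher information with a pseudo-inverse (the
background direction is flat when bg → 0).  Two-component fits report
both the amplitude-weighted mean `sum a_i tau_i` and the
intensity-weighted mean `sum f_i tau_i`; the generator's mixture
components are specified as photon (intensity) fractions, so an equal
1 ns / 5 ns mixture has an intensity-weighted mean of 3 ns.

The synthetic TCSPC generator draws photon delays as
`Exp(tau) + N(t0, sigma_IRF)` and emits the IRF histogram noise-free
(exact Gaussian bin mass); detector afterpulsing, pile-up and repetition
wrap-around are not modelled.

## Cell-movie generation and analysis

The movie generator renders a pore array (diameter varying by column
block, depth by row block, plus three corner marker holes) as Gaussian
spots with EMCCD noise modelled as gain-scaled Poisson plus Gaussian
read noise (gain 30, read SD 15); the full EM-register gamma statistics
are a documented simplification.  Covered pores are assigned
high or low population with exact configured fractions (low mean 8 % of
high, i.e. the <10 % regime); pore brightness scales as `d²`
(cytoplasmic volume in the well).  A configurable fraction of covered
pores switches as a two-state telegraph (default rate 0.2 /s — several
transitions per 15 s movie); single-molecule spikes with exponential
dwell times occur only on high pores.  The ground truth records both
the assigned and the *realized* population (a switching pore that never
occupied the well during the movie is observationally negative).

Analysis: pores are localized by phase-correlation registration of the
declared layout (markers anchor the grid) followed by sub-pixel
centroid refinement (< 0.5 px on the default movie).  Traces are the
mean over a 7×7 pixel window minus the mean of the window's outer
one-pixel ring (24 pixels) — "outer edge pixels" interpreted as that
ring, configurable — making traces exactly invariant to global offsets.
The positive threshold is mean + 3 SD of the no-cell control trace
means (k configurable; controls are mandatory).  Positives are split
high/low by a two-component 1-D Gaussian mixture *per pore diameter*,
because absolute intensity grows with pore size and the bimodal
structure exists within each size; the 8 %/high ratio is used only to
generate data, never by the classifier.  A trace is "switching" when a
two-means split separates levels by more than 3 within-level SDs *and*
the step exceeds 3× the control frame noise (pure noise splits at
≈ 1.6 σ and must not count); switching traces are classified by their
upper-level mean.  Occupancy fractions per (d, h) carry Wilson binomial
CIs.

## Two-state HMM

Gaussian-emission two-state HMM fitted by EM (hmmlearn), initialized
from a two-means split, decoded by the most-probable path, states
always reported sorted by mean.  This is a maximum-likelihood surrogate
for variational-Bayes single-molecule HMM tools; equivalence is claimed
only at the level of state assignments on well-separated traces.  A
fitted separation below 2 off-state SDs triggers a single-state
fallback (zero events) so noise-only traces do not yield spurious
spikes.  Trace metrics: peak = on-mean − off-mean, background
sigma = SD of off-state residuals, SNR = peak/sigma — invariant under
affine gain/offset by construction.  Minimum event length is one frame
(no morphological cleanup) by default.

## What the synthetic tests do and do not show

The generators reproduce the *statistical structure* the analyses
assume — Poisson photon statistics from confined diffusion at known
concentration, exponential decays under a Gaussian IRF, bimodal pore
populations with telegraph switching and EMCCD noise.  Passing the
recovery suites therefore shows the estimators are correct and
calibrated under their own assumptions.  They do not certify behaviour
under real-data effects that are deliberately not modelled: dye
photophysics (blinking, bleaching, saturation), anomalous or
membrane-bound diffusion, detector afterpulsing, focus drift,
non-planar cell geometry, or full vectorial field structure inside the
aperture (the planar-mirror and 1-D stack models replace the 3-D
electromagnetic problem).  Predicted enhancement factors are
semi-quantitative for apertures above cutoff, where the 1-D stitching
does not apply.

## Numerical choices

* Transfer matrix: stable downward recursion on interface reflection
  ratios; opaque layers underflow cleanly (T → 0) instead of
  overflowing.
* Dipole integrals: adaptive quadrature split at the branch point
  u = 1; the evanescent tail is truncated where its weight
  `exp(-2 k z sqrt(u²-1))` is below 1e-17.
* All randomness flows from a single integer seed per run (numpy
  `default_rng` plus a derived seed for the numba kernel); identical
  seeds reproduce every generator bit-for-bit.
* Problem sizes in the test suites (0.25–0.5 s simulated traces,
  20-seed ensembles, 64-pore movies, 2–10×10⁵-photon decays) are chosen
  so each statistical check resolves its tolerance with comfortable
  margin.
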