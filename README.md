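# zmwell

Optical modelling and single-molecule data analysis for **overmilled
zero-mode-waveguide (ZMW) nanowells** — subwavelength apertures in a
palladium film whose cavity is extended ("overmilled") into the glass
coverslip below, creating an attoliter observation volume that live-cell
protrusions can enter.

Nanowells make single-molecule fluorescence possible at micromolar
label concentrations: the aperture blocks propagating light above the
cutoff wavelength λ<sub>c</sub> = 1.7·d, the reflected excitation forms
a standing wave that focuses light into the well, and the metal mirror
redirects emission toward the objective.  This package implements the
computational chain of such an experiment for people who design or
analyse nanowell measurements:

* **Optical calculus** (`zmwell.optics`, `zmwell.dipole`, `zmwell.tmm`):
  metal-modified quantum yield
  Φ = γ<sub>r</sub> / (γ<sub>r</sub> + γ<sub>loss</sub> + γ<sub>nr</sub><sup>0</sup>),
  lifetime τ = Φ/γ<sub>r</sub>, detection efficiency
  η = P<sub>ff</sub><sup>z−</sup>/P<sub>ff</sub>, detected signal
  S(z) = I<sub>ex</sub>(z)·η(z)·Φ(z) and the signal-weighted enhancement
  ζ̄ = ∫ζS dz / ∫S dz against the free-diffusion reference
  (η<sub>0</sub> = 0.5).  Excitation profiles come from a 1-D transfer
  matrix, emission rates from the classical dipole-above-mirror
  (Chance–Prock–Silbey) angular-spectrum integrals.
* **FCS** (`zmwell.fcs`): multi-tau autocorrelation, fits of
  G(t<sub>c</sub>) = (1/N)(1 + t<sub>c</sub>/t<sub>D</sub>)<sup>−1</sup>(1 + t<sub>c</sub>/(p²t<sub>D</sub>))<sup>−1/2</sup>
  with p = 3.4 fixed, molecular brightness ε = ⟨I⟩/N, effective volume
  V<sub>FCS</sub> = N/(N<sub>A</sub>c) and enhancement
  ε<sub>ZMW</sub>/ε<sub>0</sub>.
* **TCSPC lifetimes** (`zmwell.lifetime`): Poisson-MLE reconvolution
  fitting (mono/bi-exponential) against the instrument response.
* **Cell imaging** (`zmwell.imaging`): pore localization on bright-field
  images, 7×7-pixel traces with edge-ring background subtraction,
  high/low/negative classification against a no-cell control threshold,
  occupancy-by-size statistics, wide-field vs TIRF comparison.
* **Trace HMM** (`zmwell.hmm`): two-state Gaussian HMM decoding of
  single-molecule traces with peak, background σ and SNR = peak/σ.
* **Synthetic data** (`zmwell.synthetic`): seed-deterministic generators
  for every input — axial field/emission profiles, Brownian-dynamics
  photon traces at a stated concentration, TCSPC histograms, and EMCCD
  pore-array movies with bimodal high/low pores, switching pores and
  single-molecule spikes.

The fitting stages follow the statsmodels convention: a model object
built from data whose `fit()` returns a results object with estimates,
uncertainties, diagnostics and a `summary()`.

## Worked example

Predict the optics of a d = 140 nm pore overmilled 100 nm deep, then
measure an FCS volume from a simulated 500 nM experiment:

```python
from zmwell import (ALEXA488, NanowellGeometry, SignalModel, SimConfig,
                    FcsModel, autocorrelate, emit_photon_trace,
                    make_optics_profiles, simulate_nanowell_diffusion)

geom = NanowellGeometry(diameter=140, overmill_depth=100)
exc, emi = make_optics_profiles(geom, ALEXA488)
model = SignalModel.from_profiles(exc, emi, ALEXA488, geom.overmill_depth)
print(f"zeta_bar = {model.average_enhancement():.2f}")
print(f"tau_avg  = {model.signal_averaged_lifetime():.2f} ns")

run = simulate_nanowell_diffusion(
    NanowellGeometry(diameter=200, overmill_depth=200),
    SimConfig(seed=1, duration_s=1.0))
trace = emit_photon_trace(run)
res = FcsModel(autocorrelate(trace, n_blocks=8), trace=trace).fit()
print(res.summary())
```

prints

```
zeta_bar = 2.99
tau_avg  = 3.03 ns
FCS 3-D diffusion fit (p = 3.40 fixed)
--------------------------------------------
N (particles)   : 2.42 +/- 0.079
t_D (ms)        : 0.04484 +/- 0.0025
G(0) amplitude  : 0.4133
residual norm   : 2.42
converged       : True
brightness eps  : 30.78 counts/ms
```

The predicted signal enhancement ζ̄ ≈ 3 for this geometry comes almost
entirely from the standing-wave focusing of the excitation; the reduced
signal-averaged lifetime (3.0 ns vs the 4.0 ns free-dye value of
Alexa488) reflects metal losses near the aperture.  The FCS fit of the
simulated d = 200 nm, h = 200 nm pore recovers N ≈ 2.4 molecules —
`res.fcs_volume_liters(c)` converts this to ≈ 9.2 aL, close to the
9.4 aL cylinder volume of the simulated pore.

A command-line pipeline wraps the same stages:

```bash
zmwell simulate-optics --config optics.yaml --seed 1 --out-dir run1
zmwell simulate-fcs    --config pore.yaml   --seed 1 --out-dir run2
zmwell fit-fcs         --config fit.yaml            --out-dir run3
```

Every run writes a `manifest.json` (config snapshot, seed, file hashes,
applied thresholds); re-running with the same config and seed reproduces
stochastic outputs bit-for-bit.

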