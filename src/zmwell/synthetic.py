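"""Synthetic-data generators for the nanowell analysis pipeline.

Every generator is seed-deterministic: the same configuration and seed
produce bit-identical output.  The generators emulate

* axial excitation / dipole-emission profiles (semi-analytic stand-ins
  for a full-wave field solver),
* photon time traces from confined Brownian diffusion at a stated
  concentration (Poisson photon statistics),
* TCSPC decay histograms convolved with a Gaussian instrument response,
* EMCCD movies of pore arrays with a bimodal high/low pore-intensity
  structure, switching pores, and single-molecule intensity spikes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.constants import N_A

from ._brownian import brownian_kernel
from .dipole import mirror_dipole_sample
from .geometry import ALEXA488, FluorophoreSpec, NanowellGeometry
from .optics import (
    AVERAGING_TOP_NM,
    DipoleEmissionProfile,
    ExcitationProfile,
    SignalModel,
    cutoff_wavelength,
    evanescent_decay_length,
    standing_wave_profile,
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generators.

    Defaults reproduce the in-vitro single-molecule conditions: 500 nM
    dye, free-dye diffusion, 1 ms-scale binning for display but 10 us
    internal bins for correlation analysis, and EMCCD camera imaging at
    100 nm pixels.
    """

    seed: int = 0
    concentration_molar: float = 500e-9
    diffusion_um2_s: float = 400.0
    time_step_us: float = 0.4
    duration_s: float = 2.0
    bin_width_ms: float = 0.002
    brightness_cpms: float = 30.0  # detected counts/ms per molecule at S = 1
    leak_brightness: float = 0.0  # relative brightness of reservoir molecules
    reservoir_lateral_nm: float = 500.0
    reservoir_height_nm: float = 250.0
    strict_step: bool = False  # error (not warn) when RMS step > d/10
    # camera (EMCCD, modelled as gain-scaled Poisson + Gaussian read noise)
    pixel_nm: float = 100.0
    em_gain: float = 30.0
    read_noise: float = 15.0
    frame_interval_s: float = 0.5
    psf_sigma_px: float = 1.3
    # pore-array trace structure
    covered_fraction: float = 0.8
    high_fraction: float = 0.5
    low_to_high_ratio: float = 0.08
    switching_fraction: float = 0.2
    switch_rate_per_s: float = 0.2
    spike_rate_per_s: float = 0.1
    spike_mean_duration_s: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "concentration_molar",
            "diffusion_um2_s",
            "time_step_us",
            "duration_s",
            "bin_width_ms",
            "brightness_cpms",
            "reservoir_lateral_nm",
            "reservoir_height_nm",
            "pixel_nm",
            "em_gain",
            "frame_interval_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# optics profiles

class PropagatingApertureError(ValueError):
    """The aperture is above cutoff: no evanescent decay length exists."""


def make_optics_profiles(
    geometry: NanowellGeometry,
    fluor: FluorophoreSpec = ALEXA488,
    mode: str = "widefield",
    angle_deg: float = 0.0,
    dz_nm: float = 5.0,
    n_medium: float = 1.33,
    mirror_floor_nm: float = 10.0,
    if_propagating: str = "raise",
) -> tuple[ExcitationProfile, DipoleEmissionProfile]:
    """Deterministic axial profiles for one pore geometry and fluorophore.

    Excitation: transfer-matrix standing wave below the Pd film, stitched
    to the evanescent decay inside the aperture.  Emission: planar-mirror
    dipole model sampled on the same grid, with the emitter-mirror
    distance floored at ``mirror_floor_nm`` (inside the aperture the
    planar model is used at the floor distance; quenching there is
    strong, as expected next to the metal).

    ``if_propagating``: for apertures above cutoff at the excitation
    wavelength, ``"raise"`` (default) or ``"uniform"`` (no axial
    attenuation inside the aperture; flagged in the mode tag).
    """
    h, t_m = geometry.overmill_depth, geometry.metal_thickness
    z = np.arange(-h, AVERAGING_TOP_NM + 0.5 * dz_nm, dz_nm)

    if angle_deg == 0 and mode == "tirf":
        angle_deg = 70.0
    exc_below = standing_wave_profile(
        fluor.excitation_nm,
        angle_deg=angle_deg,
        z_nm=z[z < 0] if (z < 0).any() else np.array([-dz_nm]),
    )
    intensity = np.empty_like(z)
    intensity[z < 0] = exc_below.intensity[: (z < 0).sum()]
    sol_at0 = standing_wave_profile(fluor.excitation_nm, angle_deg=angle_deg,
                                    z_nm=np.array([0.0]))
    i0 = float(sol_at0.intensity[0])

    lam_m = fluor.excitation_nm / n_medium
    lam_c = cutoff_wavelength(geometry.diameter)
    inside = z >= 0
    if lam_m > lam_c:  # below cutoff: evanescent decay inside the aperture
        lam_dec = evanescent_decay_length(
            geometry.diameter, fluor.excitation_nm, n_medium
        )
        intensity[inside] = i0 * np.exp(-z[inside] / lam_dec)
        tag = mode
    elif if_propagating == "uniform":
        intensity[inside] = i0
        tag = f"{mode}+propagating-aperture"
    else:
        raise PropagatingApertureError(
            f"aperture d = {geometry.diameter:.0f} nm is above cutoff at "
            f"{fluor.excitation_nm:.0f} nm (lambda_c = {lam_c:.0f} nm >= "
            f"lambda_m = {lam_m:.0f} nm); pass if_propagating='uniform' to "
            "disable axial attenuation explicitly"
        )

    reflector = None  # Pd film at the emission wavelength
    from .materials import palladium_index

    n_pd = palladium_index(fluor.emission_nm)
    p_tot = np.empty_like(z)
    p_ff = np.empty_like(z)
    p_down = np.empty_like(z)
    for i, zi in enumerate(z):
        dist = max(-zi, mirror_floor_nm)
        s = mirror_dipole_sample(
            dist, fluor.emission_nm, reflector=(n_pd, t_m), n_medium=n_medium
        )
        p_tot[i] = s.p_total("isotropic")
        p_ff[i] = s.p_ff("isotropic")
        p_down[i] = s.p_ff_down("isotropic")
    emission = DipoleEmissionProfile(
        z_nm=z, p_total=p_tot, p_ff=np.minimum(p_ff, p_tot), p_ff_down=p_down,
        orientation="isotropic",
    )
    excitation = ExcitationProfile(
        z_nm=z, intensity=intensity, mode=tag, wavelength_nm=fluor.excitation_nm
    )
    return excitation, emission


# ---------------------------------------------------------------------------
# Brownian diffusion + photon traces

@dataclass
class DiffusionRun:
    """Decimated trajectories of a nanowell diffusion simulation.

    ``z_nm`` holds the axial position of every particle at the start of
    each photon bin (shape ``(n_bins, n_particles)``); the lateral
    coordinates are not stored because the detected signal model is
    axial-only.  ``in_pore`` is the corresponding boolean mask.
    """

    geometry: NanowellGeometry
    config: SimConfig
    z_nm: np.ndarray
    n_particles: int
    seed: int

    @property
    def n_bins(self) -> int:
        return self.z_nm.shape[0]

    @property
    def in_pore(self) -> np.ndarray:
        return self.z_nm < self.geometry.metal_thickness

    def occupancy(self) -> float:
        """Time-averaged particle count in the pore (nanowell + aperture)."""
        return float(self.in_pore.sum(axis=1).mean())

    def expected_occupancy(self) -> float:
        """Closed-form expectation c * N_A * V for the pore volume."""
        return (
            self.config.concentration_molar * N_A * self.geometry.total_volume_liters
        )

    @property
    def domain_volume_liters(self) -> float:
        """Pore + reservoir volume of the simulation domain."""
        cfg = self.config
        v_res_nm3 = cfg.reservoir_lateral_nm**2 * cfg.reservoir_height_nm
        return (self.geometry.total_volume_nm3 + v_res_nm3) * 1e-24

    @property
    def realized_concentration_molar(self) -> float:
        """Actual concentration of this run.

        Re-injection at the reservoir top conserves the particle number,
        so each run's bath holds exactly the initially Poisson-drawn
        count; normalizing estimates by this realized concentration
        removes the finite-bath shot noise between seeds.
        """
        return self.n_particles / (N_A * self.domain_volume_liters)


def simulate_nanowell_diffusion(
    geometry: NanowellGeometry, config: SimConfig
) -> DiffusionRun:
    """Brownian dynamics of point particles in a nanowell open to a reservoir.

    The long-run mean particle count in any subvolume V equals
    ``c * N_A * V`` (within sampling error): the initial particle number
    is Poisson-drawn at the nominal concentration, positions start
    uniform, and the boundary rules preserve the uniform measure.
    """
    rng = np.random.default_rng(config.seed)
    d_nm2_us = config.diffusion_um2_s  # um^2/s = nm^2/us numerically
    sigma = math.sqrt(2.0 * d_nm2_us * config.time_step_us)
    if sigma > geometry.diameter / 10.0:
        msg = (
            f"RMS step {sigma:.1f} nm exceeds d/10 = {geometry.diameter / 10:.1f} nm; "
            "reduce time_step_us"
        )
        if config.strict_step:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)

    h, t_m, R = geometry.overmill_depth, geometry.metal_thickness, geometry.radius
    L, H = config.reservoir_lateral_nm, config.reservoir_height_nm
    if L < geometry.diameter:
        raise ValueError("reservoir must be laterally wider than the aperture")
    z_top = t_m + H
    v_pore = geometry.total_volume_nm3
    v_res = L * L * H
    n_per_nm3 = config.concentration_molar * N_A * 1e-24
    n_mean = n_per_nm3 * (v_pore + v_res)
    n = int(rng.poisson(n_mean))

    # uniform initial positions over the union volume
    x = np.empty(n)
    y = np.empty(n)
    z = np.empty(n)
    in_res = rng.random(n) < v_res / (v_pore + v_res)
    n_res = int(in_res.sum())
    x[in_res] = (rng.random(n_res) - 0.5) * L
    y[in_res] = (rng.random(n_res) - 0.5) * L
    z[in_res] = t_m + rng.random(n_res) * H
    n_pore = n - n_res
    r = R * np.sqrt(rng.random(n_pore))
    th = 2 * np.pi * rng.random(n_pore)
    x[~in_res] = r * np.cos(th)
    y[~in_res] = r * np.sin(th)
    z[~in_res] = -h + rng.random(n_pore) * (h + t_m)

    bin_us = config.bin_width_ms * 1000.0
    steps_per_bin = max(1, int(round(bin_us / config.time_step_us)))
    n_bins = int(round(config.duration_s * 1000.0 / config.bin_width_ms))
    z_out = np.empty((n_bins, n), dtype=np.float64)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    brownian_kernel(
        kernel_seed, n_bins, steps_per_bin, x, y, z,
        sigma, R, h, t_m, L, z_top, z_out,
    )
    return DiffusionRun(
        geometry=geometry,
        config=config,
        z_nm=z_out.astype(np.float32),
        n_particles=n,
        seed=config.seed,
    )


def emit_photon_trace(
    run: DiffusionRun,
    signal_model: SignalModel | None = None,
    config: SimConfig | None = None,
):
    """Binned Poisson photon counts from a diffusion run.

    Per-bin counts are Poisson with rate proportional to the summed
    detected signal ``S(z_i)`` over in-pore particles; ``signal_model=None``
    uses a uniform top-hat signal (S = 1 inside the pore).  Reservoir
    molecules contribute ``config.leak_brightness`` (relative units) to
    model leak-through background.
    """
    from .fcs import PhotonTrace

    cfg = config if config is not None else run.config
    rng = np.random.default_rng((run.seed, 0x9E3779B9))
    in_pore = run.in_pore
    if signal_model is None:
        s_sum = in_pore.sum(axis=1).astype(float)
    else:
        s_vals = np.zeros_like(run.z_nm, dtype=float)
        zp = run.z_nm[in_pore].astype(float)
        s_vals[in_pore] = np.interp(zp, signal_model.z_nm, signal_model.signal)
        s_sum = s_vals.sum(axis=1)
    if cfg.leak_brightness > 0:
        s_sum = s_sum + cfg.leak_brightness * (~in_pore).sum(axis=1)
    expected = cfg.brightness_cpms * cfg.bin_width_ms * s_sum
    counts = rng.poisson(expected)
    return PhotonTrace(bin_width_ms=cfg.bin_width_ms, counts=counts)


# ---------------------------------------------------------------------------
# TCSPC decays

def make_tcspc(
    components,
    irf_fwhm_ps: float = 200.0,
    n_photons: int = 1_000_000,
    bin_ps: float = 25.0,
    window_ns: float = 50.0,
    irf_center_ns: float = 5.0,
    seed: int = 0,
):
    """Synthetic TCSPC histogram: exponential decay(s) + Gaussian IRF jitter.

    ``components`` is a :class:`FluorophoreSpec` (mono-exponential at its
    free lifetime) or a list of ``(tau_ns, photon_fraction)`` pairs for
    mixtures; photon fractions are the probabilities that a detected
    photon originates from each component (i.e. intensity fractions).
    The IRF histogram is emitted noise-free (exact Gaussian bin mass).
    """
    from .lifetime import TcspcDecay

    if isinstance(components, FluorophoreSpec):
        components = [(components.lifetime_ns, 1.0)]
    taus = np.array([c[0] for c in components], dtype=float)
    fracs = np.array([c[1] for c in components], dtype=float)
    if np.any(taus <= 0) or np.any(fracs < 0) or fracs.sum() == 0:
        raise ValueError("invalid decay components")
    fracs = fracs / fracs.sum()
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    bin_ns = bin_ps / 1000.0
    if bin_ns > taus.min() / 2.0:
        warnings.warn(
            f"bin width {bin_ns:.3f} ns exceeds tau/2 for the fastest "
            f"component ({taus.min():.3f} ns)", stacklevel=2,
        )
    sigma_ns = irf_fwhm_ps / 1000.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    rng = np.random.default_rng(seed)
    comp = rng.choice(len(taus), size=n_photons, p=fracs)
    t = rng.exponential(taus[comp]) + irf_center_ns
    if sigma_ns > 0:
        t = t + rng.normal(0.0, sigma_ns, size=n_photons)
    edges = np.arange(0.0, window_ns + 0.5 * bin_ns, bin_ns)
    counts, _ = np.histogram(t, bins=edges)

    centers = 0.5 * (edges[:-1] + edges[1:])
    from scipy.stats import norm

    irf_mass = norm.cdf(edges[1:], irf_center_ns, max(sigma_ns, 1e-6)) - norm.cdf(
        edges[:-1], irf_center_ns, max(sigma_ns, 1e-6)
    )
    return TcspcDecay(
        bin_width_ps=bin_ps,
        counts=counts.astype(float),
        irf=irf_mass,
        meta={
            "tau_ns": taus.tolist(),
            "photon_fractions": fracs.tolist(),
            "irf_fwhm_ps": irf_fwhm_ps,
            "irf_center_ns": irf_center_ns,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# pore-array movies

@dataclass(frozen=True)
class PoreArrayLayout:
    """Grid layout of a pore array on the camera.

    ``pores`` columns: pore_id, row, col, x_px, y_px, d_nm, h_nm.
    ``markers`` are larger alignment holes used as registration anchors.
    """

    pores: pd.DataFrame
    markers: pd.DataFrame
    pixel_nm: float
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        xy = self.pores[["x_px", "y_px"]].to_numpy()
        if len(np.unique(xy, axis=0)) != len(xy):
            raise ValueError("pore centers must be unique")


def make_layout(
    n_rows: int = 8,
    n_cols: int = 8,
    pitch_px: float = 10.0,
    diameters_nm=(100.0, 140.0, 200.0, 280.0),
    depths_nm=(0.0, 50.0, 100.0, 200.0),
    pixel_nm: float = 100.0,
    margin_px: float = 12.0,
) -> PoreArrayLayout:
    """Regular pore grid; diameter varies by column block, depth by row block."""
    rows, cols, xs, ys, ds, hs = [], [], [], [], [], []
    for r in range(n_rows):
        for c in range(n_cols):
            rows.append(r)
            cols.append(c)
            xs.append(margin_px + c * pitch_px)
            ys.append(margin_px + r * pitch_px)
            ds.append(diameters_nm[c * len(diameters_nm) // n_cols])
            hs.append(depths_nm[r * len(depths_nm) // n_rows])
    pores = pd.DataFrame(
        {
            "pore_id": np.arange(n_rows * n_cols),
            "row": rows,
            "col": cols,
            "x_px": xs,
            "y_px": ys,
            "d_nm": ds,
            "h_nm": hs,
        }
    )
    size_y = int(2 * margin_px + (n_rows - 1) * pitch_px) + 1
    size_x = int(2 * margin_px + (n_cols - 1) * pitch_px) + 1
    mk = margin_px - 0.6 * pitch_px
    markers = pd.DataFrame(
        {
            "x_px": [mk, size_x - 1 - mk, mk],
            "y_px": [mk, mk, size_y - 1 - mk],
        }
    )
    layout = PoreArrayLayout(
        pores=pores, markers=markers, pixel_nm=pixel_nm, shape=(size_y, size_x)
    )
    min_sep = pitch_px * pixel_nm
    if min_sep < max(diameters_nm):
        raise ValueError("pores overlap at the given pitch/pixel size")
    return layout


def _render_spots(shape, xs, ys, amps, sigma_px):
    img = np.zeros(shape, dtype=float)
    yy, xx = np.indices((7, 7)) - 3.0
    kern_base = np.exp(-(xx**2 + yy**2) / (2 * sigma_px**2))
    for x0, y0, a in zip(xs, ys, amps):
        ix, iy = int(round(x0)), int(round(y0))
        dx, dy = x0 - ix, y0 - iy
        yy, xx = np.indices((7, 7)) - 3.0
        kern = np.exp(-((xx - dx) ** 2 + (yy - dy) ** 2) / (2 * sigma_px**2))
        y_lo, y_hi = max(iy - 3, 0), min(iy + 4, shape[0])
        x_lo, x_hi = max(ix - 3, 0), min(ix + 4, shape[1])
        img[y_lo:y_hi, x_lo:x_hi] += (
            a * kern[y_lo - iy + 3 : y_hi - iy + 3, x_lo - ix + 3 : x_hi - ix + 3]
        )
    return img


def _telegraph(rng, n_frames, dt_s, rate_on, rate_off, start_state=None):
    """Two-state telegraph sequence (0/1) with exponential dwell times."""
    p_stat = rate_on / (rate_on + rate_off)
    state = (rng.random() < p_stat) if start_state is None else start_state
    seq = np.empty(n_frames, dtype=np.int8)
    for i in range(n_frames):
        seq[i] = state
        rate = rate_off if state else rate_on
        if rng.random() < 1.0 - math.exp(-rate * dt_s):
            state = not state
    return seq


def make_cell_movie(
    layout: PoreArrayLayout,
    config: SimConfig,
    n_frames: int = 30,
    high_amplitude: float = 1500.0,
    spike_amplitude: float = 70.0,
    background_rate: float = 2.0,
    low_scale: float = 1.0,
) -> dict:
    """Synthetic bright-field image + two-channel movie + ground truth.

    Channel 1 (cytoplasm marker): covered pores are 'high' (protrusion in
    the well) or 'low' (cell on top only, < 10 % of the high signal);
    a configurable fraction of covered pores switches state as a two-state
    telegraph.  Channel 2 (single-molecule channel): intensity spikes with
    exponential dwell times occur only on high-population pores.  EMCCD
    noise = gain-scaled Poisson + Gaussian read noise.

    ``low_scale`` rescales the low-population amplitude only — it mimics
    oblique (TIRF) illumination, under which the leak-through signal of
    cells lying on top of a pore dims while protrusion signal persists.
    Two calls with the same seed share the pore assignments, so matched
    wide-field/TIRF pairs can be generated by varying only ``low_scale``.
    """
    rng = np.random.default_rng(config.seed)
    pores = layout.pores
    n_pores = len(pores)
    shape = layout.shape
    dt = config.frame_interval_s

    # exact-count assignment: the truth-table fractions equal the configured
    # fractions up to rounding, with the pore identities randomized
    covered = np.zeros(n_pores, bool)
    covered[rng.permutation(n_pores)[: round(config.covered_fraction * n_pores)]] = (
        True
    )
    cov_idx = np.flatnonzero(covered)
    high = np.zeros(n_pores, bool)
    high[rng.permutation(cov_idx)[: round(config.high_fraction * len(cov_idx))]] = (
        True
    )
    population = np.where(~covered, "negative", np.where(high, "high", "low"))
    switching = covered & (rng.random(n_pores) < config.switching_fraction)

    size_scale = (pores["d_nm"].to_numpy() / 220.0) ** 2
    amp_high = high_amplitude * size_scale
    amp = np.where(
        high,
        amp_high,
        np.where(covered, low_scale * config.low_to_high_ratio * amp_high, 0.0),
    )

    # bright-field: pores and markers as dark dips on a bright background
    bf_rate = 400.0 - _render_spots(
        shape,
        pores["x_px"],
        pores["y_px"],
        120.0 * np.sqrt(size_scale),
        config.psf_sigma_px,
    )
    bf_rate -= _render_spots(
        shape,
        layout.markers["x_px"],
        layout.markers["y_px"],
        np.full(len(layout.markers), 250.0),
        1.8 * config.psf_sigma_px,
    )
    brightfield = rng.poisson(np.clip(bf_rate, 0, None)).astype(np.float32)

    states1 = np.empty((n_pores, n_frames), dtype=np.int8)
    for p in range(n_pores):
        if switching[p]:
            states1[p] = _telegraph(
                rng, n_frames, dt, config.switch_rate_per_s, config.switch_rate_per_s
            )
        else:
            states1[p] = 1
    states1[~covered] = 0

    spike_states = np.zeros((n_pores, n_frames), dtype=np.int8)
    for p in range(n_pores):
        if high[p]:
            spike_states[p] = _telegraph(
                rng,
                n_frames,
                dt,
                config.spike_rate_per_s,
                1.0 / config.spike_mean_duration_s,
                start_state=False,
            )

    def camera(rate_img):
        photons = rng.poisson(np.clip(rate_img, 0, None))
        return (
            config.em_gain * photons
            + rng.normal(0.0, config.read_noise, size=rate_img.shape)
        ).astype(np.float32)

    ch1 = np.empty((n_frames,) + shape, dtype=np.float32)
    ch2 = np.empty((n_frames,) + shape, dtype=np.float32)
    for f in range(n_frames):
        a1 = amp * states1[:, f]
        rate1 = background_rate + _render_spots(
            shape, pores["x_px"], pores["y_px"], a1, config.psf_sigma_px
        )
        ch1[f] = camera(rate1)
        a2 = spike_amplitude * spike_states[:, f] * size_scale
        rate2 = background_rate + _render_spots(
            shape, pores["x_px"], pores["y_px"], a2, config.psf_sigma_px
        )
        ch2[f] = camera(rate2)

    truth = pores.copy()
    truth["covered"] = covered
    truth["population"] = population
    truth["switching"] = switching
    truth["amplitude"] = amp
    # a switching pore that never occupied the well during the movie is
    # observationally negative; record the realized population as well
    ever_on = states1.any(axis=1)
    truth["population_realized"] = np.where(ever_on, population, "negative")
    return {
        "brightfield": brightfield,
        "channel1": ch1,
        "channel2": ch2,
        "truth": truth,
        "states_channel1": states1,
        "spike_states": spike_states,
        "layout": layout,
    }


def write_movie(path, stack: np.ndarray) -> None:
    """Write an image stack as a multi-page TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
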