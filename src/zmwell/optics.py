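"""Metal-modified fluorescence calculus for ZMW nanowells.

Combines three ingredients along the pore axis ``z``:

1. the excitation intensity ``I_ex(z)`` (standing wave below the film,
   evanescent decay inside the aperture),
2. the dipole emission powers near the metal, converted to relative
   radiative and loss rates,
3. the fluorophore's intrinsic photophysics,

into the quantum yield ``Phi(z)``, lifetime ``tau(z)``, detection
efficiency ``eta(z)``, detected signal ``S(z) = I_ex * eta * Phi`` and
the signal enhancement ``zeta(z) = S / (I_ex0 * eta0 * Phi0)`` relative
to free diffusion, with the free-space detection efficiency fixed at
``eta0 = 0.5`` (half of an isotropic emitter's far field reaches the
objective in a homogeneous medium).

Axis convention: ``z = 0`` at the glass-side metal surface, the nanowell
at ``-h <= z <= 0``, the aperture at ``0 <= z <= t_m``.  Signal-weighted
averages run from the bottom of the well (``z = -h``) to 200 nm beyond
the reference plane (``z = +200``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import FluorophoreSpec, NanowellGeometry
from .materials import N_GLASS, N_WATER, palladium_index
from .tmm import Layer, solve_stack
from .dipole import mirror_dipole_sample

ETA_FREE_SPACE = 0.5  # far-field fraction reaching the objective, free diffusion
AVERAGING_TOP_NM = 200.0  # upper end of the signal-weighted averaging range


# ---------------------------------------------------------------------------
# cutoff / evanescent theory

def cutoff_wavelength(diameter_nm: float) -> float:
    """Cutoff wavelength ``lambda_c = 1.7 d`` of a circular ZMW aperture.

    Light with (in-medium) wavelength longer than ``lambda_c`` cannot
    propagate through the aperture.
    """
    if diameter_nm < 0:
        raise ValueError("diameter must be >= 0")
    return 1.7 * diameter_nm


def evanescent_decay_length(
    diameter_nm: float, wavelength_nm: float, n_medium: float = N_WATER
) -> float:
    """1/e intensity decay length of the below-cutoff evanescent field, nm.

    First-order waveguide result
    ``Lambda = 1 / (4 pi sqrt(1/lambda_c^2 - 1/lambda_m^2))`` with
    ``lambda_m = lambda / n`` the wavelength in the medium.  Raises in the
    propagating regime ``lambda_m >= lambda_c`` where no finite decay
    length exists.
    """
    lam_c = cutoff_wavelength(diameter_nm)
    lam_m = wavelength_nm / n_medium
    if lam_m <= lam_c:
        raise ValueError(
            f"propagating regime: in-medium wavelength {lam_m:.1f} nm does not "
            f"exceed the cutoff {lam_c:.1f} nm for d = {diameter_nm:.0f} nm; "
            "no finite decay length exists"
        )
    return 1.0 / (4.0 * np.pi * np.sqrt(1.0 / lam_c**2 - 1.0 / lam_m**2))


# ---------------------------------------------------------------------------
# profile containers

@dataclass(frozen=True)
class ExcitationProfile:
    """Relative excitation intensity ``I_ex(z)/I0`` on a z grid (nm)."""

    z_nm: np.ndarray
    intensity: np.ndarray
    mode: str = "widefield"
    wavelength_nm: float = 488.0

    def __post_init__(self) -> None:
        z = np.asarray(self.z_nm, float)
        i = np.asarray(self.intensity, float)
        object.__setattr__(self, "z_nm", z)
        object.__setattr__(self, "intensity", i)
        if z.ndim != 1 or z.size != i.size:
            raise ValueError("z grid and intensity must be 1-D and aligned")
        if np.any(np.diff(z) <= 0):
            raise ValueError("z grid must be strictly increasing")
        if np.any(i < 0):
            raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class DipoleEmissionProfile:
    """Normalized dipole emission powers vs z (all relative to ``P_r0``)."""

    z_nm: np.ndarray
    p_total: np.ndarray  # P_r / P_r0
    p_ff: np.ndarray  # far-field power / P_r0
    p_ff_down: np.ndarray  # far-field power into the detection half-space / P_r0
    orientation: str = "isotropic"

    def __post_init__(self) -> None:
        z = np.asarray(self.z_nm, float)
        pt = np.asarray(self.p_total, float)
        pf = np.asarray(self.p_ff, float)
        pd_ = np.asarray(self.p_ff_down, float)
        for name, arr in (("p_total", pt), ("p_ff", pf), ("p_ff_down", pd_)):
            if arr.shape != z.shape:
                raise ValueError(f"{name} not aligned with z grid")
        object.__setattr__(self, "z_nm", z)
        object.__setattr__(self, "p_total", pt)
        object.__setattr__(self, "p_ff", pf)
        object.__setattr__(self, "p_ff_down", pd_)
        if np.any(np.diff(z) <= 0):
            raise ValueError("z grid must be strictly increasing")
        tol = 1e-9 + 1e-6 * np.abs(pt)
        if np.any(pf > pt + tol):
            raise ValueError("far-field power exceeds total radiated power")
        if np.any(pd_ > pf + tol):
            raise ValueError("downward far-field power exceeds total far field")
        if np.any(pt < 0) or np.any(pf < 0) or np.any(pd_ < 0):
            raise ValueError("powers must be >= 0")


# ---------------------------------------------------------------------------
# elementary operations (Eqs. of the optical calculus)

def relative_rates(profile: DipoleEmissionProfile) -> tuple[np.ndarray, np.ndarray]:
    """Relative radiative and loss rates ``(gamma_r/gamma_r0, gamma_loss/gamma_r0)``.

    The escaping far-field power maps to the radiative rate,
    ``gamma_r/gamma_r0 = P_ff/P_r0``; the absorbed remainder maps to the
    metal loss rate, ``gamma_loss/gamma_r0 = (P_r - P_ff)/P_r0``.
    """
    gr = profile.p_ff.copy()
    gl = profile.p_total - profile.p_ff
    if np.any(gl < -1e-9):
        raise ValueError("invalid profile: P_ff > P_r")
    return gr, np.clip(gl, 0.0, None)


def quantum_yield(gamma_r_rel, gamma_loss_rel, fluor: FluorophoreSpec):
    """Metal-modified quantum yield.

    ``Phi = gr / (gr + gloss + (1 - Phi0)/Phi0)`` with rates normalized to
    the intrinsic radiative rate; reduces to ``Phi0`` in free space
    (``gr = 1``, ``gloss = 0``).
    """
    gr = np.asarray(gamma_r_rel, float)
    gl = np.asarray(gamma_loss_rel, float)
    if np.any(gr < 0) or np.any(gl < 0):
        raise ValueError("relative rates must be >= 0")
    phi0 = fluor.quantum_yield
    return gr / (gr + gl + (1.0 - phi0) / phi0)


def lifetime_from_rates(phi, gamma_r_rel, fluor: FluorophoreSpec):
    """Fluorescence lifetime ``tau = Phi / gamma_r`` in ns.

    With ``gamma_r = gamma_r_rel * Phi0 / tau0`` this equals the inverse
    of the total de-excitation rate.
    """
    gr = np.asarray(gamma_r_rel, float)
    if np.any(gr <= 0):
        raise ValueError("gamma_r_rel must be > 0 for a finite lifetime")
    return np.asarray(phi, float) * fluor.lifetime_ns / (gr * fluor.quantum_yield)


def detection_efficiency(p_ff_down, p_ff_total):
    """Fraction of the far-field emission reaching the detection side."""
    down = np.asarray(p_ff_down, float)
    total = np.asarray(p_ff_total, float)
    if np.any(total <= 0):
        raise ValueError("total far-field power must be > 0")
    if np.any(down < 0) or np.any(down > total * (1 + 1e-12)):
        raise ValueError("need 0 <= P_ff_down <= P_ff_total")
    return np.clip(down / total, 0.0, 1.0)


def detected_signal(i_ex, eta, phi):
    """Detected signal ``S(z) = I_ex(z) * eta(z) * Phi(z)`` (pointwise)."""
    i_ex, eta, phi = (np.asarray(a, float) for a in (i_ex, eta, phi))
    if not i_ex.shape == eta.shape == phi.shape:
        raise ValueError("profiles are not on aligned grids")
    return i_ex * eta * phi


def _trapz_weighted(values, weights, z):
    num = np.trapezoid(values * weights, z)
    den = np.trapezoid(weights, z)
    if den <= 0:
        raise ValueError("weight profile integrates to zero over the range")
    return float(num / den)


# ---------------------------------------------------------------------------
# assembled signal model

@dataclass(frozen=True)
class SignalModel:
    """Axial profiles of the metal-modified fluorescence observables.

    Built by :meth:`from_profiles` from an excitation profile and a dipole
    emission profile on a shared z grid, for a given fluorophore and well
    depth ``h``.
    """

    z_nm: np.ndarray
    phi: np.ndarray
    tau_ns: np.ndarray
    eta: np.ndarray
    signal: np.ndarray
    zeta: np.ndarray
    fluor: FluorophoreSpec
    overmill_depth_nm: float
    eta0: float = ETA_FREE_SPACE
    i_ex0: float = 1.0

    @classmethod
    def from_profiles(
        cls,
        excitation: ExcitationProfile,
        emission: DipoleEmissionProfile,
        fluor: FluorophoreSpec,
        overmill_depth_nm: float,
        eta0: float = ETA_FREE_SPACE,
        i_ex0: float = 1.0,
    ) -> "SignalModel":
        if excitation.z_nm.shape != emission.z_nm.shape or not np.allclose(
            excitation.z_nm, emission.z_nm
        ):
            raise ValueError("excitation and emission profiles on different z grids")
        gr, gl = relative_rates(emission)
        phi = quantum_yield(gr, gl, fluor)
        tau = lifetime_from_rates(phi, gr, fluor)
        eta = detection_efficiency(emission.p_ff_down, emission.p_ff)
        s = detected_signal(excitation.intensity, eta, phi)
        zeta = s / (i_ex0 * eta0 * fluor.quantum_yield)
        return cls(
            z_nm=excitation.z_nm,
            phi=phi,
            tau_ns=tau,
            eta=eta,
            signal=s,
            zeta=zeta,
            fluor=fluor,
            overmill_depth_nm=overmill_depth_nm,
            eta0=eta0,
            i_ex0=i_ex0,
        )

    def _range_mask(self) -> np.ndarray:
        lo, hi = -self.overmill_depth_nm, AVERAGING_TOP_NM
        m = (self.z_nm >= lo - 1e-9) & (self.z_nm <= hi + 1e-9)
        if m.sum() < 2:
            raise ValueError("averaging range contains fewer than 2 grid points")
        return m

    def average_enhancement(self) -> float:
        """Signal-weighted mean enhancement over ``[-h, +200 nm]``."""
        m = self._range_mask()
        return _trapz_weighted(self.zeta[m], self.signal[m], self.z_nm[m])

    def signal_averaged_lifetime(self) -> float:
        """Signal-weighted mean lifetime over ``[-h, +200 nm]``, ns."""
        m = self._range_mask()
        return _trapz_weighted(self.tau_ns[m], self.signal[m], self.z_nm[m])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_nm": self.z_nm,
                "phi": self.phi,
                "tau_ns": self.tau_ns,
                "eta": self.eta,
                "signal": self.signal,
                "zeta": self.zeta,
            }
        )

    def plot(self, ax=None):
        """Quick-look plot of Phi, eta, S and zeta vs z."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.z_nm, self.phi, label=r"$\Phi(z)$")
        ax.plot(self.z_nm, self.eta, label=r"$\eta(z)$")
        ax.plot(self.z_nm, self.signal, label=r"$S(z)$")
        ax.plot(self.z_nm, self.zeta, label=r"$\zeta(z)$")
        ax.set_xlabel("z (nm)")
        ax.legend()
        return ax


def average_enhancement(zeta, signal, z_nm) -> float:
    """Signal-weighted average of an enhancement profile (free function)."""
    zeta = np.asarray(zeta, float)
    signal = np.asarray(signal, float)
    z = np.asarray(z_nm, float)
    if zeta.shape != signal.shape or zeta.shape != z.shape:
        raise ValueError("misaligned profiles")
    return _trapz_weighted(zeta, signal, z)


def signal_averaged_lifetime(tau_ns, signal, z_nm) -> float:
    """Signal-weighted average lifetime (free function)."""
    return _trapz_weighted(
        np.asarray(tau_ns, float), np.asarray(signal, float), np.asarray(z_nm, float)
    )


# ---------------------------------------------------------------------------
# standing-wave excitation

def pd_film_stack(
    wavelength_nm: float,
    metal_thickness_nm: float = 100.0,
    n_medium: float = N_WATER,
    n_backing: float = N_WATER,
) -> list[Layer]:
    """Medium / Pd film / backing stack for the excitation problem.

    The incident medium is the water-filled nanowell below the film; the
    backing is the aqueous reservoir above it.
    """
    n_pd = palladium_index(wavelength_nm)
    return [Layer(n_medium), Layer(n_pd, metal_thickness_nm), Layer(n_backing)]


def standing_wave_profile(
    wavelength_nm: float,
    angle_deg: float = 0.0,
    layers: list[Layer] | None = None,
    z_nm: np.ndarray | None = None,
    pol: str = "s",
) -> ExcitationProfile:
    """Excitation intensity profile below (and through) a layer stack.

    Light is incident from the first layer of ``layers`` (default: water /
    100 nm Pd / water at the given wavelength).  Interference of the
    incident and reflected waves forms a standing wave below the metal;
    at oblique incidence the axial period lengthens because only the
    z-component of the wave vector enters the interference phase, which
    shifts the first intensity maximum away from the surface.

    ``layers="perfect"`` models an ideal mirror at ``z = 0`` in water:
    ``I(z) = 4 sin^2(k z)``, a node at the surface and peaks of exactly
    4x the incident intensity.
    """
    if z_nm is None:
        z_nm = np.arange(-400.0, 200.0 + 1e-9, 1.0)
    z_nm = np.asarray(z_nm, float)
    if isinstance(layers, str):
        if layers != "perfect":
            raise ValueError(f"unknown layer spec {layers!r}")
        n0 = N_WATER
        kz = (
            2.0 * np.pi * n0 / wavelength_nm
        ) * np.cos(np.radians(angle_deg))
        intensity = np.where(z_nm < 0, 4.0 * np.sin(kz * z_nm) ** 2, 0.0)
        return ExcitationProfile(
            z_nm=z_nm,
            intensity=intensity,
            mode="perfect-mirror",
            wavelength_nm=wavelength_nm,
        )
    if layers is None:
        layers = pd_film_stack(wavelength_nm)
    sol = solve_stack(layers, wavelength_nm, angle_deg=angle_deg, pol=pol)
    intensity = sol.intensity(z_nm)
    mode = "widefield" if angle_deg == 0 else f"tirf({angle_deg:g})"
    return ExcitationProfile(
        z_nm=z_nm, intensity=intensity, mode=mode, wavelength_nm=wavelength_nm
    )


# ---------------------------------------------------------------------------
# (d, h) heatmap assembly

def enhancement_heatmap(
    diameters_nm,
    depths_nm,
    fluor: FluorophoreSpec,
    dz_nm: float = 5.0,
) -> pd.DataFrame:
    """Predicted ``zeta_bar`` and signal-averaged ``tau`` over a (d, h) grid.

    Returns a long-format table with columns ``d_nm, h_nm, quantity,
    value`` mirroring the study's heatmap layout.
    """
    from .synthetic import make_optics_profiles  # local import to avoid cycle

    rows = []
    for d in diameters_nm:
        for h in depths_nm:
            geom = NanowellGeometry(diameter=d, overmill_depth=h)
            exc, emi = make_optics_profiles(geom, fluor, dz_nm=dz_nm)
            model = SignalModel.from_profiles(exc, emi, fluor, h)
            rows.append((d, h, "zeta_bar", model.average_enhancement()))
            rows.append((d, h, "tau_ns", model.signal_averaged_lifetime()))
    return pd.DataFrame(rows, columns=["d_nm", "h_nm", "quantity", "value"])
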