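"""Classical dipole emission near a planar reflector.

Semi-analytic stand-in for full-wave simulations of an emitter inside a
ZMW nanowell: the Pd film above the emitter is modelled as a laterally
infinite planar reflector and the emission is computed from the
angular-spectrum representation of a dipole below the plane
(Chance-Prock-Silbey / Drexhage theory).

Outputs are powers normalized to the free-space radiated power
``P_r0``:

* ``p_total``  -- total power dissipated by the dipole, ``P_r/P_r0``
  (equals the total decay-rate enhancement);
* ``p_ff_down`` -- far-field power radiated into the lower (detection)
  half-space;
* ``p_ff_up``  -- far-field power leaking through the film to the upper
  half-space (zero for an opaque reflector);
* ``p_ff = p_ff_down + p_ff_up``.

The difference ``p_total - p_ff`` is absorbed by the metal (quenching).
Orientation averaging for isotropic emission weights parallel dipoles
2/3 and perpendicular dipoles 1/3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .materials import N_WATER
from .tmm import Layer, reflection_coefficient, solve_stack

PERFECT_MIRROR = "perfect"

_ORIENTATIONS = ("parallel", "perpendicular", "isotropic")


def _reflector_layers(reflector, n_medium: float, n_above: float) -> list[Layer] | None:
    """Build the stack seen by an upward-travelling wave, or None for PEC."""
    if isinstance(reflector, str):
        if reflector != PERFECT_MIRROR:
            raise ValueError(f"unknown reflector {reflector!r}")
        return None
    if isinstance(reflector, (int, float, complex)):
        return [Layer(n_medium), Layer(complex(reflector))]
    # (index, thickness_nm) film with n_above backing
    if isinstance(reflector, tuple) and len(reflector) == 2:
        n_f, d_f = reflector
        return [Layer(n_medium), Layer(complex(n_f), float(d_f)), Layer(n_above)]
    raise TypeError("reflector must be 'perfect', a complex index, or (index, d_nm)")


def _pec_rates(x: float) -> tuple[float, float]:
    """Closed-form total rates for a perfect mirror; x = 2 k z."""
    if x < 1e-4:  # series limits: perpendicular -> 2, parallel -> 0
        p_perp = 2.0 - x**2 / 10.0
        p_par = x**2 / 5.0 * 0.25  # leading order x^2/20
        return p_par, p_perp
    s, c = np.sin(x), np.cos(x)
    p_perp = 1.0 + 3.0 * (s / x**3 - c / x**2)
    p_par = 1.0 - 1.5 * (s / x - s / x**3 + c / x**2)
    return p_par, p_perp


@dataclass(frozen=True)
class MirrorDipoleSample:
    """Normalized emission powers for one emitter-mirror distance."""

    z_nm: float
    p_total_parallel: float
    p_total_perpendicular: float
    p_ff_down_parallel: float
    p_ff_down_perpendicular: float
    p_ff_up_parallel: float
    p_ff_up_perpendicular: float

    def p_total(self, orientation: str = "isotropic") -> float:
        return self._avg("p_total", orientation)

    def p_ff_down(self, orientation: str = "isotropic") -> float:
        return self._avg("p_ff_down", orientation)

    def p_ff_up(self, orientation: str = "isotropic") -> float:
        return self._avg("p_ff_up", orientation)

    def p_ff(self, orientation: str = "isotropic") -> float:
        return self.p_ff_down(orientation) + self.p_ff_up(orientation)

    def _avg(self, stem: str, orientation: str) -> float:
        if orientation not in _ORIENTATIONS:
            raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
        par = getattr(self, f"{stem}_parallel")
        perp = getattr(self, f"{stem}_perpendicular")
        if orientation == "parallel":
            return par
        if orientation == "perpendicular":
            return perp
        return (2.0 * par + perp) / 3.0


def mirror_dipole_sample(
    z_nm: float,
    wavelength_nm: float,
    reflector="perfect",
    n_medium: float = N_WATER,
    n_above: float = N_WATER,
) -> MirrorDipoleSample:
    """Emission of a dipole ``z_nm`` below a planar reflector.

    Parameters
    ----------
    z_nm : float
        Emitter-reflector distance (> 0), nm.
    reflector : "perfect" | complex | (complex, float)
        Perfect electric conductor, a semi-infinite medium of the given
        complex index, or a finite film ``(index, thickness_nm)`` backed
        by ``n_above`` (through which far-field leakage is computed).
    """
    if z_nm <= 0:
        raise ValueError("emitter must sit below the reflector (z_nm > 0)")
    k1 = 2.0 * np.pi * n_medium / wavelength_nm
    x = 2.0 * k1 * z_nm

    layers = _reflector_layers(reflector, n_medium, n_above)

    if layers is None:
        p_par, p_perp = _pec_rates(x)

        def rs(u):
            return -1.0 + 0.0j

        def rp(u):
            return 1.0 + 0.0j

        opaque = True
    else:

        def rs(u):
            return reflection_coefficient(layers, wavelength_nm, u * k1, "s")

        def rp(u):
            return reflection_coefficient(layers, wavelength_nm, u * k1, "p")

        # a semi-infinite layer only blocks the upward far field if it
        # absorbs; a transparent half-space transmits into its far field
        opaque = (
            len(layers) == 2 and abs(complex(layers[1].index).imag) > 1e-9
        )

        def sz(u):
            val = np.sqrt(complex(1.0 - u * u))
            return val if val.imag >= 0 else -val

        def integrand_perp(u):
            s = sz(u)
            return np.real(u**3 / s * rp(u) * np.exp(1j * x * s))

        def integrand_par(u):
            s = sz(u)
            return np.real(u / s * (rs(u) - s * s * rp(u)) * np.exp(1j * x * s))

        # split at the branch point u = 1; the evanescent tail decays as
        # exp(-x sqrt(u^2-1))
        u_max = 1.0 + 40.0 / max(x, 1e-3)
        args = dict(limit=400, epsabs=1e-10, epsrel=1e-9)
        i_perp = (
            quad(integrand_perp, 0.0, 1.0, **args)[0]
            + quad(integrand_perp, 1.0, u_max, **args)[0]
        )
        i_par = (
            quad(integrand_par, 0.0, 1.0, **args)[0]
            + quad(integrand_par, 1.0, u_max, **args)[0]
        )
        p_perp = 1.0 + 1.5 * i_perp
        p_par = 1.0 + 0.75 * i_par

    # far field into the lower (detection) half-space
    def ff_down_perp(ct):
        st2 = 1.0 - ct * ct
        u = np.sqrt(st2)
        return 0.75 * st2 * np.abs(1.0 + rp(u) * np.exp(1j * x * ct)) ** 2

    def ff_down_par(ct):
        st2 = 1.0 - ct * ct
        u = np.sqrt(st2)
        ph = np.exp(1j * x * ct)
        return 0.375 * (
            np.abs(1.0 + rs(u) * ph) ** 2 + ct * ct * np.abs(1.0 - rp(u) * ph) ** 2
        )

    args = dict(limit=200, epsabs=1e-11, epsrel=1e-10)
    d_perp = quad(ff_down_perp, 0.0, 1.0, **args)[0]
    d_par = quad(ff_down_par, 0.0, 1.0, **args)[0]

    # far-field leakage through a finite film
    if layers is None or opaque:
        u_perp = u_par = 0.0
    else:

        def t_power(u, pol):
            sol = solve_stack(layers, wavelength_nm, pol=pol, kpar=u * k1)
            return sol.T

        def ff_up_perp(ct):
            st2 = 1.0 - ct * ct
            return 0.75 * st2 * t_power(np.sqrt(st2), "p")

        def ff_up_par(ct):
            st2 = 1.0 - ct * ct
            return 0.375 * (
                t_power(np.sqrt(st2), "s") + ct * ct * t_power(np.sqrt(st2), "p")
            )

        u_perp = quad(ff_up_perp, 0.0, 1.0, **args)[0]
        u_par = quad(ff_up_par, 0.0, 1.0, **args)[0]

    return MirrorDipoleSample(
        z_nm=z_nm,
        p_total_parallel=float(p_par),
        p_total_perpendicular=float(p_perp),
        p_ff_down_parallel=float(d_par),
        p_ff_down_perpendicular=float(d_perp),
        p_ff_up_parallel=float(u_par),
        p_ff_up_perpendicular=float(u_perp),
    )
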