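"""One-dimensional transfer-matrix optics for planar layer stacks.

Used for the standing-wave excitation profile below the Pd film and for
the Fresnel reflection/transmission coefficients that enter the
dipole-above-mirror emission model.

Conventions
-----------
* Light is incident from the first (semi-infinite) layer, propagating
  toward positive ``z``; the first interface sits at ``z = 0``.
* ``pol`` is ``"s"`` (TE) or ``"p"`` (TM).  Internally both are solved as
  a scalar Helmholtz problem: the s-field is ``E_y``, the p-field is
  ``H_y`` with the interface admittance ``kz/eps``.
* ``kz`` branches are taken with ``Im(kz) >= 0`` so evanescent waves decay
  into each half-space; arbitrary real ``kpar`` (including beyond-light-line
  values needed by the dipole model) is supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Layer:
    """A homogeneous layer: complex refractive index, thickness in nm.

    ``thickness_nm=None`` marks a semi-infinite medium (first/last layer).
    """

    index: complex
    thickness_nm: float | None = None

    def __post_init__(self) -> None:
        n = complex(self.index)
        if n.real <= 0:
            raise ValueError(f"nonphysical refractive index {n} (Re <= 0)")
        if self.thickness_nm is not None and self.thickness_nm <= 0:
            raise ValueError("layer thickness must be > 0")


def _kz(n: complex, k0: float, kpar: float) -> complex:
    kz = np.sqrt(complex((n * k0) ** 2 - kpar**2))
    if kz.imag < 0:
        kz = -kz
    # lossless propagating wave: enforce forward direction
    if abs(kz.imag) < 1e-12 * abs(kz.real) and kz.real < 0:
        kz = -kz
    return kz


def _admittances(layers: list[Layer], k0: float, kpar: float, pol: str):
    ns = [complex(l.index) for l in layers]
    kzs = np.array([_kz(n, k0, kpar) for n in ns])
    if pol == "s":
        q = kzs.copy()
        w = np.ones(len(ns), dtype=complex)  # flux weight
    elif pol == "p":
        eps = np.array([n**2 for n in ns])
        q = kzs / eps
        w = 1.0 / eps
    else:
        raise ValueError("pol must be 's' or 'p'")
    return kzs, q, w


def reflection_coefficient(
    layers: list[Layer], wavelength_nm: float, kpar: float, pol: str
) -> complex:
    """Amplitude reflection of the stack seen from the first layer.

    Recursive Airy summation; valid for any real ``kpar >= 0`` including
    the evanescent region ``kpar > n0*k0``.  For p polarization the
    convention is the ``H``-field one, for which a perfect mirror gives
    ``r_p -> +1`` (and ``r_s -> -1``).
    """
    k0 = 2.0 * np.pi / wavelength_nm
    kzs, q, _ = _admittances(layers, k0, kpar, pol)
    return _interface_reflections(layers, kzs, q)[0]


def _interface_reflections(layers, kzs, q) -> np.ndarray:
    """R[j]: reflection at interface j (layers j | j+1) seen from layer j,
    including everything below.  Airy recursion from the exit medium up;
    numerically stable for arbitrarily opaque layers (the round-trip
    factor underflows to 0)."""
    n_int = len(layers) - 1
    R = np.zeros(n_int, dtype=complex)
    gamma = 0.0 + 0.0j
    for j in range(n_int - 1, -1, -1):
        rho = (q[j] - q[j + 1]) / (q[j] + q[j + 1])
        d = layers[j + 1].thickness_nm
        phase = gamma * np.exp(2j * kzs[j + 1] * d) if d is not None else 0.0
        gamma = (rho + phase) / (1.0 + rho * phase)
        R[j] = gamma
    return R


@dataclass
class TmmSolution:
    """Field solution of a stack at one wavelength / in-plane momentum."""

    layers: list[Layer]
    wavelength_nm: float
    kpar: float
    pol: str
    r: complex
    t: complex
    R: float
    T: float
    layer_absorption: np.ndarray  # absorbed fraction per layer
    _a: np.ndarray  # forward amplitudes at each layer entry
    _b: np.ndarray  # backward amplitudes at each layer entry
    _kzs: np.ndarray
    _zb: np.ndarray  # interface z positions (first interface at 0)

    @property
    def A(self) -> float:
        return float(self.layer_absorption.sum())

    def field(self, z: np.ndarray) -> np.ndarray:
        """Complex scalar field (E_y for s, H_y for p) at positions ``z``."""
        z = np.asarray(z, dtype=float)
        out = np.empty(z.shape, dtype=complex)
        idx = np.searchsorted(self._zb, z, side="right")
        for j in range(len(self.layers)):
            m = idx == j
            if not m.any():
                continue
            z0 = 0.0 if j == 0 else self._zb[j - 1]
            zeta = z[m] - z0
            kz = self._kzs[j]
            out[m] = self._a[j] * np.exp(1j * kz * zeta)
            if self._b[j] != 0:  # avoid 0 * overflow in opaque layers
                out[m] += self._b[j] * np.exp(-1j * kz * zeta)
        return out

    def intensity(self, z: np.ndarray) -> np.ndarray:
        """|E|^2 normalized to the incident intensity.

        For s polarization this is ``|E_y|^2``; for p the two transverse
        electric-field components are reconstructed from ``H_y``.
        """
        z = np.asarray(z, dtype=float)
        if self.pol == "s":
            return np.abs(self.field(z)) ** 2
        # p: E_x ~ (i/k0 eps) dH/dz, E_z ~ -(kpar/k0 eps) H
        k0 = 2.0 * np.pi / self.wavelength_nm
        out = np.empty(z.shape, dtype=float)
        idx = np.searchsorted(self._zb, z, side="right")
        for j in range(len(self.layers)):
            m = idx == j
            if not m.any():
                continue
            z0 = 0.0 if j == 0 else self._zb[j - 1]
            zeta = z[m] - z0
            kz = self._kzs[j]
            eps = complex(self.layers[j].index) ** 2
            up = self._a[j] * np.exp(1j * kz * zeta)
            dn = (
                self._b[j] * np.exp(-1j * kz * zeta)
                if self._b[j] != 0
                else np.zeros_like(up)
            )
            ex = (kz / (k0 * eps)) * (up - dn)
            ez = (self.kpar / (k0 * eps)) * (up + dn)
            out[m] = np.abs(ex) ** 2 + np.abs(ez) ** 2
        n0 = complex(self.layers[0].index)
        inc = (abs(self._kzs[0]) ** 2 + self.kpar**2) / (k0 * abs(n0) ** 2) ** 2
        return out / inc


def solve_stack(
    layers: list[Layer],
    wavelength_nm: float,
    angle_deg: float = 0.0,
    pol: str = "s",
    kpar: float | None = None,
) -> TmmSolution:
    """Solve the full field problem for a stack at one incidence condition.

    ``angle_deg`` is measured in the (lossless) incident medium; passing
    ``kpar`` directly overrides it.
    """
    if len(layers) < 2:
        raise ValueError("need at least incident and exit media")
    if layers[0].thickness_nm is not None or layers[-1].thickness_nm is not None:
        raise ValueError("first and last layers must be semi-infinite")
    k0 = 2.0 * np.pi / wavelength_nm
    n0 = complex(layers[0].index)
    if kpar is None:
        kpar = float(n0.real * k0 * np.sin(np.radians(angle_deg)))
    kzs, q, w = _admittances(layers, k0, kpar, pol)

    r_int = _interface_reflections(layers, kzs, q)
    r = r_int[0]
    n_layers = len(layers)
    a = np.empty(n_layers, dtype=complex)  # forward amplitude at layer entry
    b = np.empty(n_layers, dtype=complex)  # backward amplitude at layer entry
    a[0], b[0] = 1.0, r
    zb = []
    zpos = 0.0
    # stable downward recursion: amplitudes only ever decay through layers
    for j in range(n_layers - 1):
        d = layers[j].thickness_nm
        e = 1.0 + 0.0j if j == 0 else np.exp(1j * kzs[j] * d)
        if j > 0:
            zpos += d
        zb.append(zpos)
        a_if = a[j] * e  # forward amplitude at interface j
        if j + 1 < n_layers - 1:
            e_next = np.exp(1j * kzs[j + 1] * layers[j + 1].thickness_nm)
            kappa = r_int[j + 1] * e_next**2
        else:
            kappa = 0.0
        a[j + 1] = a_if * (1.0 + r_int[j]) / (1.0 + kappa)
        b[j + 1] = a[j + 1] * kappa
    t = a[-1]

    def flux_entry(j: int) -> float:
        psi = a[j] + b[j]
        dpsi = 1j * kzs[j] * (a[j] - b[j])
        return float(np.imag(np.conj(psi) * dpsi * w[j]))

    def flux_exit(j: int) -> float:
        d = layers[j].thickness_nm
        a_if = a[j] * np.exp(1j * kzs[j] * d)
        psi = a_if * (1.0 + r_int[j])
        dpsi = 1j * kzs[j] * a_if * (1.0 - r_int[j])
        return float(np.imag(np.conj(psi) * dpsi * w[j]))

    f_inc = float(np.real(kzs[0] * w[0]))  # incident-wave flux, |a0|=1
    R = abs(r) ** 2
    T = flux_entry(n_layers - 1) / f_inc
    absorbed = np.zeros(n_layers)
    for j in range(1, n_layers - 1):
        absorbed[j] = (flux_entry(j) - flux_exit(j)) / f_inc
    return TmmSolution(
        layers=list(layers),
        wavelength_nm=wavelength_nm,
        kpar=kpar,
        pol=pol,
        r=r,
        t=t,
        R=R,
        T=T,
        layer_absorption=absorbed,
        _a=a,
        _b=b,
        _kzs=kzs,
        _zb=np.array(zb),
    )
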