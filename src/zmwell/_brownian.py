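"""Numba kernel for confined Brownian dynamics in a nanowell + reservoir.

Domain (package z convention, nm):

* pore region  : cylinder r <= R, -h <= z < t_m  (nanowell + aperture)
* reservoir    : square slab |x|,|y| <= L/2, t_m <= z <= z_top

Boundary handling uses Metropolis-style move rejection: a proposed step
ending outside the domain is rejected and the particle keeps its
position for that step.  With symmetric Gaussian proposals this
satisfies detailed balance with respect to the uniform measure, so the
equilibrium density is exactly uniform over the domain (the
grand-canonical occupancy contract) at the cost of slightly slowed
dynamics within one step length of a wall.  The only exception is the
reservoir top, where particles are re-injected at a uniform lateral
position with reflected z, which preserves lateral uniformity and
models exchange with an infinite bath.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def brownian_kernel(
    seed: int,
    n_bins: int,
    steps_per_bin: int,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    sigma: float,
    radius: float,
    depth: float,
    t_metal: float,
    lateral: float,
    z_top: float,
    z_out: np.ndarray,
) -> None:
    np.random.seed(seed)
    n = x.shape[0]
    half = 0.5 * lateral
    r2max = radius * radius
    for b in range(n_bins):
        for i in range(n):
            z_out[b, i] = z[i]
        for _ in range(steps_per_bin):
            step = np.random.normal(0.0, sigma, 3 * n)
            for i in range(n):
                xn = x[i] + step[3 * i]
                yn = y[i] + step[3 * i + 1]
                zn = z[i] + step[3 * i + 2]
                if zn > z_top:  # bath exchange at the reservoir top
                    zn = 2.0 * z_top - zn
                    xn = (np.random.random() - 0.5) * lateral
                    yn = (np.random.random() - 0.5) * lateral
                if zn < t_metal:
                    # pore region: must be inside the cylinder
                    if zn < -depth or xn * xn + yn * yn > r2max:
                        continue  # reject
                else:
                    # reservoir slab: must be inside the lateral box
                    if xn < -half or xn > half or yn < -half or yn > half:
                        continue  # reject
                x[i] = xn
                y[i] = yn
                z[i] = zn
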