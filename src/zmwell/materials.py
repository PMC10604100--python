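"""Optical constants for the layer materials.

The palladium table is a coarse visible-range tabulation of the complex
refractive index of evaporated Pd films, representative of the classic
transition-metal dataset of Johnson & Christy (1974), interpolated
log-linearly in wavelength.  The table is a configuration item: pass your
own ``(wavelength_nm, n, k)`` array to :func:`palladium_index` if a
different source is preferred.
"""

from __future__ import annotations

import numpy as np

# wavelength (nm), n, k for evaporated palladium
PD_NK_TABLE = np.array(
    [
        # lam_nm   n      k
        [300.0, 1.21, 2.36],
        [350.0, 1.37, 2.84],
        [400.0, 1.51, 3.21],
        [450.0, 1.64, 3.63],
        [500.0, 1.75, 4.02],
        [550.0, 1.84, 4.37],
        [600.0, 1.96, 4.74],
        [650.0, 2.09, 5.10],
        [700.0, 2.24, 5.46],
        [800.0, 2.59, 6.21],
        [900.0, 3.00, 6.99],
        [1000.0, 3.45, 7.79],
    ]
)

N_WATER = 1.33
N_GLASS = 1.52


def palladium_index(wavelength_nm: float, table: np.ndarray | None = None) -> complex:
    """Complex refractive index n + ik of Pd at ``wavelength_nm``.

    Interpolates ``log(n)`` and ``log(k)`` linearly in ``log(wavelength)``,
    which tracks the smooth dispersion of Pd in the visible better than
    linear interpolation on sparse tables.
    """
    tab = PD_NK_TABLE if table is None else np.asarray(table, dtype=float)
    lam, n, k = tab[:, 0], tab[:, 1], tab[:, 2]
    if not lam[0] <= wavelength_nm <= lam[-1]:
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside tabulated range "
            f"[{lam[0]}, {lam[-1]}] nm"
        )
    x = np.log(wavelength_nm)
    n_i = np.exp(np.interp(x, np.log(lam), np.log(n)))
    k_i = np.exp(np.interp(x, np.log(lam), np.log(k)))
    return complex(n_i, k_i)
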