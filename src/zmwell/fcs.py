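"""Fluorescence correlation spectroscopy on binned photon traces.

The autocorrelation of intensity fluctuations,
``G(t_c) = <dI(t) dI(t+t_c)> / <I>^2``, decays from an amplitude
``G(0+) = 1/N`` (N = mean number of molecules in the observation
volume) on the time scale of the diffusion time ``t_D``.  Curves are
fitted with the standard 3-D diffusion model

``G(t_c) = (1/N) (1 + t_c/t_D)^-1 (1 + t_c/(p^2 t_D))^-1/2``

with the axial-elongation factor fixed at ``p = 3.4``.  For a nanowell
this is an *effective-parameter* description — the fitted N and t_D
summarize amplitude and decay time, they make no geometric claim.

Derived quantities: molecular brightness ``eps = <I>/N`` (counts/ms per
molecule), effective volume ``V_FCS = N/(N_A c)``, and the signal
enhancement factor ``eps_ZMW / eps_free``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.constants import N_A

FCS_P_FACTOR = 3.4


@dataclass(frozen=True)
class PhotonTrace:
    """Binned photon counts from one detection channel."""

    bin_width_ms: float
    counts: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1:
            raise ValueError("counts must be 1-D")
        if np.any(c < 0):
            raise ValueError("counts must be >= 0")
        object.__setattr__(self, "counts", c)
        if self.bin_width_ms <= 0:
            raise ValueError("bin_width_ms must be > 0")

    @property
    def duration_s(self) -> float:
        return len(self.counts) * self.bin_width_ms / 1000.0

    @property
    def mean_rate_cpms(self) -> float:
        """Mean intensity <I> in counts per ms."""
        return float(self.counts.mean() / self.bin_width_ms)

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(len(self.counts)) * self.bin_width_ms
        return pd.DataFrame({"time_ms": t, "counts": self.counts})


@dataclass(frozen=True)
class CorrelationCurve:
    """Fluctuation autocorrelation on a quasi-logarithmic lag grid.

    Normalization: ``G -> 0`` at long lags (the mean is divided out).
    ``sem`` carries optional per-lag standard errors from block averaging.
    """

    lag_ms: np.ndarray
    g: np.ndarray
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        lag = np.asarray(self.lag_ms, float)
        g = np.asarray(self.g, float)
        object.__setattr__(self, "lag_ms", lag)
        object.__setattr__(self, "g", g)
        if np.any(np.diff(lag) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not (np.all(np.isfinite(lag)) and np.all(np.isfinite(g))):
            raise ValueError("non-finite correlation values")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"lag_ms": self.lag_ms, "g": self.g})
        if self.sem is not None:
            df["sem"] = self.sem
        return df


def _correlate_single(counts: np.ndarray, m: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Multi-tau autocorrelation of one (sub-)trace, symmetric normalization.

    Level 0 evaluates lags ``1..2m`` at the native bin width; every further
    level halves the time resolution (bin pairs summed) and evaluates lags
    ``m+1..2m`` in the coarser units.
    """
    x = counts.astype(float)
    lags_bins: list[float] = []
    gs: list[float] = []
    level = 0
    scale = 1.0
    while True:
        n = len(x)
        j_lo, j_hi = (1, 2 * m) if level == 0 else (m + 1, 2 * m)
        if n < j_hi + 2:
            break
        for j in range(j_lo, j_hi + 1):
            left = x[: n - j]
            right = x[j:]
            ml, mr = left.mean(), right.mean()
            if ml <= 0 or mr <= 0:
                raise ValueError("zero-mean segment: normalization undefined")
            gs.append(float(np.dot(left, right) / len(left) / (ml * mr) - 1.0))
            lags_bins.append(j * scale)
        if n // 2 < 2 * m + 2:
            break
        x = x[: 2 * (n // 2)].reshape(-1, 2).sum(axis=1)
        scale *= 2.0
        level += 1
    return np.array(lags_bins), np.array(gs)


def autocorrelate(
    trace: PhotonTrace,
    m: int = 16,
    n_blocks: int = 0,
    max_lag_ms: float | None = None,
) -> CorrelationCurve:
    """Multi-tau autocorrelation ``G(t_c)`` of a photon trace.

    ``n_blocks > 1`` additionally splits the trace into contiguous blocks,
    correlates each, and attaches the standard error of the block mean as
    per-lag uncertainty (used for weighted fitting).
    """
    if trace.counts.sum() == 0:
        raise ValueError("empty trace: autocorrelation undefined")
    lags_bins, g = _correlate_single(trace.counts, m=m)
    lag_ms = lags_bins * trace.bin_width_ms
    sem = None
    if n_blocks > 1:
        nb = len(trace.counts) // n_blocks
        segs = []
        for b in range(n_blocks):
            seg = trace.counts[b * nb : (b + 1) * nb]
            lb, gb = _correlate_single(seg, m=m)
            segs.append((lb, gb))
        k = min(len(gb) for _, gb in segs)
        gmat = np.stack([gb[:k] for _, gb in segs])
        sem_full = gmat.std(axis=0, ddof=1) / np.sqrt(n_blocks)
        sem = np.full(len(g), np.nan)
        sem[:k] = sem_full
    if max_lag_ms is not None:
        keep = lag_ms <= max_lag_ms
        lag_ms, g = lag_ms[keep], g[keep]
        if sem is not None:
            sem = sem[keep]
    return CorrelationCurve(lag_ms=lag_ms, g=g, sem=sem)


def fcs_model_3d(lag_ms, n_particles, t_d_ms, p: float = FCS_P_FACTOR):
    """Standard 3-D diffusion FCS model with fixed axial ratio ``p``."""
    tc = np.asarray(lag_ms, float)
    return (
        1.0
        / n_particles
        / (1.0 + tc / t_d_ms)
        / np.sqrt(1.0 + tc / (p**2 * t_d_ms))
    )


class FcsFitError(RuntimeError):
    pass


class FcsModel:
    """3-D diffusion model for an FCS curve (statsmodels-style).

    Parameters
    ----------
    curve : CorrelationCurve
        Must span the decay with at least 10 lags.
    trace : PhotonTrace, optional
        Attaches the mean intensity so the results can report molecular
        brightness.
    p : float
        Axial elongation factor, fixed (never fitted); default 3.4.
    """

    def __init__(
        self,
        curve: CorrelationCurve,
        trace: PhotonTrace | None = None,
        p: float = FCS_P_FACTOR,
    ) -> None:
        if len(curve.lag_ms) < 10:
            raise ValueError("need at least 10 lags spanning the decay")
        self.curve = curve
        self.trace = trace
        self.p = p

    def fit(self, n0: float | None = None, td0: float | None = None) -> "FcsResults":
        """Weighted least squares fit; returns an :class:`FcsResults`."""
        import lmfit

        g = self.curve.g
        lag = self.curve.lag_ms
        amp0 = max(np.median(g[: max(3, len(g) // 20)]), 1e-6)
        if n0 is None:
            n0 = 1.0 / amp0
        if td0 is None:
            half = amp0 / 2.0
            below = np.nonzero(g < half)[0]
            td0 = lag[below[0]] if len(below) else lag[len(lag) // 2]
        weights = None
        if self.curve.sem is not None:
            s = self.curve.sem
            good = np.isfinite(s) & (s > 0)
            if good.sum() > len(s) // 2:
                floor = np.nanmedian(s[good]) * 1e-3
                weights = 1.0 / np.clip(np.where(good, s, np.nan), floor, None)
                weights = np.where(np.isfinite(weights), weights, 0.0)

        model = lmfit.Model(
            lambda x, n_particles, t_d_ms: fcs_model_3d(
                x, n_particles, t_d_ms, self.p
            )
        )
        params = model.make_params(
            n_particles=dict(value=n0, min=1e-6),
            t_d_ms=dict(value=max(td0, 1e-6), min=1e-9),
        )
        out = model.fit(g, params, x=lag, weights=weights)

        n_fit = out.params["n_particles"].value
        td_fit = out.params["t_d_ms"].value
        decaying = fcs_model_3d(lag[0], n_fit, td_fit, self.p) > 2.0 * fcs_model_3d(
            lag[-1], n_fit, td_fit, self.p
        )
        success = bool(out.success) and decaying
        return FcsResults(
            model=self,
            n_particles=float(n_fit),
            t_d_ms=float(td_fit),
            n_stderr=out.params["n_particles"].stderr,
            t_d_stderr=out.params["t_d_ms"].stderr,
            covar=out.covar,
            residual_norm=float(np.sqrt(np.mean(out.residual**2))),
            success=success,
            lmfit_result=out,
        )


@dataclass
class FcsResults:
    """Fitted FCS parameters and derived per-molecule quantities."""

    model: FcsModel
    n_particles: float
    t_d_ms: float
    n_stderr: float | None
    t_d_stderr: float | None
    covar: np.ndarray | None
    residual_norm: float
    success: bool
    lmfit_result: object = field(repr=False, default=None)

    @property
    def amplitude(self) -> float:
        """Model amplitude ``G(0) = 1/N`` (never read from the zero-lag bin)."""
        return 1.0 / self.n_particles

    def brightness_cpms(self, trace: PhotonTrace | None = None) -> float:
        """Molecular brightness ``eps = <I>/N`` in counts/ms per molecule."""
        tr = trace if trace is not None else self.model.trace
        if tr is None:
            raise ValueError("no photon trace attached")
        return tr.mean_rate_cpms / self.n_particles

    def fcs_volume_liters(self, concentration_molar: float) -> float:
        """Effective volume ``V_FCS = N / (N_A c)`` in liters."""
        if concentration_molar <= 0:
            raise ValueError("concentration must be > 0")
        return self.n_particles / (N_A * concentration_molar)

    def fitted_curve(self) -> np.ndarray:
        return fcs_model_3d(
            self.model.curve.lag_ms, self.n_particles, self.t_d_ms, self.model.p
        )

    def summary(self) -> str:
        lines = [
            "FCS 3-D diffusion fit (p = %.2f fixed)" % self.model.p,
            "-" * 44,
            f"N (particles)   : {self.n_particles:.4g}"
            + (f" +/- {self.n_stderr:.2g}" if self.n_stderr else ""),
            f"t_D (ms)        : {self.t_d_ms:.4g}"
            + (f" +/- {self.t_d_stderr:.2g}" if self.t_d_stderr else ""),
            f"G(0) amplitude  : {self.amplitude:.4g}",
            f"residual norm   : {self.residual_norm:.3g}",
            f"converged       : {self.success}",
        ]
        if self.model.trace is not None:
            lines.append(f"brightness eps  : {self.brightness_cpms():.4g} counts/ms")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        ax.semilogx(c.lag_ms, c.g, ".", label="data")
        ax.semilogx(c.lag_ms, self.fitted_curve(), "-", label="fit")
        ax.set_xlabel(r"$t_c$ (ms)")
        ax.set_ylabel(r"$G(t_c)$")
        ax.legend()
        return ax


def fit_fcs(
    curve: CorrelationCurve,
    trace: PhotonTrace | None = None,
    p: float = FCS_P_FACTOR,
) -> FcsResults:
    """Convenience wrapper: build an :class:`FcsModel` and fit it."""
    return FcsModel(curve, trace=trace, p=p).fit()


def brightness_volume(
    results: FcsResults, trace: PhotonTrace, concentration_molar: float
) -> tuple[float, float]:
    """Molecular brightness (counts/ms) and effective volume (liters)."""
    return (
        results.brightness_cpms(trace),
        results.fcs_volume_liters(concentration_molar),
    )


def enhancement_factor(eps_zmw: float, eps_free: float) -> float:
    """Signal enhancement: counts per molecule in the ZMW vs free diffusion."""
    if eps_free <= 0:
        raise ValueError("free-diffusion brightness must be > 0")
    return eps_zmw / eps_free


@dataclass(frozen=True)
class ScalingFit:
    """Power-law / affine scaling of particle number with pore size."""

    d_exponent: float
    d_exponent_ci: tuple[float, float]
    h_slope: float
    h_slope_ci: tuple[float, float]
    h_intercept: float
    details: pd.DataFrame


def scaling_analysis(table: pd.DataFrame) -> ScalingFit:
    """Scaling of N with diameter (log-log slope) and depth (linear slope).

    ``table`` columns: ``d_nm``, ``h_nm``, ``n`` (fitted or simulated mean
    particle number).  For exact cylinders N ~ d^2 at fixed h and N is
    affine in h with an intercept set by the aperture volume.
    """
    req = {"d_nm", "h_nm", "n"}
    if not req.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(req)}")
    rows = []
    # log-log in d at fixed h
    d_fits = []
    for h, grp in table.groupby("h_nm"):
        if grp["d_nm"].nunique() < 3:
            continue
        res = stats.linregress(np.log(grp["d_nm"]), np.log(grp["n"]))
        ci = stats.t.ppf(0.975, len(grp) - 2) * res.stderr
        d_fits.append((res.slope, ci))
        rows.append(("d_exponent", h, res.slope, ci))
    # linear in h at fixed d
    h_fits = []
    for d, grp in table.groupby("d_nm"):
        if grp["h_nm"].nunique() < 3:
            continue
        res = stats.linregress(grp["h_nm"], grp["n"])
        ci = stats.t.ppf(0.975, len(grp) - 2) * res.stderr
        h_fits.append((res.slope, ci, res.intercept))
        rows.append(("h_slope", d, res.slope, ci))
    if not d_fits or not h_fits:
        raise ValueError("degenerate grid: need >= 3 points per axis")
    d_exp = float(np.mean([s for s, _ in d_fits]))
    d_ci = float(np.mean([c for _, c in d_fits]))
    h_slope = float(np.mean([s for s, _, _ in h_fits]))
    h_ci = float(np.mean([c for _, c, _ in h_fits]))
    h_int = float(np.mean([i for _, _, i in h_fits]))
    details = pd.DataFrame(rows, columns=["quantity", "fixed_value", "slope", "ci95"])
    return ScalingFit(
        d_exponent=d_exp,
        d_exponent_ci=(d_exp - d_ci, d_exp + d_ci),
        h_slope=h_slope,
        h_slope_ci=(h_slope - h_ci, h_slope + h_ci),
        h_intercept=h_int,
        details=details,
    )
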