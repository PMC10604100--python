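"""Pore-array image analysis: localization, traces, classification.

The analysis chain mirrors a live-cell nanowell experiment: pores are
located on a bright-field image by registering the declared array layout
to the image, per-pore intensity traces are extracted from each
fluorescence frame as the mean over a 7x7 pixel window minus the local
background from the window's outer edge pixels, and traces are
classified against a no-cell control threshold into negative / low /
high populations with a stable / switching label.

Pixel convention: 0-based indices, pixel centers at integer coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import PoreArrayLayout

WINDOW = 7  # pore intensity window (px); background ring = its outer edge


class RegistrationError(RuntimeError):
    pass


def _render_template(layout: PoreArrayLayout, sigma_px: float = 1.5) -> np.ndarray:
    """Dark-spot template of the layout (pores + markers) for registration."""
    img = np.zeros(layout.shape)
    yy = np.arange(layout.shape[0])[:, None]
    xx = np.arange(layout.shape[1])[None, :]
    pts = pd.concat(
        [layout.pores[["x_px", "y_px"]], layout.markers[["x_px", "y_px"]]],
        ignore_index=True,
    )
    for _, p in pts.iterrows():
        img += np.exp(
            -((xx - p.x_px) ** 2 + (yy - p.y_px) ** 2) / (2 * sigma_px**2)
        )
    return img


def detect_pores(
    brightfield: np.ndarray,
    layout: PoreArrayLayout,
    refine_radius_px: int = 3,
    min_anchors: int = 3,
) -> pd.DataFrame:
    """Locate every layout pore on a bright-field image.

    The declared grid (anchored by the marker holes) is registered to the
    image by phase correlation against a rendered template; each pore
    center is then refined to sub-pixel precision by an intensity
    centroid of the local dip.  Returns the pore table with ``x_px``,
    ``y_px`` replaced by the detected centers and a ``missing`` flag.
    """
    from skimage.registration import phase_cross_correlation

    img = np.asarray(brightfield, float)
    if img.std() == 0:
        raise RegistrationError("blank image: no pores detected")
    if len(layout.markers) < min_anchors:
        raise RegistrationError(
            f"need at least {min_anchors} marker anchors, "
            f"got {len(layout.markers)}"
        )
    template = _render_template(layout)
    inv = img.max() - img  # pores are dark on bright metal
    shift, error, _ = phase_cross_correlation(
        inv, template, upsample_factor=10, normalization=None
    )
    dy, dx = float(shift[0]), float(shift[1])

    out = layout.pores.copy()
    xs, ys, missing = [], [], []
    r = refine_radius_px
    for _, p in layout.pores.iterrows():
        x0, y0 = p.x_px + dx, p.y_px + dy
        ix, iy = int(round(x0)), int(round(y0))
        if not (r <= ix < img.shape[1] - r and r <= iy < img.shape[0] - r):
            xs.append(x0)
            ys.append(y0)
            missing.append(True)
            continue
        win = inv[iy - r : iy + r + 1, ix - r : ix + r + 1]
        w = win - win.min()
        tot = w.sum()
        if tot <= 0:
            xs.append(x0)
            ys.append(y0)
            missing.append(True)
            continue
        gy, gx = np.indices(w.shape)
        xs.append(ix - r + float((gx * w).sum() / tot))
        ys.append(iy - r + float((gy * w).sum() / tot))
        missing.append(False)
    out["x_px"] = xs
    out["y_px"] = ys
    out["missing"] = missing
    return out


@dataclass(frozen=True)
class PoreTrace:
    """Background-subtracted intensity time series of one pore."""

    pore_id: int
    d_nm: float
    h_nm: float
    times_s: np.ndarray
    values: np.ndarray
    channel: str = ""

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def extract_pore_traces(
    movie: np.ndarray,
    centers: pd.DataFrame,
    frame_interval_s: float = 1.0,
    channel: str = "",
) -> list[PoreTrace]:
    """Per-pore traces: mean over 7x7 px minus the outer-edge-pixel mean.

    The background for each pore is the mean of the 24 pixels forming the
    outer one-pixel ring of its 7x7 window, so traces are exactly
    invariant to global additive offsets.  Pores within 3 px of the image
    border are excluded with a warning.
    """
    movie = np.asarray(movie, float)
    if movie.ndim != 3:
        raise ValueError("movie must be (frames, y, x)")
    half = WINDOW // 2
    n_frames, ny, nx = movie.shape
    times = np.arange(n_frames) * frame_interval_s
    ring = np.ones((WINDOW, WINDOW), bool)
    ring[1:-1, 1:-1] = False

    traces: list[PoreTrace] = []
    for _, p in centers.iterrows():
        ix, iy = int(round(p.x_px)), int(round(p.y_px))
        if not (half <= ix < nx - half and half <= iy < ny - half):
            warnings.warn(
                f"pore {int(p.pore_id)} within {half} px of the border; excluded",
                stacklevel=2,
            )
            continue
        win = movie[:, iy - half : iy + half + 1, ix - half : ix + half + 1]
        inner_mean = win.mean(axis=(1, 2))
        bg = win[:, ring].mean(axis=1)
        traces.append(
            PoreTrace(
                pore_id=int(p.pore_id),
                d_nm=float(p.get("d_nm", np.nan)),
                h_nm=float(p.get("h_nm", np.nan)),
                times_s=times,
                values=inner_mean - bg,
                channel=channel,
            )
        )
    return traces


def switching_score(values: np.ndarray, min_state_frac: float = 0.1) -> float:
    """Two-state fluctuation score of a trace.

    Splits the samples by a two-means threshold and returns the step size
    between the two level means in units of the pooled within-level SD.
    Returns 0 when either level holds less than ``min_state_frac`` of the
    frames (a constant trace with outliers is not 'switching').
    """
    v = np.asarray(values, float)
    if v.std() == 0:
        return 0.0
    thr = 0.5 * (v.min() + v.max())
    for _ in range(20):  # two-means on 1-D data
        lo, hi = v[v <= thr], v[v > thr]
        if len(lo) == 0 or len(hi) == 0:
            return 0.0
        new = 0.5 * (lo.mean() + hi.mean())
        if abs(new - thr) < 1e-12:
            break
        thr = new
    lo, hi = v[v <= thr], v[v > thr]
    f = min(len(lo), len(hi)) / len(v)
    if f < min_state_frac:
        return 0.0
    pooled = np.sqrt(
        (len(lo) * lo.var() + len(hi) * hi.var()) / len(v)
    )
    if pooled == 0:
        return np.inf
    return float((hi.mean() - lo.mean()) / pooled)


def _level_step(values: np.ndarray) -> float:
    """Step size between the two levels of a two-means split."""
    v = np.asarray(values, float)
    if v.std() == 0:
        return 0.0
    thr = 0.5 * (v.min() + v.max())
    for _ in range(20):
        lo, hi = v[v <= thr], v[v > thr]
        if len(lo) == 0 or len(hi) == 0:
            return 0.0
        new = 0.5 * (lo.mean() + hi.mean())
        if abs(new - thr) < 1e-12:
            break
        thr = new
    lo, hi = v[v <= thr], v[v > thr]
    return float(hi.mean() - lo.mean())


def _upper_level_mean(values: np.ndarray) -> float:
    """Mean of the upper level of a two-means split of the samples."""
    v = np.asarray(values, float)
    thr = 0.5 * (v.min() + v.max())
    for _ in range(20):
        lo, hi = v[v <= thr], v[v > thr]
        if len(lo) == 0 or len(hi) == 0:
            return float(v.mean())
        new = 0.5 * (lo.mean() + hi.mean())
        if abs(new - thr) < 1e-12:
            break
        thr = new
    hi = v[v > thr]
    return float(hi.mean()) if len(hi) else float(v.mean())


def _split_high_low(levels: np.ndarray, seed: int) -> np.ndarray:
    """Two-component 1-D Gaussian mixture labels ('high'/'low')."""
    from sklearn.mixture import GaussianMixture

    if len(levels) < 2 or np.std(levels) == 0:
        return np.full(len(levels), "high", dtype=object)
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3).fit(
        levels.reshape(-1, 1)
    )
    comp = gm.predict(levels.reshape(-1, 1))
    hi_comp = int(np.argmax(gm.means_.ravel()))
    return np.where(comp == hi_comp, "high", "low")


def classify_pores(
    traces: list[PoreTrace],
    control_traces: list[PoreTrace],
    k_sigma: float = 3.0,
    switching_threshold: float = 3.0,
    min_state_frac: float = 0.1,
    group_by_diameter: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Classify pore traces as negative / low / high and stable / switching.

    The positive threshold is ``mean + k_sigma * SD`` of the no-cell
    control trace means (controls are mandatory — there is no default
    threshold).  Positive pores are split into low/high by a two-component
    1-D Gaussian mixture on their occupied-level intensities, separately
    for each pore diameter (the absolute intensity grows with pore size,
    so the bimodal structure exists per size, not globally).  For
    switching traces the occupied level is the upper mean of a two-means
    split; for stable traces it is the trace mean.
    """
    if not control_traces:
        raise ValueError("control traces from cell-free pores are required")
    ctrl = np.array([t.mean for t in control_traces])
    threshold = float(ctrl.mean() + k_sigma * ctrl.std())
    # per-frame noise floor from the controls: a genuine two-state switch
    # must step by more than plain shot/read noise
    frame_sigma = float(np.median([t.values.std() for t in control_traces]))

    means = np.array([t.mean for t in traces])
    scores = np.array(
        [switching_score(t.values, min_state_frac) for t in traces]
    )
    steps = np.array([_level_step(t.values) for t in traces])
    switching = (scores > switching_threshold) & (steps > 3.0 * frame_sigma)
    levels = np.where(
        switching, [_upper_level_mean(t.values) for t in traces], means
    )
    positive = levels > threshold

    label = np.full(len(traces), "negative", dtype=object)
    diam = np.array([t.d_nm for t in traces])
    groups = (
        [diam == d for d in np.unique(diam)] if group_by_diameter
        else [np.ones(len(traces), bool)]
    )
    for g in groups:
        sel = g & positive
        if sel.sum() == 0:
            continue
        label[sel] = _split_high_low(levels[sel], seed)

    rows = []
    for t, lab, mean, lev, sc, pos in zip(
        traces, label, means, levels, scores, positive
    ):
        rows.append(
            {
                "pore_id": t.pore_id,
                "d_nm": t.d_nm,
                "h_nm": t.h_nm,
                "mean": mean,
                "level": lev,
                "sd": float(t.values.std()),
                "label": lab,
                "stability": "switching" if (pos and sc > switching_threshold)
                else "stable",
                "fluctuation_score": sc,
            }
        )
    return pd.DataFrame(rows), threshold


def occupancy_by_size(classes: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Fraction of positive (non-negative) pores per (d, h) with binomial CIs."""
    from statsmodels.stats.proportion import proportion_confint

    rows = []
    for (d, h), grp in classes.groupby(["d_nm", "h_nm"]):
        n = len(grp)
        if n == 0:
            continue
        k = int((grp["label"] != "negative").sum())
        lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
        rows.append(
            {
                "d_nm": d,
                "h_nm": h,
                "n_pores": n,
                "n_positive": k,
                "fraction": k / n,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


def wf_tirf_compare(
    traces_wf: list[PoreTrace],
    traces_tirf: list[PoreTrace],
    classes: pd.DataFrame,
) -> pd.DataFrame:
    """High/low-class mean intensities under wide-field vs TIRF illumination.

    Requires matched pore sets; classes come from the wide-field channel.
    Leak-through from the cell body above the ZMW is reduced under TIRF,
    so low-class pores are expected to dim more than high-class pores.
    """
    ids_wf = {t.pore_id for t in traces_wf}
    ids_tirf = {t.pore_id for t in traces_tirf}
    if ids_wf != ids_tirf:
        raise ValueError("wide-field and TIRF pore sets do not match")
    mw = {t.pore_id: t.mean for t in traces_wf}
    mt = {t.pore_id: t.mean for t in traces_tirf}
    rows = []
    for lab in ("high", "low"):
        ids = classes.loc[classes["label"] == lab, "pore_id"]
        vw = np.array([mw[i] for i in ids])
        vt = np.array([mt[i] for i in ids])
        if len(vw) == 0:
            rows.append(
                {"label": lab, "n": 0, "mean_wf": np.nan, "sd_wf": np.nan,
                 "mean_tirf": np.nan, "sd_tirf": np.nan, "ratio_tirf_wf": np.nan,
                 "empty": True}
            )
            continue
        rows.append(
            {
                "label": lab,
                "n": len(vw),
                "mean_wf": vw.mean(),
                "sd_wf": vw.std(),
                "mean_tirf": vt.mean(),
                "sd_tirf": vt.std(),
                "ratio_tirf_wf": vt.mean() / vw.mean() if vw.mean() != 0 else np.nan,
                "empty": False,
            }
        )
    return pd.DataFrame(rows)
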