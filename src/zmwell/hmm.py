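"""Two-state hidden Markov analysis of single-molecule pore traces.

Single membrane proteins diffusing in and out of a nanowell produce
intensity spikes on a background.  A Gaussian-emission two-state HMM is
fitted by expectation-maximization (initialized from two-means
clustering) and decoded with the most-probable path; states are always
reported sorted by mean, so the output is invariant to internal label
permutation.

Trace metrics follow the single-molecule convention: peak intensity =
on-state mean - off-state mean, background noise ``sigma`` = standard
deviation of the off-state residuals, and SNR = peak / sigma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class TwoStateHmmModel:
    """Two-state Gaussian HMM for an intensity trace (statsmodels-style).

    Parameters
    ----------
    values : array-like
        Background-subtracted intensity per frame (>= 50 frames).
    seed : int
        Fixes EM initialization; fitting is deterministic given the trace
        and the seed.
    """

    MIN_FRAMES = 50

    def __init__(self, values, seed: int = 0, min_separation: float = 2.0) -> None:
        v = np.asarray(values, float)
        if v.ndim != 1:
            raise ValueError("trace must be 1-D")
        if len(v) < self.MIN_FRAMES:
            raise ValueError(f"trace shorter than {self.MIN_FRAMES} frames")
        self.values = v
        self.seed = seed
        # minimum on/off separation in units of the off-state SD below
        # which the trace is treated as single-state
        self.min_separation = min_separation

    def fit(self, n_iter: int = 100) -> "HmmResults":
        v = self.values
        if np.std(v) == 0:
            return self._fallback("zero-variance trace")

        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=2, n_init=3, random_state=self.seed).fit(
            v.reshape(-1, 1)
        )
        means0 = np.sort(km.cluster_centers_.ravel())
        if means0[1] - means0[0] < 1e-12:
            return self._fallback("degenerate two-means split")
        lab = v > means0.mean()
        var0 = np.array(
            [
                np.var(v[~lab]) if (~lab).any() else np.var(v),
                np.var(v[lab]) if lab.any() else np.var(v),
            ]
        )
        var0 = np.clip(var0, 1e-6 * np.var(v) + 1e-12, None)

        from hmmlearn.hmm import GaussianHMM

        hmm = GaussianHMM(
            n_components=2,
            covariance_type="diag",
            init_params="",
            n_iter=n_iter,
            random_state=self.seed,
        )
        hmm.startprob_ = np.array([0.5, 0.5])
        hmm.transmat_ = np.array([[0.95, 0.05], [0.05, 0.95]])
        hmm.means_ = means0.reshape(-1, 1)
        hmm.covars_ = var0.reshape(-1, 1)
        x = v.reshape(-1, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hmm.fit(x)
            states = hmm.predict(x)

        means = hmm.means_.ravel()
        variances = hmm.covars_.ravel()
        transmat = hmm.transmat_
        if means[0] > means[1]:  # sort states: 0 = off, 1 = on
            means = means[::-1]
            variances = variances[::-1]
            transmat = transmat[::-1, ::-1]
            states = 1 - states

        off = v[states == 0]
        on = v[states == 1]
        if len(off) == 0 or len(on) == 0:
            return self._fallback("single-state decoding")
        peak = float(means[1] - means[0])
        # no genuine two-state structure: a pure-noise trace splits into two
        # pseudo-states separated by ~1 sigma
        if peak < self.min_separation * np.sqrt(max(variances[0], 1e-30)):
            return self._fallback("states not separated beyond noise")
        sigma = float(np.std(off - means[0]))
        if sigma == 0:
            sigma = float(np.sqrt(max(variances[0], 1e-30)))
        events = _on_segments(states)
        return HmmResults(
            model=self,
            means=means,
            variances=variances,
            transmat=transmat,
            states=states,
            peak=peak,
            sigma=sigma,
            snr=peak / sigma if sigma > 0 else np.inf,
            events=events,
            success=True,
            message="ok",
        )

    def _fallback(self, reason: str) -> "HmmResults":
        v = self.values
        states = np.zeros(len(v), dtype=int)
        return HmmResults(
            model=self,
            means=np.array([float(v.mean()), float(v.mean())]),
            variances=np.array([float(v.var()), float(v.var())]),
            transmat=np.eye(2),
            states=states,
            peak=np.nan,
            sigma=float(v.std()),
            snr=np.nan,
            events=[],
            success=False,
            message=f"single-state fallback: {reason}",
        )


def _on_segments(states: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of contiguous on-state runs (stop exclusive)."""
    out = []
    in_run = False
    start = 0
    for i, s in enumerate(states):
        if s == 1 and not in_run:
            in_run, start = True, i
        elif s == 0 and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, len(states)))
    return out


@dataclass
class HmmResults:
    """Decoded two-state trace: state parameters, path, and spike metrics."""

    model: TwoStateHmmModel
    means: np.ndarray  # sorted: [off, on]
    variances: np.ndarray
    transmat: np.ndarray
    states: np.ndarray
    peak: float
    sigma: float
    snr: float
    events: list[tuple[int, int]]
    success: bool
    message: str = ""

    @property
    def n_events(self) -> int:
        return len(self.events)

    def dwell_times(self, frame_interval_s: float = 1.0) -> np.ndarray:
        return np.array([(b - a) * frame_interval_s for a, b in self.events])

    def spike_stats(self) -> dict:
        """Peak intensity, background sigma, SNR and event count."""
        return {
            "peak": self.peak,
            "sigma": self.sigma,
            "snr": self.snr,
            "n_events": self.n_events,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.states)),
                             "state": self.states})

    def summary(self) -> str:
        return "\n".join(
            [
                "Two-state Gaussian HMM (EM, two-means init)",
                "-" * 44,
                f"off mean / on mean : {self.means[0]:.4g} / {self.means[1]:.4g}",
                f"peak intensity     : {self.peak:.4g}",
                f"background sigma   : {self.sigma:.4g}",
                f"SNR                : {self.snr:.3g}",
                f"on events          : {self.n_events}",
                f"status             : {self.message}",
            ]
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        v = self.model.values
        ax.plot(v, lw=0.8, label="trace")
        ax.plot(self.means[self.states], lw=1.2, label="decoded")
        ax.set_xlabel("frame")
        ax.set_ylabel("intensity")
        ax.legend()
        return ax


def fit_two_state_hmm(values, seed: int = 0) -> HmmResults:
    """Convenience wrapper for :class:`TwoStateHmmModel`."""
    return TwoStateHmmModel(values, seed=seed).fit()


def spike_stats(result: HmmResults) -> tuple[float, float, float, int]:
    """(peak, sigma, SNR, n_events) of a fitted trace."""
    s = result.spike_stats()
    return s["peak"], s["sigma"], s["snr"], s["n_events"]
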