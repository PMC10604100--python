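"""File I/O and run provenance.

All tabular artifacts are UTF-8 comma-separated CSV with a mandatory
header row and ``.`` decimals; profiles carry a JSON metadata sidecar.
Every pipeline run writes a :class:`RunManifest` so stochastic outputs
are reproducible bit-for-bit from the recorded seed and configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .optics import DipoleEmissionProfile, ExcitationProfile


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    subcommand: str
    seed: int
    config: dict
    version: str = ""
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def record_input(self, path) -> None:
        self.inputs[str(path)] = sha256_file(path)

    def record_output(self, path) -> None:
        self.outputs[str(path)] = sha256_file(path)

    def write(self, path) -> None:
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def new_manifest(subcommand: str, seed: int, config: dict) -> RunManifest:
    from . import __version__

    return RunManifest(
        subcommand=subcommand,
        seed=seed,
        config=config,
        version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )


# ---------------------------------------------------------------------------
# profiles

def write_profile(path, z_nm, value, metadata: dict | None = None) -> None:
    """Write an axial profile as CSV (z_nm, value) + JSON sidecar."""
    path = Path(path)
    pd.DataFrame({"z_nm": z_nm, "value": value}).to_csv(path, index=False)
    if metadata is not None:
        path.with_suffix(".json").write_text(json.dumps(metadata, indent=2))


def read_profile(path) -> tuple[np.ndarray, np.ndarray, dict]:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    side = path.with_suffix(".json")
    if side.exists():
        meta = json.loads(side.read_text())
    return df["z_nm"].to_numpy(), df["value"].to_numpy(), meta


def write_excitation_profile(path, profile: ExcitationProfile) -> None:
    write_profile(
        path,
        profile.z_nm,
        profile.intensity,
        {"kind": "excitation", "mode": profile.mode,
         "wavelength_nm": profile.wavelength_nm},
    )


def read_excitation_profile(path) -> ExcitationProfile:
    z, v, meta = read_profile(path)
    return ExcitationProfile(
        z_nm=z,
        intensity=v,
        mode=meta.get("mode", "widefield"),
        wavelength_nm=meta.get("wavelength_nm", 488.0),
    )


def write_emission_profile(path, profile: DipoleEmissionProfile) -> None:
    path = Path(path)
    pd.DataFrame(
        {
            "z_nm": profile.z_nm,
            "p_total": profile.p_total,
            "p_ff": profile.p_ff,
            "p_ff_down": profile.p_ff_down,
        }
    ).to_csv(path, index=False)
    path.with_suffix(".json").write_text(
        json.dumps({"kind": "emission", "orientation": profile.orientation})
    )


def read_emission_profile(path) -> DipoleEmissionProfile:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    side = path.with_suffix(".json")
    if side.exists():
        meta = json.loads(side.read_text())
    return DipoleEmissionProfile(
        z_nm=df["z_nm"].to_numpy(),
        p_total=df["p_total"].to_numpy(),
        p_ff=df["p_ff"].to_numpy(),
        p_ff_down=df["p_ff_down"].to_numpy(),
        orientation=meta.get("orientation", "isotropic"),
    )


# ---------------------------------------------------------------------------
# traces and decays

def write_trace(path, trace) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_trace(path, bin_width_ms: float | None = None):
    from .fcs import PhotonTrace

    df = pd.read_csv(path)
    if bin_width_ms is None:
        t = df["time_ms"].to_numpy()
        bin_width_ms = float(t[1] - t[0]) if len(t) > 1 else 1.0
    return PhotonTrace(
        bin_width_ms=bin_width_ms, counts=df["counts"].to_numpy()
    )


def write_decay(path, decay) -> None:
    decay.to_frame().to_csv(path, index=False)


def read_decay(path):
    from .lifetime import TcspcDecay

    df = pd.read_csv(path)
    t = df["time_ps"].to_numpy()
    bin_ps = float(t[1] - t[0]) if len(t) > 1 else 25.0
    return TcspcDecay(
        bin_width_ps=bin_ps,
        counts=df["counts"].to_numpy(),
        irf=df["irf"].to_numpy(),
    )
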