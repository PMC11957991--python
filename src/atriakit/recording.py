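"""In-memory containers and file I/O for multichannel electrophysiology data.

A :class:`Recording` holds a channel-by-sample matrix in millivolts together
with the sample rate and the role of each channel (one atrial bipolar channel
plus up to three surface-ECG leads).  Recordings round-trip through HDF5
(h5py) or a CSV + JSON-sidecar pair; event annotations travel as tidy CSV
tables with columns ``time_s, kind, label``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["Recording", "BeatAnnotations", "ATRIAL", "ECG1", "ECG2", "ECG3"]

ATRIAL = "atrial_bipolar"
ECG1 = "ecg_1"
ECG2 = "ecg_2"
ECG3 = "ecg_3"

#: Physiological floor on consecutive rat R-R spacing (ms).
MIN_RR_MS = 50.0


@dataclass
class Recording:
    """Multichannel signal matrix with channel roles.

    Attributes
    ----------
    signals : np.ndarray, shape (n_channels, n_samples)
        Amplitudes in mV.
    sample_rate : float
        Hz.
    channel_roles : list of str
        Unique role per channel, e.g. ``["atrial_bipolar", "ecg_1"]``.
    t0 : float
        Time of the first sample, seconds.
    annotations : pd.DataFrame or None
        Optional event table with columns ``time_s, kind, label`` (ground
        truth when the recording is synthetic).
    """

    signals: np.ndarray
    sample_rate: float
    channel_roles: list[str]
    t0: float = 0.0
    annotations: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if len(self.channel_roles) != self.signals.shape[0]:
            raise ValueError("one role per channel required")
        if len(set(self.channel_roles)) != len(self.channel_roles):
            raise ValueError("channel roles must be unique")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    def channel(self, role: str) -> np.ndarray:
        """Return the 1-D signal of the channel with the given role."""
        try:
            idx = self.channel_roles.index(role)
        except ValueError:
            raise KeyError(f"no channel with role {role!r}") from None
        return self.signals[idx]

    def with_channel(self, role: str, data: np.ndarray) -> "Recording":
        """Copy of the recording with one channel's samples replaced."""
        idx = self.channel_roles.index(role)
        sig = self.signals.copy()
        sig[idx] = data
        return Recording(sig, self.sample_rate, list(self.channel_roles),
                         self.t0, self.annotations)

    def index_at(self, t: float) -> int:
        """Sample index of time ``t`` (seconds, clipped to the signal)."""
        return int(np.clip(round((t - self.t0) * self.sample_rate),
                           0, self.n_samples - 1))

    # -- persistence ------------------------------------------------------
    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("signals", data=self.signals)
            d.attrs["sample_rate_hz"] = self.sample_rate
            d.attrs["channel_roles"] = ",".join(self.channel_roles)
            d.attrs["t0_s"] = self.t0
            if self.annotations is not None:
                grp = f.create_group("annotations")
                grp.create_dataset("time_s", data=self.annotations["time_s"].to_numpy(float))
                kinds = self.annotations["kind"].astype(str).to_numpy()
                grp.create_dataset("kind", data=kinds.astype("S"))
                labels = self.annotations.get("label", pd.Series([""] * len(kinds)))
                grp.create_dataset("label", data=labels.astype(str).to_numpy().astype("S"))

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "Recording":
        with h5py.File(path, "r") as f:
            d = f["signals"]
            ann = None
            if "annotations" in f:
                grp = f["annotations"]
                ann = pd.DataFrame({
                    "time_s": grp["time_s"][()],
                    "kind": [k.decode() for k in grp["kind"][()]],
                    "label": [k.decode() for k in grp["label"][()]],
                })
            return cls(d[()], float(d.attrs["sample_rate_hz"]),
                       str(d.attrs["channel_roles"]).split(","),
                       float(d.attrs.get("t0_s", 0.0)), ann)

    def to_csv(self, signals_path: str | Path) -> None:
        """Write a ``signals.csv`` / ``meta.json`` pair next to each other."""
        signals_path = Path(signals_path)
        pd.DataFrame(self.signals.T, columns=self.channel_roles).to_csv(
            signals_path, index=False)
        meta = {"sample_rate_hz": self.sample_rate, "t0_s": self.t0,
                "channel_roles": self.channel_roles}
        signals_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, signals_path: str | Path) -> "Recording":
        signals_path = Path(signals_path)
        df = pd.read_csv(signals_path)
        meta = json.loads(signals_path.with_suffix(".json").read_text())
        return cls(df[meta["channel_roles"]].to_numpy().T,
                   meta["sample_rate_hz"], meta["channel_roles"],
                   meta.get("t0_s", 0.0))


@dataclass
class BeatAnnotations:
    """Detected beat times in seconds (strictly increasing).

    ``qrs_times`` are R-peak times; ``p_times`` (optional) hold the matched
    P-wave onsets, one per R peak where one was found (NaN otherwise).
    Consecutive R peaks closer than the rat refractory floor (50 ms) violate
    the invariant and are rejected.
    """

    qrs_times: np.ndarray
    p_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.qrs_times = np.asarray(self.qrs_times, float)
        if np.any(np.diff(self.qrs_times) < MIN_RR_MS / 1000.0):
            raise ValueError("QRS times violate the 50-ms refractory floor")
        if self.p_times is not None:
            self.p_times = np.asarray(self.p_times, float)

    def __len__(self) -> int:
        return len(self.qrs_times)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"qrs_time_s": self.qrs_times})
        if self.p_times is not None:
            df["p_time_s"] = self.p_times
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BeatAnnotations":
        df = pd.read_csv(path)
        p = df["p_time_s"].to_numpy() if "p_time_s" in df else None
        return cls(df["qrs_time_s"].to_numpy(), p)
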