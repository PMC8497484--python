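"""Epoched data container and its on-disk form (binary array + JSON sidecar)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .layout import ChannelLayout

SCHEMA_VERSION = "1"


@dataclass
class EpochSet:
    """Trials x channels x timepoints of voltage (microvolts).

    ``times`` is in ms relative to the time-locking event (shock onset for
    the main epochs).  ``rejected``/``reject_reason`` carry per-trial
    artifact flags; statistics downstream use retained trials only.
    """

    participant: str
    data: np.ndarray  # (n_trials, n_channels, n_times) float64, microvolts
    sfreq: float
    times: np.ndarray  # ms
    conditions: list[str]
    layout: ChannelLayout
    rejected: np.ndarray = field(default=None)  # bool per trial
    reject_reason: list = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.times = np.asarray(self.times, float)
        n_trials, n_channels, n_times = self.data.shape
        if n_channels != self.layout.n_channels:
            raise ValueError("data/layout channel mismatch")
        if n_times != len(self.times):
            raise ValueError("data/time-axis mismatch")
        if len(self.conditions) != n_trials:
            raise ValueError("conditions/trials mismatch")
        if not np.isfinite(self.data).all():
            raise ValueError("data must be finite")
        if self.rejected is None:
            self.rejected = np.zeros(n_trials, dtype=bool)
        if self.reject_reason is None:
            self.reject_reason = [None] * n_trials

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            times=self.times.copy(),
            conditions=list(self.conditions),
            rejected=self.rejected.copy(),
            reject_reason=list(self.reject_reason),
        )

    def time_mask(self, start_ms: float, stop_ms: float) -> np.ndarray:
        return (self.times >= start_ms) & (self.times <= stop_ms)

    # -- persistence --------------------------------------------------------

    def save(self, stem: str | Path) -> None:
        """Write ``<stem>.npy`` (float64 array) + ``<stem>.json`` sidecar."""
        stem = Path(stem)
        np.save(stem.with_suffix(".npy"), self.data)
        sidecar = {
            "schema_version": SCHEMA_VERSION,
            "participant": self.participant,
            "sfreq": self.sfreq,
            "times_ms": self.times.tolist(),
            "conditions": self.conditions,
            "channels": list(self.layout.names),
            "positions": self.layout.positions.tolist(),
            "non_scalp": list(self.layout.non_scalp),
            "rejected": self.rejected.astype(int).tolist(),
            "reject_reason": self.reject_reason,
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar))

    def save_hdf5(self, path: str | Path) -> None:
        """Alternative single-file container (requires h5py)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times_ms", data=self.times)
            f.create_dataset("positions", data=self.layout.positions)
            f.attrs["schema_version"] = SCHEMA_VERSION
            f.attrs["participant"] = self.participant
            f.attrs["sfreq"] = self.sfreq
            f.attrs["channels"] = list(self.layout.names)
            f.attrs["non_scalp"] = list(self.layout.non_scalp)
            f.attrs["conditions"] = self.conditions
            f.create_dataset("rejected", data=self.rejected.astype(np.int8))
            f.attrs["reject_reason"] = [
                r if r is not None else "" for r in self.reject_reason
            ]

    @classmethod
    def load_hdf5(cls, path: str | Path) -> "EpochSet":
        import h5py

        with h5py.File(path, "r") as f:
            layout = ChannelLayout(
                tuple(f.attrs["channels"]),
                np.asarray(f["positions"]),
                tuple(f.attrs["non_scalp"]),
            )
            return cls(
                participant=str(f.attrs["participant"]),
                data=np.asarray(f["data"]),
                sfreq=float(f.attrs["sfreq"]),
                times=np.asarray(f["times_ms"]),
                conditions=[str(c) for c in f.attrs["conditions"]],
                layout=layout,
                rejected=np.asarray(f["rejected"], dtype=bool),
                reject_reason=[r or None for r in f.attrs["reject_reason"]],
            )

    @classmethod
    def load(cls, stem: str | Path) -> "EpochSet":
        stem = Path(stem)
        meta = json.loads(stem.with_suffix(".json").read_text())
        layout = ChannelLayout(
            tuple(meta["channels"]),
            np.asarray(meta["positions"]),
            tuple(meta["non_scalp"]),
        )
        return cls(
            participant=meta["participant"],
            data=np.load(stem.with_suffix(".npy")),
            sfreq=meta["sfreq"],
            times=np.asarray(meta["times_ms"]),
            conditions=list(meta["conditions"]),
            layout=layout,
            rejected=np.asarray(meta["rejected"], dtype=bool),
            reject_reason=list(meta["reject_reason"]),
        )
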