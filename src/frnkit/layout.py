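"""Electrode layout and spatial channel adjacency.

The packaged montage is a 61-channel 10-20/10-10 scalp set plus the two
mastoids (M1, M2) and a right suborbital EMG/EOG electrode (SO2), all on the
unit sphere in head coordinates.  Cluster-forming adjacency between scalp
channels is defined by a great-circle distance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

#: non-scalp channels in the packaged montage
NON_SCALP = ("M1", "M2", "SO2")

#: great-circle adjacency threshold (radians) giving a median neighbour
#: count of 7 on the packaged 61-channel montage
DEFAULT_ADJACENCY_RADIUS = 0.57


@dataclass(frozen=True)
class ChannelLayout:
    """Named electrode positions on the unit sphere.

    Parameters
    ----------
    names
        Channel names, unique, in recording order.
    positions
        ``(n_channels, 3)`` unit vectors in head coordinates.
    non_scalp
        Names flagged as non-scalp (reference/EMG sites); these never enter
        scalp-level statistics, interpolation or adjacency.
    """

    names: tuple[str, ...]
    positions: np.ndarray
    non_scalp: tuple[str, ...] = NON_SCALP

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        pos = np.asarray(self.positions, float)
        if pos.shape != (len(self.names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("positions must lie on the unit sphere")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.names)

    @property
    def scalp_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if n not in self.non_scalp)

    @property
    def scalp_indices(self) -> np.ndarray:
        return np.array(
            [i for i, n in enumerate(self.names) if n not in self.non_scalp]
        )

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def great_circle(self) -> np.ndarray:
        """Pairwise great-circle distances (radians) between all channels."""
        cosang = np.clip(self.positions @ self.positions.T, -1.0, 1.0)
        return np.arccos(cosang)

    def subset(self, names: list[str] | tuple[str, ...]) -> "ChannelLayout":
        idx = [self.index(n) for n in names]
        return ChannelLayout(
            tuple(names),
            self.positions[idx],
            tuple(n for n in self.non_scalp if n in names),
        )


def load_default_layout() -> ChannelLayout:
    """Load the packaged 61+3 channel montage."""
    text = (
        resources.files("frnkit.data").joinpath("montage64.txt").read_text()
    )
    names, rows = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        names.append(parts[0])
        rows.append([float(v) for v in parts[1:4]])
    return ChannelLayout(tuple(names), np.asarray(rows))


def scalp_adjacency(
    layout: ChannelLayout, radius: float = DEFAULT_ADJACENCY_RADIUS
) -> np.ndarray:
    """Boolean neighbour matrix over *scalp* channels.

    Two scalp channels are neighbours when their great-circle distance is at
    most ``radius`` radians.  The relation is symmetric and irreflexive.
    """
    idx = layout.scalp_indices
    d = layout.great_circle()[np.ix_(idx, idx)]
    adj = (d <= radius) & ~np.eye(len(idx), dtype=bool)
    if not adj.any(axis=1).all():
        lonely = [layout.scalp_names[i] for i in np.flatnonzero(~adj.any(axis=1))]
        raise ValueError(f"isolated channels at radius {radius}: {lonely}")
    return adj
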