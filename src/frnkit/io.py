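"""File formats and run configuration.

Schedules/behaviour/startle summaries travel as CSV, results as JSON with
an embedded schema version, epochs as binary array + JSON sidecar (see
``epochs``).  Real recordings enter through BrainVision (.vhdr/.vmrk/.eeg)
via marker-based segmentation; a fixture writer produces small round-trip
triplets for testing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .epochs import EpochSet, SCHEMA_VERSION
from .layout import DEFAULT_ADJACENCY_RADIUS, load_default_layout
from .preprocess import PreprocConfig
from .synth import GroundTruthEffects


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to regenerate a full synthetic study run."""

    seed: int = 0
    n_participants: int = 44
    n_blocks: int = 5
    trials_per_block: int = 40
    noise_rate: float = 0.2
    sampling_rate: float = 500.0
    effects: GroundTruthEffects = field(default_factory=GroundTruthEffects)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    n_perm: int = 5_000
    alpha_sample: float = 0.05
    min_cluster_size: int = 25
    adjacency_radius: float = DEFAULT_ADJACENCY_RADIUS
    prior_scale: float = float(np.sqrt(2.0) / 2.0)
    evidence_threshold: float = 0.975
    #: restrict the encoder map to these channels (None = whole scalp)
    encoder_channels: tuple[str, ...] | None = None
    congruence_bias: float = 0.5545
    congruence_bias_sd: float = 0.0486
    query_accuracy: float = 0.6295
    startle_base_amplitude: float = 8.0
    startle_stakes_delta: float = 0.91
    startle_delta_sd: float = 2.7
    startle_response_rate: float = 0.5

    def to_json(self) -> str:
        return json.dumps(
            {"schema_version": SCHEMA_VERSION, **dataclasses.asdict(self)},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        raw.pop("schema_version", None)
        eff = raw.pop("effects", None)
        pre = raw.pop("preproc", None)
        if eff is not None:
            for k in ("rpe_window", "late_window", "salience_window"):
                if k in eff:
                    eff[k] = tuple(eff[k])
            raw["effects"] = GroundTruthEffects(**eff)
        if pre is not None:
            for k in ("notch_hz", "baseline_window", "scan_window"):
                if k in pre:
                    pre[k] = tuple(pre[k])
            raw["preproc"] = PreprocConfig(**pre)
        if raw.get("encoder_channels") is not None:
            raw["encoder_channels"] = tuple(raw["encoder_channels"])
        return cls(**raw)


def write_json(path: str | Path, payload: dict) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **payload}
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# BrainVision


def write_brainvision_fixture(
    stem: str | Path,
    data_uv: np.ndarray,
    sfreq: float,
    channel_names: list[str],
    marker_samples: list[int],
    marker_code: str = "S  1",
) -> Path:
    """Write a minimal BrainVision triplet (.vhdr/.vmrk/.eeg).

    ``data_uv`` is (channels, samples) in microvolts, stored multiplexed
    IEEE float 32.  Returns the header path.
    """
    stem = Path(stem)
    name = stem.name
    vhdr = stem.with_suffix(".vhdr")
    vmrk = stem.with_suffix(".vmrk")
    eeg = stem.with_suffix(".eeg")
    n_ch = data_uv.shape[0]
    interval_us = int(round(1e6 / sfreq))
    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        f"MarkerFile={name}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={interval_us}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, ch in enumerate(channel_names, 1):
        header.append(f"Ch{i}={ch},,1,µV")
    vhdr.write_text("\n".join(header) + "\n", encoding="utf-8")

    markers = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, pos in enumerate(marker_samples, 2):
        markers.append(f"Mk{k}=Stimulus,{marker_code},{pos + 1},1,0")
    vmrk.write_text("\n".join(markers) + "\n", encoding="utf-8")

    np.asarray(data_uv, np.float32).T.tofile(eeg)
    return vhdr


def read_brainvision(
    vhdr_path: str | Path,
    tmin_ms: float = -300.0,
    tmax_ms: float = 700.0,
    marker: str = "Stimulus/S  1",
    condition_map: dict[str, str] | None = None,
    participant: str = "",
) -> EpochSet:
    """Read a BrainVision triplet and segment it around stimulus markers.

    Epochs span [tmin_ms, tmax_ms) around each occurrence of ``marker``
    (or each key of ``condition_map``, which assigns condition labels per
    marker description; unmatched markers are ignored).  Channel names
    must exist in the packaged montage, which supplies positions.
    """
    import mne

    vhdr_path = Path(vhdr_path)
    if not vhdr_path.with_suffix(".eeg").exists():
        raise FileNotFoundError(
            f"missing data file for header: {vhdr_path.with_suffix('.eeg')}"
        )
    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    sfreq = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # Volts -> microvolts

    full = load_default_layout()
    unknown = [ch for ch in raw.ch_names if ch not in full.names]
    if unknown:
        raise ValueError(f"channels not in packaged montage: {unknown}")
    layout = full.subset(raw.ch_names)

    if condition_map is None:
        condition_map = {marker: "LP"}
    onsets, labels = [], []
    for ann in raw.annotations:
        if ann["description"] in condition_map:
            onsets.append(int(round(ann["onset"] * sfreq)))
            labels.append(condition_map[ann["description"]])

    n_pre = int(round(-tmin_ms / 1000.0 * sfreq))
    n_post = int(round(tmax_ms / 1000.0 * sfreq))
    times = np.arange(-n_pre, n_post) * 1000.0 / sfreq
    trials, conditions = [], []
    for onset, label in zip(onsets, labels):
        lo, hi = onset - n_pre, onset + n_post
        if lo < 0 or hi > data.shape[1]:
            continue  # epoch falls off the recording edge
        trials.append(data[:, lo:hi])
        conditions.append(label)
    if not trials:
        raise ValueError(f"no complete epochs for marker(s) {list(condition_map)}")
    return EpochSet(
        participant=participant or vhdr_path.stem,
        data=np.stack(trials),
        sfreq=sfreq,
        times=times,
        conditions=conditions,
        layout=layout,
    )
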