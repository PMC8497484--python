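"""Preprocessing chain from epoched data to per-participant condition averages.

Fixed stage order: filter -> baseline -> artifact rejection -> mastoid
re-reference -> (optional) bad-channel interpolation -> downsample ->
condition averages.  All defaults equal the study parameters: 50/60 Hz
notches, 0.1-30 Hz band, baseline -200..0 ms, rejection rules 50 uV/ms
gradient, 100 uV absolute, 12 uV flatline, 100 Hz analysis rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .design import CONDITIONS
from .epochs import EpochSet


@dataclass(frozen=True)
class PreprocConfig:
    notch_hz: tuple[float, ...] = (60.0, 50.0)
    highpass_hz: float = 0.1
    lowpass_hz: float = 30.0
    baseline_window: tuple[float, float] = (-200.0, 0.0)
    artifact_gradient: float = 50.0  # uV per ms
    artifact_absolute: float = 100.0  # uV relative to baseline
    artifact_flat_range: float = 12.0  # uV peak-to-peak
    flat_rule: str = "all_channels"  # or "per_channel"
    scan_window: tuple[float, float] = (-200.0, 700.0)
    target_rate: float = 100.0
    filter_order: int = 4
    notch_q: float = 30.0

    def __post_init__(self) -> None:
        if self.highpass_hz >= self.lowpass_hz:
            raise ValueError("highpass must be below lowpass")
        if self.flat_rule not in ("all_channels", "per_channel"):
            raise ValueError("flat_rule must be all_channels or per_channel")

    @classmethod
    def from_file(cls, path) -> "PreprocConfig":
        """Read ``key = value`` lines; unknown keys rejected."""
        kwargs = {}
        for ln, line in enumerate(open(path), 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected key = value")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"{path}:{ln}: unknown key {key!r}")
            f = cls.__dataclass_fields__[key]
            if key == "flat_rule":
                kwargs[key] = val
            elif key in ("notch_hz", "baseline_window", "scan_window"):
                kwargs[key] = tuple(float(v) for v in val.split(","))
            elif key == "filter_order":
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)


def _filter_sos(config: PreprocConfig, sfreq: float) -> np.ndarray:
    sos = []
    for f0 in config.notch_hz:
        if f0 < sfreq / 2.0:
            b, a = signal.iirnotch(f0, config.notch_q, fs=sfreq)
            sos.append(signal.tf2sos(b, a))
    sos.append(signal.butter(config.filter_order, config.highpass_hz,
                             "highpass", fs=sfreq, output="sos"))
    sos.append(signal.butter(config.filter_order, config.lowpass_hz,
                             "lowpass", fs=sfreq, output="sos"))
    return np.vstack(sos)


def filter_response(
    config: PreprocConfig, sfreq: float, freqs_hz: np.ndarray
) -> np.ndarray:
    """Designed zero-phase magnitude response |H(f)| of the full cascade."""
    sos = _filter_sos(config, sfreq)
    w = 2.0 * np.pi * np.asarray(freqs_hz, float) / sfreq
    _, h = signal.sosfreqz(sos, worN=w)
    return np.abs(h)


def filter_epochs(epochs: EpochSet, config: PreprocConfig | None = None) -> EpochSet:
    """Zero-phase notch + band-pass filtering of every trial and channel.

    The Butterworth/notch cascade's magnitude response is applied once,
    with zero phase, in the frequency domain on odd-reflection-padded
    epochs.  A forward-backward time-domain pass cannot honour the design
    response here: the 0.1 Hz edge settles over many seconds, so on 1 s
    epochs its output is transient-dominated.  The spectral application
    realizes exactly the designed |H(f)| on every epoch instead.
    """
    config = config or PreprocConfig()
    if epochs.sfreq <= 2.0 * config.lowpass_hz:
        raise ValueError("sampling rate must exceed twice the low-pass edge")
    n = epochs.data.shape[-1]
    if n < 32:
        raise ValueError(
            f"epoch too short for stable filtering: need >= 32 samples, got {n}"
        )
    pad = n  # one epoch length of odd reflection on each side
    x = np.pad(epochs.data, [(0, 0), (0, 0), (pad, pad)],
               mode="reflect", reflect_type="odd")
    freqs = np.fft.rfftfreq(x.shape[-1], 1.0 / epochs.sfreq)
    gain = filter_response(config, epochs.sfreq, freqs)
    y = np.fft.irfft(np.fft.rfft(x, axis=-1) * gain, n=x.shape[-1], axis=-1)
    out = epochs.copy()
    out.data = y[:, :, pad : pad + n]
    return out


def baseline_correct(
    epochs: EpochSet, window: tuple[float, float] = (-200.0, 0.0)
) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``window`` (ms)."""
    mask = epochs.time_mask(*window)
    if not mask.any():
        raise ValueError(f"baseline window {window} contains no samples")
    out = epochs.copy()
    out.data = out.data - out.data[:, :, mask].mean(axis=-1, keepdims=True)
    return out


def reject_artifacts(
    epochs: EpochSet, config: PreprocConfig | None = None
) -> EpochSet:
    """Flag trials violating the gradient, absolute or flatline rules.

    A trial is flagged when ANY scalp channel exceeds the gradient
    (|dv| between adjacent samples / sample interval in ms) or absolute
    rules inside the scan window, or when ALL scalp channels stay below the
    flatline peak-to-peak range (``flat_rule="per_channel"`` instead flags
    any single flat channel).  The absolute rule presumes prior baseline
    correction.  Reasons record the first violated rule and channel.
    """
    config = config or PreprocConfig()
    out = epochs.copy()
    mask = out.time_mask(*config.scan_window)
    scalp = out.layout.scalp_indices
    names = out.layout.names
    dt_ms = 1000.0 / out.sfreq
    for i in range(out.n_trials):
        x = out.data[i][np.ix_(scalp, mask)]
        bad = np.flatnonzero(np.abs(x).max(axis=-1) > config.artifact_absolute)
        if bad.size:
            out.rejected[i] = True
            out.reject_reason[i] = f"absolute:{names[scalp[bad[0]]]}"
            continue
        grad = np.abs(np.diff(x, axis=-1)) / dt_ms
        bad = np.flatnonzero(grad.max(axis=-1) > config.artifact_gradient)
        if bad.size:
            out.rejected[i] = True
            out.reject_reason[i] = f"gradient:{names[scalp[bad[0]]]}"
            continue
        ranges = np.ptp(x, axis=-1)
        if config.flat_rule == "all_channels":
            if (ranges < config.artifact_flat_range).all():
                out.rejected[i] = True
                out.reject_reason[i] = "flat:all"
        else:
            bad = np.flatnonzero(ranges < config.artifact_flat_range)
            if bad.size:
                out.rejected[i] = True
                out.reject_reason[i] = f"flat:{names[scalp[bad[0]]]}"
    return out


def rereference_mastoids(
    epochs: EpochSet, left: str = "M1", right: str = "M2"
) -> EpochSet:
    """Re-reference to the average of the two mastoids.

    Data recorded against the left mastoid carry an implicit zero there, so
    subtracting (M1 + M2)/2 from every channel leaves the two mastoid
    channels equal and opposite and their mean at zero.
    """
    for name in (left, right):
        if name not in epochs.layout.names:
            raise ValueError(f"mastoid channel {name!r} missing")
    out = epochs.copy()
    li, ri = out.layout.index(left), out.layout.index(right)
    ref = 0.5 * (out.data[:, li, :] + out.data[:, ri, :])
    out.data = out.data - ref[:, None, :]
    return out


def spline_interpolation_weights(
    positions: np.ndarray, bad_index: int, m: int = 4,
    reg: float = 1e-5, n_terms: int = 50,
) -> tuple[np.ndarray, float]:
    """Spherical-spline weights predicting one channel from the others.

    Returns (weights over good channels, constant term applied to the mean
    of the solved constant).  ``positions`` are unit vectors; the spline
    uses Legendre order ``m`` with Tikhonov regularization ``reg``.
    """
    n = len(positions)
    good = [i for i in range(n) if i != bad_index]

    def g(cosang: np.ndarray) -> np.ndarray:
        ns = np.arange(1, n_terms + 1)
        coef = np.zeros(n_terms + 1)
        coef[1:] = (2 * ns + 1) / (ns * (ns + 1.0)) ** m
        return np.polynomial.legendre.legval(cosang, coef) / (4.0 * np.pi)

    cos_gg = np.clip(positions[good] @ positions[good].T, -1.0, 1.0)
    cos_bg = np.clip(positions[good] @ positions[bad_index], -1.0, 1.0)
    G = g(cos_gg) + reg * np.eye(len(good))
    # solve [[G, 1], [1^T, 0]] [w; c] = [v; 0]  =>  interpolant g_b.w + c
    A = np.zeros((len(good) + 1, len(good) + 1))
    A[:-1, :-1] = G
    A[:-1, -1] = 1.0
    A[-1, :-1] = 1.0
    inv = np.linalg.solve(A, np.eye(len(good) + 1))
    # value at bad site = [g(bad,good), 1] . A^-1 . [v; 0]
    proj = np.concatenate([g(cos_bg), [1.0]]) @ inv
    return proj[:-1], 0.0


def interpolate_channel(
    epochs: EpochSet, bad: str, m: int = 4, reg: float = 1e-5
) -> EpochSet:
    """Replace one scalp channel by spherical-spline interpolation."""
    if bad in epochs.layout.non_scalp:
        raise ValueError(f"{bad!r} is not a scalp channel")
    scalp = list(epochs.layout.scalp_indices)
    bi = epochs.layout.index(bad)
    if len(scalp) - 1 < 4:
        raise ValueError("need at least 4 good scalp channels")
    pos = epochs.layout.positions[scalp]
    w, _ = spline_interpolation_weights(pos, scalp.index(bi), m=m, reg=reg)
    good = [i for i in scalp if i != bi]
    out = epochs.copy()
    out.data[:, bi, :] = np.einsum("g,tgs->ts", w, out.data[:, good, :])
    return out


def downsample(epochs: EpochSet, target_rate: float = 100.0) -> EpochSet:
    """Decimate to ``target_rate`` (must divide the source rate)."""
    factor = epochs.sfreq / target_rate
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"target rate {target_rate} must integer-divide {epochs.sfreq}"
        )
    factor = int(round(factor))
    out = epochs.copy()
    out.data = out.data[:, :, ::factor]
    out.times = out.times[::factor]
    out.sfreq = target_rate
    return out


def condition_averages(
    epochs: EpochSet,
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Mean waveform (channels x time) and retained count per condition.

    Conditions with zero retained trials map to None; downstream contrasts
    involving them must exclude the participant.
    """
    cond = np.asarray(epochs.conditions)
    keep = ~epochs.rejected
    averages: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for c in CONDITIONS:
        sel = (cond == c) & keep
        counts[c] = int(sel.sum())
        averages[c] = epochs.data[sel].mean(axis=0) if counts[c] else None
    return averages, counts


def preprocess(
    epochs: EpochSet, config: PreprocConfig | None = None,
    ica_hook=None, bad_channels: tuple[str, ...] = (),
) -> EpochSet:
    """Run the full fixed-order chain on one participant's epochs.

    ``ica_hook`` is an optional callable EpochSet -> EpochSet applied after
    filtering (external ocular-correction step; identity by default).
    """
    config = config or PreprocConfig()
    out = filter_epochs(epochs, config)
    if ica_hook is not None:
        out = ica_hook(out)
    out = baseline_correct(out, config.baseline_window)
    out = reject_artifacts(out, config)
    out = rereference_mastoids(out)
    for bad in bad_channels:
        out = interpolate_channel(out, bad)
    if out.sfreq != config.target_rate:
        out = downsample(out, config.target_rate)
    return out


def rejection_log(epochs: EpochSet) -> dict[str, int]:
    """Per-rule rejection counts for run logging."""
    log: dict[str, int] = {"total": int(epochs.rejected.sum()),
                           "retained": int((~epochs.rejected).sum())}
    for reason in epochs.reject_reason:
        if reason is not None:
            rule = reason.split(":")[0]
            log[rule] = log.get(rule, 0) + 1
    return log
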