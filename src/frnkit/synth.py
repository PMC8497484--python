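"""Synthetic epoched EEG and startle EMG with known ground truth.

The generator emulates the geometry of the shock-locked recordings: a
frontocentral RPE-signed component (default 150-260 ms, centred on C2), a
posterior later component with the reversed sign convention (390-480 ms,
POz), an intensity-scaled salience component, 1/f background noise with a
shared across-channel part, and injectable blink/jump/flatline artifacts
matched to the preprocessing rejection rules.  Effect amplitudes are free
simulation parameters, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import INTENSITY_STEP, POSITIVE_RPE, TrialSchedule
from .epochs import EpochSet
from .layout import ChannelLayout, load_default_layout

#: Gaussian scalp-gain width (radians): gain 0.5 at ~1.2 electrode spacings,
#: making the component maximum unambiguous at its centre electrode
SPATIAL_SIGMA = 0.33

EPOCH_START_MS = -300.0
EPOCH_STOP_MS = 700.0


@dataclass(frozen=True)
class GroundTruthEffects:
    """Injected component amplitudes, windows and centres.

    Sign convention: ``rpe_amplitude > 0`` makes the positive-RPE cells
    (LP, HP) more positive; the late component uses the opposite
    convention; ``salience_gain`` scales voltage with shock-intensity step
    (small = 1, medium = 2, large = 3).  Amplitudes in microvolts.
    """

    rpe_amplitude: float = 1.0
    rpe_window: tuple[float, float] = (150.0, 260.0)
    rpe_center: str = "C2"
    late_amplitude: float = 0.5
    late_window: tuple[float, float] = (390.0, 480.0)
    late_center: str = "POz"
    salience_gain: float = 0.5
    salience_window: tuple[float, float] = (100.0, 300.0)
    salience_center: str = "FCz"
    noise_exponent: float = 1.0
    noise_rms: float = 5.0
    artifact_rates: dict = field(
        default_factory=lambda: {"blink": 0.02, "jump": 0.01, "flat": 0.005}
    )

    def __post_init__(self) -> None:
        for w in (self.rpe_window, self.late_window, self.salience_window):
            if not (EPOCH_START_MS <= w[0] < w[1] <= EPOCH_STOP_MS):
                raise ValueError(f"window {w} outside epoch")
        for k, v in self.artifact_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"artifact rate {k}={v} outside [0, 1]")


def raised_cosine(times_ms: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Unit-peak raised-cosine (Hann) bump supported on ``window``."""
    t0, t1 = window
    phase = (times_ms - t0) / (t1 - t0)
    bump = np.where((phase >= 0) & (phase <= 1),
                    0.5 * (1.0 - np.cos(2.0 * np.pi * phase)), 0.0)
    return bump


def _scalp_gain(layout: ChannelLayout, center: str,
                sigma: float = SPATIAL_SIGMA) -> np.ndarray:
    """Gaussian gain in great-circle distance from ``center``; 0 off-scalp."""
    if center not in layout.names:
        raise ValueError(f"unknown centre channel {center!r}")
    d = layout.great_circle()[layout.index(center)]
    gain = np.exp(-0.5 * (d / sigma) ** 2)
    for name in layout.non_scalp:
        if name in layout.names:
            gain[layout.index(name)] = 0.0
    return gain


def one_over_f_noise(
    rng: np.random.Generator, n_traces: int, n_times: int,
    sfreq: float, exponent: float, rms: float,
) -> np.ndarray:
    """1/f^exponent (power) noise, each trace normalized to exact RMS."""
    if rms == 0.0:
        return np.zeros((n_traces, n_times))
    n_freq = n_times // 2 + 1
    freqs = np.fft.rfftfreq(n_times, 1.0 / sfreq)
    amp = np.zeros(n_freq)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_traces, n_freq))
            + 1j * rng.standard_normal((n_traces, n_freq))) * amp
    x = np.fft.irfft(spec, n=n_times, axis=-1)
    scale = x.std(axis=-1, keepdims=True)
    scale[scale == 0] = 1.0
    return x / scale * rms


def simulate_epochs(
    schedule: TrialSchedule,
    effects: GroundTruthEffects | None = None,
    layout: ChannelLayout | None = None,
    sampling_rate: float = 500.0,
    seed: int = 0,
    return_truth: bool = False,
):
    """Simulate shock-locked epochs (-300..700 ms) for one participant.

    Each trial is 1/f noise (independent + shared across channels, mixed
    half/half) plus condition-dependent components spatially weighted by a
    Gaussian gain around their centre channels.  Artifact trials are drawn
    at the configured rates (mutually exclusive classes) and shaped so the
    preprocessing rules detect exactly them: blink (frontal low-frequency
    deflection > 100 uV), jump (bipolar one-sample step > 50 uV/ms), flat
    (all-channel peak-to-peak < 12 uV).

    With ``return_truth`` the injected artifact classes per trial are also
    returned.
    """
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    if sampling_rate < 100.0:
        raise ValueError("sampling_rate must be >= 100 Hz")
    effects = effects or GroundTruthEffects()
    layout = layout or load_default_layout()
    rng = np.random.default_rng(seed)

    dt = 1000.0 / sampling_rate
    times = np.arange(EPOCH_START_MS, EPOCH_STOP_MS, dt)
    n_times = len(times)
    n_trials = len(schedule)
    n_ch = layout.n_channels

    gains = {
        "rpe": _scalp_gain(layout, effects.rpe_center),
        "late": _scalp_gain(layout, effects.late_center),
        "sal": _scalp_gain(layout, effects.salience_center),
    }
    bumps = {
        "rpe": raised_cosine(times, effects.rpe_window),
        "late": raised_cosine(times, effects.late_window),
        "sal": raised_cosine(times, effects.salience_window),
    }

    # artifact class per trial (exclusive; "" = clean)
    classes = np.array([""] * n_trials, dtype=object)
    u = rng.random(n_trials)
    r = effects.artifact_rates
    edges = np.cumsum([r.get("blink", 0), r.get("jump", 0), r.get("flat", 0)])
    classes[u < edges[0]] = "blink"
    classes[(u >= edges[0]) & (u < edges[1])] = "jump"
    classes[(u >= edges[1]) & (u < edges[2])] = "flat"

    m1 = layout.index("M1") if "M1" in layout.names else None
    blink_gain = None
    if "Fpz" in layout.names:
        blink_gain = _scalp_gain(layout, "Fpz", sigma=0.8)
    scalp_idx = layout.scalp_indices

    data = np.empty((n_trials, n_ch, n_times))
    for i, trial in enumerate(schedule.trials):
        shared = one_over_f_noise(rng, 1, n_times, sampling_rate,
                                  effects.noise_exponent, 1.0)
        indep = one_over_f_noise(rng, n_ch, n_times, sampling_rate,
                                 effects.noise_exponent, 1.0)
        if effects.noise_rms > 0:
            noise = 0.5 * shared + 0.5 * indep
            noise *= effects.noise_rms / noise.std(axis=-1, keepdims=True)
        else:
            noise = np.zeros((n_ch, n_times))

        x = noise
        rpe_sign = 1.0 if trial.condition in POSITIVE_RPE else -1.0
        x = x + np.outer(gains["rpe"],
                         rpe_sign * effects.rpe_amplitude * bumps["rpe"])
        x = x + np.outer(gains["late"],
                         -rpe_sign * effects.late_amplitude * bumps["late"])
        step = INTENSITY_STEP[trial.outcome_level]
        x = x + np.outer(gains["sal"],
                         step * effects.salience_gain * bumps["sal"])

        if classes[i] == "blink":
            # frontal slow deflection well above the 100 uV absolute rule
            onset = rng.uniform(50.0, 400.0)
            x = x + np.outer(200.0 * blink_gain,
                             raised_cosine(times, (onset, onset + 300.0)))
        elif classes[i] == "jump":
            # bipolar one-sample flip: gradient > 50 uV/ms, |v| < 100 uV
            ch = rng.choice(scalp_idx)
            j = rng.integers(n_times // 4, 3 * n_times // 4)
            amp = 40.0 + 25.0 * dt  # step of 2*amp across one sample interval
            x[ch, j] += -amp
            x[ch, j + 1] += amp
        elif classes[i] == "flat":
            # dead recording: rescale everything to a tiny range
            ptp = np.ptp(x[scalp_idx])
            if ptp > 0:
                x = x * (6.0 / ptp)

        if m1 is not None:  # recorded against the left mastoid
            x[m1] = 0.0
        data[i] = x

    epochs = EpochSet(
        participant="sim",
        data=data,
        sfreq=sampling_rate,
        times=times,
        conditions=schedule.conditions,
        layout=layout,
    )
    if return_truth:
        return epochs, classes
    return epochs


# ---------------------------------------------------------------------------
# startle EMG


@dataclass
class StartleRaw:
    """Raw suborbital EMG traces around noise-burst onsets (-100..400 ms)."""

    data: np.ndarray  # (n_trials, n_times) microvolts
    sfreq: float
    times: np.ndarray  # ms
    stakes: list[str]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def _emg_chain_gain(sfreq: float, highpass_hz: float = 28.0,
                    notch_hz: tuple[float, ...] = (60.0, 50.0)) -> float:
    """RMS fraction of white noise surviving the startle filter chain."""
    from scipy import signal

    sos = [signal.butter(4, highpass_hz, "highpass", fs=sfreq, output="sos")]
    for f0 in notch_hz:
        if f0 < sfreq / 2.0:
            b, a = signal.iirnotch(f0, 30.0, fs=sfreq)
            sos.append(signal.tf2sos(b, a))
    w = np.linspace(0.0, np.pi, 2048)
    _, h = signal.sosfreqz(np.vstack(sos), worN=w)
    # zero-phase (forward-backward) application squares the magnitude
    return float(np.sqrt(np.mean(np.abs(h) ** 4)))


def simulate_startle_trials(
    schedule: TrialSchedule,
    base_amplitude: float = 8.0,
    stakes_delta: float = 0.91,
    response_rate: float = 0.5,
    latency_ms: float = 120.0,
    seed: int = 0,
    sampling_rate: float = 500.0,
    artifact_rate: float = 0.05,
    baseline_rms: float = 0.8,
    return_truth: bool = False,
):
    """Simulate raw EMG around each noise burst of the schedule.

    With probability ``response_rate`` a startle burst is present: a
    band-limited high-frequency carrier under a raised-cosine envelope
    peaking at ``latency_ms`` (half-width ~50 ms), scaled so the rectified,
    50 ms-smoothed trace peaks near ``base_amplitude`` (+ ``stakes_delta``
    on high-stakes trials).  Non-response trials carry only baseline EMG
    noise below the +-5 uV detection rule.  With probability
    ``artifact_rate`` a slow baseline-window deflection is added, which the
    processing chain discards as a baseline artifact.
    """
    if not 0.0 <= response_rate <= 1.0:
        raise ValueError("response_rate must be in [0, 1]")
    noise_trials = [t for t in schedule.trials if t.noise_burst]
    if not noise_trials:
        raise ValueError("schedule has no noise-burst trials")
    rng = np.random.default_rng(seed)
    dt = 1000.0 / sampling_rate
    times = np.arange(-100.0, 400.0, dt)
    n_times = len(times)

    data = np.empty((len(noise_trials), n_times))
    truth = np.empty(len(noise_trials), dtype=object)
    # rectified mean of a Gaussian carrier of sd s is s*sqrt(2/pi); the
    # 50 ms rolling mean attenuates the envelope peak and the 28 Hz
    # high-pass + notch chain removes part of the white-carrier power, so
    # the carrier is scaled up by both losses to make the processed peak
    # land near the nominal amplitude
    rect_factor = np.sqrt(2.0 / np.pi) * _emg_chain_gain(sampling_rate)
    env = raised_cosine(times, (latency_ms - 100.0, latency_ms + 100.0))
    half_win = int(round(0.025 * sampling_rate))
    peak_i = int(np.argmax(env))
    smear = float(env[peak_i - half_win : peak_i + half_win + 1].mean())
    art_env = raised_cosine(times, (-120.0, 0.0))
    for i, trial in enumerate(noise_trials):
        x = rng.standard_normal(n_times) * baseline_rms
        responded = rng.random() < response_rate
        if responded:
            amp = base_amplitude + (stakes_delta if trial.stakes == "high" else 0.0)
            x = x + rng.standard_normal(n_times) * env * (
                amp / (rect_factor * smear)
            )
        artifact = rng.random() < artifact_rate
        if artifact:
            # high-frequency burst in the baseline window (e.g. a facial
            # clench); survives the 28 Hz high-pass and trips the +-5 uV
            # baseline rule after rectification
            x = x + rng.standard_normal(n_times) * art_env * (12.0 / rect_factor)
        truth[i] = "artifact" if artifact else ("startle" if responded else "none")
        data[i] = x

    raw = StartleRaw(data=data, sfreq=sampling_rate, times=times,
                     stakes=[t.stakes for t in noise_trials])
    if return_truth:
        return raw, truth
    return raw
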