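"""Startle-EMG processing and trial-count-weighted group statistics.

Suborbital EMG around each noise burst is high-passed at 28 Hz (plus 50/60
Hz notches), rectified, averaged in a centred rolling 50 ms window and
baseline-corrected from -50..0 ms.  Trials whose baseline exceeds +-5 uV
are artifacts; trials with no 0-200 ms sample beyond +-5 uV are
non-startle; the rest are valid and enter per-participant averages.
Because valid-trial counts vary widely across participants, group tests
and correlations weight participants by those counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy import stats as sps

from .synth import StartleRaw

DETECTION_UV = 5.0
OUTLIER_Z = 3.29


@dataclass
class StartleSet:
    """Processed (rectified, smoothed, baselined) startle trials."""

    traces: np.ndarray  # (n_trials, n_times), processed, microvolts
    times: np.ndarray  # ms
    sfreq: float
    stakes: list[str]
    validity: np.ndarray  # "valid" | "baseline_artifact" | "non_startle"

    def valid_mask(self) -> np.ndarray:
        return self.validity == "valid"

    def average(self, stakes: str | None = None) -> np.ndarray | None:
        """Mean processed trace over valid trials (optionally one stakes level)."""
        sel = self.valid_mask()
        if stakes is not None:
            sel &= np.asarray(self.stakes) == stakes
        return self.traces[sel].mean(axis=0) if sel.any() else None

    def amplitude_at(self, latency_ms: float = 120.0,
                     stakes: str | None = None) -> float | None:
        avg = self.average(stakes)
        if avg is None:
            return None
        return float(avg[np.argmin(np.abs(self.times - latency_ms))])

    def mean_amplitude(self, window=(100.0, 140.0),
                       stakes: str | None = None) -> float | None:
        avg = self.average(stakes)
        if avg is None:
            return None
        mask = (self.times >= window[0]) & (self.times <= window[1])
        return float(avg[mask].mean())

    def counts(self) -> dict[str, int]:
        out = {"valid": 0, "baseline_artifact": 0, "non_startle": 0}
        for v in self.validity:
            out[v] += 1
        out["valid_high"] = int(
            (self.valid_mask() & (np.asarray(self.stakes) == "high")).sum()
        )
        out["valid_low"] = int(
            (self.valid_mask() & (np.asarray(self.stakes) == "low")).sum()
        )
        return out


def rolling_mean(x: np.ndarray, sfreq: float, window_ms: float = 50.0) -> np.ndarray:
    """Centred rolling mean over ``window_ms``; edges use the truncated window."""
    x = np.asarray(x, float)
    win = max(1, int(round(window_ms / 1000.0 * sfreq)))
    kernel = np.ones(win)
    sums = np.apply_along_axis(
        lambda v: np.convolve(v, kernel, mode="same"), -1, x
    )
    counts = np.convolve(np.ones(x.shape[-1]), kernel, mode="same")
    return sums / counts


def process_startle(
    raw: StartleRaw,
    highpass_hz: float = 28.0,
    notch_hz: tuple[float, ...] = (60.0, 50.0),
    window_ms: float = 50.0,
    baseline: tuple[float, float] = (-50.0, 0.0),
    detection_uv: float = DETECTION_UV,
) -> StartleSet:
    """Run the EMG chain and classify every trial.

    Chain: 28 Hz high-pass + notches (zero-phase) -> rectify -> centred
    rolling 50 ms mean (edges truncated) -> subtract the -50..0 ms mean.
    The baseline-artifact rule is evaluated on the rectified smoothed
    signal before baseline subtraction.
    """
    if raw.times[0] > -100.0 or raw.times[-1] < 399.0 - 1000.0 / raw.sfreq:
        raise ValueError("traces must cover -100..400 ms")
    sos = [signal.butter(4, highpass_hz, "highpass", fs=raw.sfreq, output="sos")]
    for f0 in notch_hz:
        if f0 < raw.sfreq / 2.0:
            b, a = signal.iirnotch(f0, 30.0, fs=raw.sfreq)
            sos.append(signal.tf2sos(b, a))
    sos = np.vstack(sos)
    filtered = signal.sosfiltfilt(sos, raw.data, axis=-1)
    rectified = np.abs(filtered)

    smoothed = rolling_mean(rectified, raw.sfreq, window_ms)

    base_mask = (raw.times >= baseline[0]) & (raw.times <= baseline[1])
    response_mask = (raw.times >= 0.0) & (raw.times <= 200.0)
    validity = np.empty(raw.n_trials, dtype=object)
    traces = np.empty_like(smoothed)
    for i in range(raw.n_trials):
        pre = smoothed[i]
        if np.abs(pre[base_mask]).max() > detection_uv:
            validity[i] = "baseline_artifact"
        elif np.abs(pre[response_mask] - pre[base_mask].mean()).max() <= detection_uv:
            validity[i] = "non_startle"
        else:
            validity[i] = "valid"
        traces[i] = pre - pre[base_mask].mean()
    return StartleSet(traces=traces, times=raw.times.copy(), sfreq=raw.sfreq,
                      stakes=list(raw.stakes), validity=validity)


# ---------------------------------------------------------------------------
# weighted group statistics


def _weighted_moments(x: np.ndarray, w: np.ndarray, n_eff: int):
    """Weighted mean and sd with weights rescaled to sum to ``n_eff``."""
    w = w * (n_eff / w.sum())
    mean = float((w * x).sum() / n_eff)
    var = float((w * (x - mean) ** 2).sum() / (n_eff - 1))
    return mean, np.sqrt(var)


def weighted_paired_test(
    high: np.ndarray, low: np.ndarray, weights: np.ndarray,
    n_eff: int | None = None, ci: float = 0.95,
) -> dict:
    """Trial-count-weighted paired t test on high - low differences.

    Weights are trial counts, treated as relative frequencies and rescaled
    to sum to the number of independent participants ``n_eff`` (default:
    the number of positive-weight rows, so zero-weighting a participant is
    identical to excluding them; callers collapsing duplicate rows of the
    same participant pass ``n_eff`` explicitly).  t = mean/(sd/sqrt(N)),
    df = N - 1, d = mean/sd, CI from the central t.
    """
    high = np.asarray(high, float)
    low = np.asarray(low, float)
    w = np.asarray(weights, float)
    if not (len(high) == len(low) == len(w)):
        raise ValueError("high, low and weights must have equal length")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    keep = w > 0
    diffs, w = (high - low)[keep], w[keep]
    n = int(n_eff) if n_eff is not None else int(keep.sum())
    if n < 3:
        raise ValueError("need at least 3 participants with both conditions")
    mean, sd = _weighted_moments(diffs, w, n)
    if sd == 0:
        return {"mean_diff": mean, "sd": 0.0, "n": n, "t": np.inf * np.sign(mean),
                "df": n - 1, "p": 0.0 if mean else 1.0, "d": np.inf * np.sign(mean),
                "ci_low": mean, "ci_high": mean, "degenerate": True}
    se = sd / np.sqrt(n)
    t = mean / se
    tcrit = sps.t.ppf(0.5 + ci / 2.0, n - 1)
    return {"mean_diff": mean, "sd": sd, "n": n, "t": float(t), "df": n - 1,
            "p": float(2.0 * sps.t.sf(abs(t), n - 1)), "d": float(mean / sd),
            "ci_low": mean - tcrit * se, "ci_high": mean + tcrit * se,
            "degenerate": False}


def weighted_correlation(
    x: np.ndarray, y: np.ndarray, weights: np.ndarray,
    n_eff: int | None = None,
) -> dict:
    """Weighted Pearson and Spearman correlations with t-based p values.

    Pearson r comes from weighted covariances; Spearman rho is the
    weighted Pearson correlation of (unweighted) rank-transformed data;
    p = two-sided from t = r sqrt(N-2)/sqrt(1-r^2) with N independent
    participants.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(weights, float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y and weights must have equal length")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    n = int(n_eff) if n_eff is not None else len(x)
    if n < 4:
        raise ValueError("need at least 4 participants")

    def wpearson(a, b):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            raise ValueError("zero variance: correlation undefined")
        wn = w / w.sum()
        ma, mb = (wn * a).sum(), (wn * b).sum()
        cov = (wn * (a - ma) * (b - mb)).sum()
        va = (wn * (a - ma) ** 2).sum()
        vb = (wn * (b - mb) ** 2).sum()
        return float(cov / np.sqrt(va * vb))

    def p_of(r):
        if abs(r) >= 1.0:
            return 0.0
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        return float(2.0 * sps.t.sf(abs(t), n - 2))

    r = wpearson(x, y)
    rho = wpearson(sps.rankdata(x), sps.rankdata(y))
    return {"pearson_r": r, "pearson_p": p_of(r),
            "spearman_rho": rho, "spearman_p": p_of(rho), "n": n}


def outlier_screen(values: np.ndarray, z_crit: float = OUTLIER_Z) -> np.ndarray:
    """Flag values with |z| strictly greater than ``z_crit``."""
    x = np.asarray(values, float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros(len(x), dtype=bool)
    return np.abs((x - x.mean()) / sd) > z_crit


def frn_amplitude(
    condition_averages: dict, channel_names, times,
    channel: str = "C2", window: tuple[float, float] = (150.0, 260.0),
) -> float:
    """FRN amplitude = mean LN - HP difference at one channel over a window."""
    ci = list(channel_names).index(channel)
    times = np.asarray(times)
    mask = (times >= window[0]) & (times <= window[1])
    diff = np.asarray(condition_averages["LN"]) - np.asarray(condition_averages["HP"])
    return float(diff[ci, mask].mean())


def startle_summary_frame(per_participant: list[dict]) -> pd.DataFrame:
    """Tabular per-participant startle summary (counts and amplitudes)."""
    return pd.DataFrame(
        per_participant,
        columns=["participant", "valid", "baseline_artifact", "non_startle",
                 "valid_high", "valid_low", "amp_high", "amp_low", "amp_120"],
    )
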