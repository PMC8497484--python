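"""Parameter-recovery and calibration experiments on synthetic studies.

These harnesses define the package's validation conditions: ground-truth
effects injected at fixed amplitudes relative to noise, analysed with the
same machinery a real study would use.  They back both the test suite and
the acceptance script.
"""

from __future__ import annotations

import dataclasses
from itertools import product

import numpy as np

from . import bayes, cluster, pipeline, startle
from .design import generate_schedule
from .io import RunConfig
from .layout import load_default_layout, scalp_adjacency
from .synth import GroundTruthEffects, simulate_startle_trials

#: recovery-study effects: component amplitude equal to the noise RMS
#: (component-level SNR 2 in the LN-HP difference), no competing effects
RECOVERY_AMPLITUDE = 3.5
RECOVERY_NOISE_RMS = 3.5

#: fronto-central/parietal strip used for reduced-grid encoder analyses
ENCODER_REGION = (
    "F2", "Fz", "FC1", "FCz", "FC2", "FC4", "C1", "Cz", "C2", "C4",
    "CP1", "CPz", "CP2", "CP4", "P1", "Pz", "P2", "P4",
    "PO3", "POz", "PO4", "O1", "Oz", "O2",
)


def _study_config(seed: int, effects: GroundTruthEffects,
                  n_participants: int = 44) -> RunConfig:
    return dataclasses.replace(
        RunConfig(), seed=seed, n_participants=n_participants, effects=effects
    )


def run_cluster_recovery(seed: int, n_perm: int = 2000,
                         late: bool = False) -> dict:
    """One LN-HP cluster-recovery run on a 44-participant synthetic study.

    Injects a C2-centred RPE component (or a POz-centred late component
    with ``late=True``), runs the cluster-randomisation test, and reports
    whether exactly one significant cluster of the expected sign peaks at
    the centre channel inside the component window.
    """
    if late:
        effects = GroundTruthEffects(
            rpe_amplitude=0.0, late_amplitude=-RECOVERY_AMPLITUDE,
            salience_gain=0.0, noise_rms=RECOVERY_NOISE_RMS, artifact_rates={},
        )
        expect_sign, center, window = -1, "POz", (390.0, 480.0)
    else:
        effects = GroundTruthEffects(
            rpe_amplitude=-RECOVERY_AMPLITUDE, late_amplitude=0.0,
            salience_gain=0.0, noise_rms=RECOVERY_NOISE_RMS, artifact_rates={},
        )
        expect_sign, center, window = 1, "C2", (150.0, 260.0)
    cfg = _study_config(seed, effects)
    layout = load_default_layout()
    adjacency = scalp_adjacency(layout, cfg.adjacency_radius)
    avgs, _, names, times = pipeline.simulate_group_averages(cfg)
    wave = pipeline.scalp_contrast(
        pipeline.contrast_wave(avgs, "LN", "HP", names, times), layout
    )
    res = cluster.run_cluster_test(
        wave, adjacency,
        cluster.ClusterConfig(n_perm=n_perm, seed=seed),
    )
    sig = [c for c in res if c.corrected_p < 0.05]
    ok = (
        len(sig) == 1
        and sig[0].sign == expect_sign
        and wave.channel_names[sig[0].peak[0]] == center
        and window[0] <= times[sig[0].peak[1]] <= window[1]
    )
    out = {"recovered": bool(ok), "n_significant": len(sig)}
    if sig:
        out["peak_channel"] = wave.channel_names[sig[0].peak[0]]
        out["peak_time_ms"] = float(times[sig[0].peak[1]])
        out["corrected_p"] = float(sig[0].corrected_p)
    return out


def run_type1_batch(n_sims: int = 500, n_participants: int = 44,
                    n_channels: int = 10, n_times: int = 100,
                    n_perm: int = 1000, seed: int = 0) -> float:
    """Family-wise false-positive rate of the cluster test on null maps."""
    adjacency = np.zeros((n_channels, n_channels), dtype=bool)
    for i in range(n_channels - 1):
        adjacency[i, i + 1] = adjacency[i + 1, i] = True
    rng = np.random.default_rng(seed)
    names = tuple(f"c{i}" for i in range(n_channels))
    times = np.arange(n_times, dtype=float)
    hits = 0
    for k in range(n_sims):
        data = rng.standard_normal((n_participants, n_channels, n_times))
        wave = cluster.ContrastWave(data, "null", names, times)
        res = cluster.run_cluster_test(
            wave, adjacency,
            cluster.ClusterConfig(n_perm=n_perm, seed=seed * 100_003 + k),
        )
        hits += any(c.corrected_p < 0.05 for c in res)
    return hits / n_sims


def run_perm_enumeration(seed: int = 0, n_perm: int = 50_000,
                         n_participants: int = 10) -> dict:
    """Monte-Carlo vs exhaustive sign-flip p on a 1-channel x 8-sample map.

    Uses the (b+1)/(m+1)-free plain comparison on both sides so the two
    estimates target the same quantity; returns both p values and the
    binomial standard error of the Monte-Carlo estimate.
    """
    rng = np.random.default_rng(seed)
    data = rng.normal(1.0, 1.0, (n_participants, 1, 8))
    wave = cluster.ContrastWave(data, "enum", ("c0",), np.arange(8.0))
    adjacency = np.zeros((1, 1), dtype=bool)
    cfg = cluster.ClusterConfig(n_perm=n_perm, min_size=2, seed=seed,
                                p_estimator="plain")
    res = cluster.run_cluster_test(wave, adjacency, cfg)
    if not res:
        raise RuntimeError("enumeration study produced no cluster")
    top = res[0]
    signs = np.array(list(product([-1.0, 1.0], repeat=n_participants)))
    null = cluster._null_from_signs(wave, adjacency, cfg, signs)
    exact = float((null >= abs(top.mass)).mean())
    se = float(np.sqrt(max(exact * (1 - exact), 1e-12) / n_perm))
    return {"mc_p": float(top.mc_p), "exact_p": exact, "binomial_se": se,
            "mass": float(top.mass)}


def run_encoder_recovery(kind: str, seed: int) -> dict:
    """Encoder-map selectivity run on the reduced fronto-central grid.

    ``kind``: "rpe" injects an RPE-positivity component at C2 (150-260
    ms), "salience" an intensity-scaled component at FCz, "flat" nothing.
    Reports which encoders produced thresholded clusters and whether the
    expected selectivity held.
    """
    if kind == "rpe":
        effects = GroundTruthEffects(
            rpe_amplitude=RECOVERY_AMPLITUDE, late_amplitude=0.0,
            salience_gain=0.0, noise_rms=RECOVERY_NOISE_RMS, artifact_rates={},
        )
    elif kind == "salience":
        effects = GroundTruthEffects(
            rpe_amplitude=0.0, late_amplitude=0.0,
            salience_gain=RECOVERY_AMPLITUDE / 2.0,
            noise_rms=RECOVERY_NOISE_RMS, artifact_rates={},
        )
    elif kind == "flat":
        effects = GroundTruthEffects(
            rpe_amplitude=0.0, late_amplitude=0.0, salience_gain=0.0,
            noise_rms=RECOVERY_NOISE_RMS, artifact_rates={},
        )
    else:
        raise ValueError(f"unknown kind {kind!r}")
    cfg = _study_config(seed, effects)
    layout = load_default_layout()
    sub = layout.subset([n for n in layout.names if n in ENCODER_REGION])
    adjacency = scalp_adjacency(sub, cfg.adjacency_radius)
    idx = [layout.index(n) for n in sub.names]
    avgs, _, _, times = pipeline.simulate_group_averages(cfg)
    sub_avgs = [
        {c: np.asarray(p[c])[idx] for c in ("LP", "LN", "HP", "HN")}
        for p in avgs
    ]
    emap = bayes.encoder_map(sub_avgs, sub.names, times, adjacency,
                             prior_scale=cfg.prior_scale,
                             threshold=cfg.evidence_threshold,
                             min_size=cfg.min_cluster_size)
    clustered = {enc: bool(emap.clusters[enc]) for enc in bayes.ENCODERS}
    c2 = sub.names.index("C2")
    window = (times >= 150) & (times <= 260)
    out = {"clusters": clustered,
           "rpe_plus_max_in_window": float(
               emap.probabilities["RPE+"][c2, window].max())}
    if kind == "rpe":
        out["ok"] = (clustered["RPE+"] and not clustered["RPE-"]
                     and not clustered["SAL+"] and not clustered["SAL-"]
                     and out["rpe_plus_max_in_window"] > 0.975)
    elif kind == "salience":
        out["ok"] = (clustered["SAL+"] and not clustered["SAL-"]
                     and not clustered["RPE+"] and not clustered["RPE-"])
    else:
        out["ok"] = not any(
            clustered[e] for e in ("RPE+", "RPE-", "SAL+", "SAL-")
        )
    return out


def run_startle_recovery(seed: int, n_participants: int = 42) -> dict:
    """Group startle run with a fixed stakes effect; recovers the delta.

    Between-participant variability is disabled so the weighted paired
    test's mean difference estimates the generator's ``stakes_delta``
    directly.
    """
    cfg = dataclasses.replace(
        RunConfig(), seed=seed, n_participants=n_participants,
        startle_delta_sd=0.0,
    )
    _, results = pipeline.startle_group(cfg)
    test = results["stakes_test"]
    return {"recovered_delta": float(test["mean_diff"]),
            "true_delta": cfg.startle_stakes_delta,
            "t": float(test["t"]), "n": int(test["n"])}


def run_startle_validity_calibration(seed: int = 0, n_participants: int = 20,
                                     response_rate: float = 0.5,
                                     artifact_rate: float = 0.05) -> dict:
    """Pooled validity-class fractions against the generator's rates."""
    counts = {"valid": 0, "baseline_artifact": 0, "non_startle": 0, "n": 0}
    peaks = []
    for i in range(n_participants):
        sched = generate_schedule(seed=pipeline.participant_seed(seed, i, 0))
        raw = simulate_startle_trials(
            sched, response_rate=response_rate, artifact_rate=artifact_rate,
            seed=pipeline.participant_seed(seed, i, 4),
        )
        sset = startle.process_startle(raw)
        c = sset.counts()
        for k in ("valid", "baseline_artifact", "non_startle"):
            counts[k] += c[k]
        counts["n"] += raw.n_trials
        avg = sset.average()
        if avg is not None:
            peaks.append(float(sset.times[int(np.argmax(avg))]))
    n = counts["n"]
    return {
        "artifact_fraction": counts["baseline_artifact"] / n,
        "artifact_rate_true": artifact_rate,
        "response_fraction": counts["valid"] / (n - counts["baseline_artifact"]),
        "response_rate_true": response_rate,
        "n_trials": n,
        "mean_peak_ms": float(np.mean(peaks)),
    }
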