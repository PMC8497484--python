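"""Group-level orchestration: simulate a study and run both analysis arms.

These functions drive the per-participant generators and the statistical
machinery end to end; they back the command-line interface and the
parameter-recovery checks.  Per-participant seeds derive deterministically
from the study seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import bayes, cluster, startle, stats
from .design import generate_schedule, score_behavior, simulate_behavior
from .io import RunConfig
from .layout import load_default_layout, scalp_adjacency
from .preprocess import (baseline_correct, condition_averages, preprocess,
                         reject_artifacts)
from .synth import simulate_epochs, simulate_startle_trials

_SEED_MOD = 2**31


def participant_seed(study_seed: int, index: int, stream: int = 0) -> int:
    """Deterministic per-participant, per-stream sub-seed below 2^31."""
    return (study_seed * 1_000_003 + index * 97 + stream * 7_919) % _SEED_MOD


def simulate_group_averages(
    cfg: RunConfig,
    full_chain: bool = False,
    analysis_rate: float | None = 100.0,
):
    """Condition averages for every participant of a synthetic study.

    With ``full_chain`` the data are generated at ``cfg.sampling_rate`` and
    run through the complete preprocessing chain; otherwise they are
    generated directly at ``analysis_rate`` and only baseline-corrected and
    artifact-screened (the geometry the group statistics consume, at a
    fraction of the cost).  Returns (averages per participant, counts per
    participant, channel names, time axis).
    """
    layout = load_default_layout()
    avgs, counts = [], []
    times = None
    for i in range(cfg.n_participants):
        schedule = generate_schedule(
            cfg.n_blocks, cfg.trials_per_block, cfg.noise_rate,
            seed=participant_seed(cfg.seed, i, 0),
        )
        rate = cfg.sampling_rate if full_chain else (analysis_rate or 100.0)
        epochs = simulate_epochs(
            schedule, cfg.effects, layout, sampling_rate=rate,
            seed=participant_seed(cfg.seed, i, 1),
        )
        if full_chain:
            epochs = preprocess(epochs, cfg.preproc)
        else:
            epochs = baseline_correct(epochs, cfg.preproc.baseline_window)
            epochs = reject_artifacts(epochs, cfg.preproc)
        avg, cnt = condition_averages(epochs)
        avgs.append(avg)
        counts.append(cnt)
        if times is None:
            times = epochs.times
    return avgs, counts, tuple(layout.names), times


def contrast_wave(
    averages: list[dict], a: str, b: str, channel_names, times
) -> cluster.ContrastWave:
    """Stack per-participant a - b difference maps into a ContrastWave."""
    usable = [p for p in averages if p.get(a) is not None and p.get(b) is not None]
    if len(usable) < 2:
        raise ValueError(f"fewer than 2 participants have both {a} and {b}")
    data = np.stack([np.asarray(p[a]) - np.asarray(p[b]) for p in usable])
    return cluster.ContrastWave(
        data=data, label=f"{a}-{b}", channel_names=tuple(channel_names),
        times=np.asarray(times),
    )


def stakes_contrast(
    averages: list[dict], channel_names, times
) -> cluster.ContrastWave:
    """High-vs-low-stakes (aggregate physical salience) contrast.

    Averages the two cells within each stakes level, so positive and
    negative RPEs occur equally often on both sides.
    """
    usable = [
        p for p in averages
        if all(p.get(c) is not None for c in ("LP", "LN", "HP", "HN"))
    ]
    if len(usable) < 2:
        raise ValueError("fewer than 2 participants have all four conditions")
    data = np.stack([
        0.5 * (np.asarray(p["HP"]) + np.asarray(p["HN"]))
        - 0.5 * (np.asarray(p["LP"]) + np.asarray(p["LN"]))
        for p in usable
    ])
    return cluster.ContrastWave(
        data=data, label="high-low", channel_names=tuple(channel_names),
        times=np.asarray(times),
    )


def scalp_contrast(wave: cluster.ContrastWave, layout) -> cluster.ContrastWave:
    """Restrict a contrast to scalp channels (order preserved)."""
    idx = layout.scalp_indices
    return cluster.ContrastWave(
        data=wave.data[:, idx, :], label=wave.label,
        channel_names=tuple(layout.names[i] for i in idx), times=wave.times,
    )


def behavior_group(cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate and score choice behaviour for the whole group."""
    rows = []
    for i in range(cfg.n_participants):
        schedule = generate_schedule(
            cfg.n_blocks, cfg.trials_per_block, cfg.noise_rate,
            seed=participant_seed(cfg.seed, i, 0),
        )
        log = simulate_behavior(
            schedule, cfg.congruence_bias, cfg.query_accuracy,
            seed=participant_seed(cfg.seed, i, 2),
            bias_sd=cfg.congruence_bias_sd,
        )
        rows.append({"participant": i, **score_behavior(schedule, log)})
    df = pd.DataFrame(rows)
    group = {
        "congruence": stats.one_sample_t(df["congruence_difference"]).as_dict(),
        "query": stats.one_sample_t(df["query_difference"]).as_dict(),
    }
    return df, group


def startle_group(
    cfg: RunConfig, frn_amplitudes: np.ndarray | None = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate, process and weight-test startle EMG for the whole group.

    Per-participant stakes effects are drawn around
    ``cfg.startle_stakes_delta`` with sd ``cfg.startle_delta_sd`` to emulate
    between-participant variability.  With ``frn_amplitudes`` (one value
    per participant) the weighted startle-FRN correlation is also computed
    over participants with valid startle data.
    """
    rng = np.random.default_rng(participant_seed(cfg.seed, 0, 3))
    rows = []
    for i in range(cfg.n_participants):
        schedule = generate_schedule(
            cfg.n_blocks, cfg.trials_per_block, cfg.noise_rate,
            seed=participant_seed(cfg.seed, i, 0),
        )
        delta = float(rng.normal(cfg.startle_stakes_delta, cfg.startle_delta_sd))
        raw = simulate_startle_trials(
            schedule, cfg.startle_base_amplitude, delta,
            cfg.startle_response_rate,
            seed=participant_seed(cfg.seed, i, 4),
        )
        sset = startle.process_startle(raw)
        cnt = sset.counts()
        rows.append(
            {"participant": i, **cnt,
             "amp_high": sset.mean_amplitude(stakes="high"),
             "amp_low": sset.mean_amplitude(stakes="low"),
             "amp_120": sset.amplitude_at(120.0)}
        )
    df = startle.startle_summary_frame(rows)
    both = df.dropna(subset=["amp_high", "amp_low"])
    results = {
        "stakes_test": startle.weighted_paired_test(
            both["amp_high"].to_numpy(), both["amp_low"].to_numpy(),
            both["valid"].to_numpy(),
        ),
        "n_excluded": int(len(df) - len(both)),
    }
    if frn_amplitudes is not None:
        ok = df["amp_120"].notna() & (df["valid"] > 0)
        results["frn_correlation"] = startle.weighted_correlation(
            df.loc[ok, "amp_120"].to_numpy(),
            np.asarray(frn_amplitudes)[ok.to_numpy()],
            df.loc[ok, "valid"].to_numpy(),
        )
    return df, results


def run_full_study(cfg: RunConfig, full_chain: bool = False) -> dict:
    """Execute the complete synthetic study and both analysis strategies.

    Returns a dict with the schedule/behaviour tables, the LN-HP cluster
    test, the encoder evidence map summary, startle statistics and the
    power calculations.
    """
    layout = load_default_layout()
    adjacency = scalp_adjacency(layout, cfg.adjacency_radius)

    avgs, counts, channel_names, times = simulate_group_averages(
        cfg, full_chain=full_chain
    )
    wave = contrast_wave(avgs, "LN", "HP", channel_names, times)
    wave = scalp_contrast(wave, layout)
    ccfg = cluster.ClusterConfig(
        n_perm=cfg.n_perm, alpha_sample=cfg.alpha_sample,
        min_size=cfg.min_cluster_size, seed=participant_seed(cfg.seed, 0, 5),
    )
    clusters = cluster.run_cluster_test(wave, adjacency, ccfg)

    scalp_idx = layout.scalp_indices
    scalp_names = [layout.names[i] for i in scalp_idx]
    scalp_avgs = [
        {c: (None if p[c] is None else np.asarray(p[c])[scalp_idx])
         for c in ("LP", "LN", "HP", "HN")}
        for p in avgs
    ]
    if cfg.encoder_channels:
        enc_layout = layout.subset(list(cfg.encoder_channels))
        enc_adj = scalp_adjacency(enc_layout, cfg.adjacency_radius)
        sel = [scalp_names.index(n) for n in cfg.encoder_channels]
        enc_avgs = [
            {c: (None if p[c] is None else p[c][sel])
             for c in ("LP", "LN", "HP", "HN")}
            for p in scalp_avgs
        ]
        enc_names = list(cfg.encoder_channels)
    else:
        enc_adj, enc_avgs, enc_names = adjacency, scalp_avgs, scalp_names
    emap = bayes.encoder_map(
        enc_avgs, enc_names, times, enc_adj,
        prior_scale=cfg.prior_scale, threshold=cfg.evidence_threshold,
        min_size=cfg.min_cluster_size,
    )

    frn = np.array([
        startle.frn_amplitude(p, scalp_names, times)
        if all(p[c] is not None for c in ("LN", "HP")) else np.nan
        for p in scalp_avgs
    ])
    behavior_df, behavior_stats = behavior_group(cfg)
    startle_df, startle_stats = startle_group(cfg, frn_amplitudes=frn)

    return {
        "config": dataclasses.asdict(cfg),
        "trial_counts": counts,
        "behavior": {"table": behavior_df, "group": behavior_stats},
        "cluster_test": cluster.clusters_to_dict(
            clusters, wave.channel_names, times
        ),
        "encoder_map": bayes.evidence_map_to_dict(emap),
        "startle": {"table": startle_df, "group": startle_stats},
        "power": {
            "n_for_power_80": stats.minimal_n(0.80, 1.0, 0.05, "one"),
            "n_for_power_99": stats.minimal_n(0.99, 1.0, 0.05, "one"),
        },
    }
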