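# frnkit

Analysis pipeline for shock-locked ERP studies of reward prediction
error (RPE), built around a fully synthetic, ground-truth-controlled
replica of the experiment it implements.

**Who it is for.** EEG/ERP researchers who want (a) the complete analysis
chain for a 2x2 *stakes x RPE* aversive-learning design — trial-schedule
generation, preprocessing, spatiotemporal cluster-randomisation testing,
Bayesian encoder mapping, startle-EMG statistics, behavioural scoring —
and (b) a synthetic-data module that makes every stage testable without
any recordings.

## The design and the statistics

Low-stakes trials end in a small or medium electric shock, high-stakes
trials in a medium or large one, predetermined half/half, so the arrival
of the lower shock is a positive RPE and the higher a negative one.
Cells are LP, LN, HP, HN; LN and HP share the medium shock, so the
**LN − HP difference wave** varies RPE with physical salience held
constant — the feedback-related negativity (FRN) contrast.

Two analysis strategies are implemented:

1. **Cluster randomisation** (nonparametric family-wise control): a
   one-sample *t* over participants at every electrode x timepoint,
   clusters of adjacent same-sign significant samples (minimum 25),
   cluster mass Σ*t* ranked against a sign-flip Monte-Carlo null, and a
   Bonferroni step over the initially formed clusters.
2. **Encoder evidence mapping**: for each of the six pairwise condition
   contrasts a JZS Bayesian *t* test (Cauchy(0, √2/2) prior on the
   standardized effect) yields posterior probabilities over
   {greater, less, equal}; five encoders (RPE ±, salience ±, null)
   each predict a pattern across the six contrasts; an encoder's evidence
   is the product of its predicted-cell probabilities, normalized across
   encoders and thresholded at 0.975.

Startle EMG around the noise-burst probes is high-passed at 28 Hz,
rectified, smoothed in a rolling 50 ms window and baseline-corrected;
group tests weight participants by their valid startle-trial counts.

See `docs/methods.md` for models, parameter defaults and limitations.

## Worked example

```python
import dataclasses
from frnkit import (RunConfig, generate_schedule, simulate_epochs,
                    preprocess, condition_averages, run_cluster_test,
                    ClusterConfig, load_default_layout, scalp_adjacency,
                    GroundTruthEffects)
from frnkit import pipeline

# a 44-participant synthetic study with a C2-centred RPE component whose
# LN-HP difference wave is positive (amplitude -2a = +7 uV at the peak)
effects = GroundTruthEffects(rpe_amplitude=-3.5, late_amplitude=0.0,
                             noise_rms=3.5, artifact_rates={})
cfg = dataclasses.replace(RunConfig(), seed=11, n_participants=44,
                          effects=effects)
avgs, counts, names, times = pipeline.simulate_group_averages(cfg)
layout = load_default_layout()
wave = pipeline.scalp_contrast(
    pipeline.contrast_wave(avgs, "LN", "HP", names, times), layout)
clusters = run_cluster_test(wave, scalp_adjacency(layout),
                            ClusterConfig(n_perm=2000, seed=11))
best = clusters[0]
print(f"{len(clusters)} clusters; top: sign={best.sign:+d}, "
      f"size={best.size}, peak={wave.channel_names[best.peak[0]]} "
      f"at {times[best.peak[1]]:.0f} ms, corrected p={best.corrected_p:.4f}")
```

Output:

```
3 clusters; top: sign=+1, size=109, peak=C2 at 210 ms, corrected p=0.0135
```

One significant positive cluster recovers the injected component: peak at
electrode C2, 210 ms (the injected window's midpoint is 205 ms and the
analysis rate 100 Hz), with the two residual noise clusters far from
significance. Recomputing published summary statistics works directly
from printed moments:

```python
from frnkit import one_sample_t
r = one_sample_t(mean=20.73, sd=23.04, n=44)
print(round(r.t, 2), round(r.d, 2))   # 5.97 0.9
```

The command line mirrors the library
(`frnkit run-all --seed 1 --out out/` writes the schedule CSV, epochs
container, cluster and encoder JSON, startle and behaviour CSVs, group
statistics and the echoed config; see `frnkit --help` for the individual
stages).

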