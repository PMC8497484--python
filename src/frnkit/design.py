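"""Trial schedule generation and choice-behaviour simulation/scoring.

The task is a 2x2 stakes x reward-prediction-error (RPE) design delivered
with electric shocks.  Low-stakes trials end in a small or medium shock,
high-stakes trials in a medium or large shock; within each stakes level the
outcome split is exactly half/half and predetermined, so the task is
unlearnable.  Cells are labelled LP/LN/HP/HN (low/high stakes x positive/
negative RPE); LN and HP share the medium shock, making LN-HP the
salience-controlled critical contrast.  A loud white-noise burst accompanies
the stakes cue on a fixed fraction of trials for startle probing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CONDITIONS = ("LP", "LN", "HP", "HN")

#: (stakes, outcome_level) -> design cell
CELL_OF = {
    ("low", "small"): "LP",
    ("low", "medium"): "LN",
    ("high", "medium"): "HP",
    ("high", "large"): "HN",
}

#: shock-intensity step per outcome level (used by the salience encoder)
INTENSITY_STEP = {"small": 1, "medium": 2, "large": 3}

#: design cells carrying a positive RPE (smaller-than-expected shock)
POSITIVE_RPE = ("LP", "HP")


@dataclass(frozen=True)
class Trial:
    block: int  # 1-based
    stakes: str  # "high" | "low"
    outcome_level: str  # "small" | "medium" | "large"
    condition: str  # LP | LN | HP | HN
    noise_burst: bool
    noise_onset_s: float | None  # seconds into cue, in [2, 5]


@dataclass(frozen=True)
class TrialSchedule:
    trials: tuple[Trial, ...]

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def conditions(self) -> list[str]:
        return [t.condition for t in self.trials]

    @property
    def n_blocks(self) -> int:
        return max(t.block for t in self.trials)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {c: 0 for c in CONDITIONS}
        for t in self.trials:
            out[t.condition] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        """One row per trial; deterministic column order."""
        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self) + 1),
                "block": [t.block for t in self.trials],
                "stakes": [t.stakes for t in self.trials],
                "outcome_level": [t.outcome_level for t in self.trials],
                "condition": [t.condition for t in self.trials],
                "noise_burst": [t.noise_burst for t in self.trials],
                "noise_onset_s": [
                    t.noise_onset_s if t.noise_burst else np.nan
                    for t in self.trials
                ],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialSchedule":
        trials = tuple(
            Trial(
                int(r.block),
                str(r.stakes),
                str(r.outcome_level),
                str(r.condition),
                bool(r.noise_burst),
                None if pd.isna(r.noise_onset_s) else float(r.noise_onset_s),
            )
            for r in df.itertuples()
        )
        return cls(trials)


def generate_schedule(
    n_blocks: int = 5,
    trials_per_block: int = 40,
    noise_rate: float = 0.2,
    seed: int = 0,
) -> TrialSchedule:
    """Generate a balanced, seeded pseudorandom trial schedule.

    Each block holds ``trials_per_block`` trials, half high and half low
    stakes in random order; within each stakes level the two permissible
    outcomes are split exactly half/half in random order.  Exactly
    ``round(noise_rate * n_trials)`` trials carry a noise burst, stratified
    evenly across blocks, with onset uniform in 2-5 s after cue onset.
    """
    if trials_per_block % 4 != 0:
        raise ValueError(
            f"trials_per_block must be divisible by 4, got {trials_per_block}"
        )
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError(f"noise_rate must be in [0, 1], got {noise_rate}")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")

    rng = np.random.default_rng(seed)
    n_trials = n_blocks * trials_per_block
    n_noise = int(round(noise_rate * n_trials))
    # stratify noise trials across blocks as evenly as possible
    per_block = np.full(n_blocks, n_noise // n_blocks)
    extra = rng.permutation(n_blocks)[: n_noise % n_blocks]
    per_block[extra] += 1

    trials: list[Trial] = []
    half = trials_per_block // 2
    quarter = trials_per_block // 4
    for b in range(n_blocks):
        stakes = np.array(["high"] * half + ["low"] * half)
        rng.shuffle(stakes)
        outcomes = {
            "high": list(rng.permutation(["medium"] * quarter + ["large"] * quarter)),
            "low": list(rng.permutation(["small"] * quarter + ["medium"] * quarter)),
        }
        noisy = np.zeros(trials_per_block, dtype=bool)
        noisy[rng.choice(trials_per_block, per_block[b], replace=False)] = True
        for i in range(trials_per_block):
            s = str(stakes[i])
            level = str(outcomes[s].pop())
            burst = bool(noisy[i])
            # microsecond precision so the schedule round-trips through CSV
            onset = round(float(rng.uniform(2.0, 5.0)), 6) if burst else None
            trials.append(Trial(b + 1, s, level, CELL_OF[(s, level)], burst, onset))
    return TrialSchedule(tuple(trials))


# ---------------------------------------------------------------------------
# choice behaviour


@dataclass(frozen=True)
class BehaviorLog:
    """Simulated or recorded keypresses plus block-end queries.

    ``chosen_key`` has one entry per trial.  ``queries`` has one row per
    block x stakes level with the queried key and the chance-better key
    (the key whose realized chosen-outcome mean shock was lower; ties make
    the query unscoreable and are recorded as None).
    """

    chosen_key: tuple[str, ...]
    queries: tuple[tuple[int, str, str, str | None], ...]
    # rows: (block, stakes, queried_key, chance_better_key or None)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        choices = pd.DataFrame(
            {"trial": np.arange(1, len(self.chosen_key) + 1),
             "chosen_key": list(self.chosen_key)}
        )
        queries = pd.DataFrame(
            self.queries, columns=["block", "stakes", "queried_key", "chance_better_key"]
        )
        return choices, queries


def _is_win(trial: Trial) -> bool:
    """Positive RPE = the lower of the two permissible shocks arrived."""
    return trial.condition in POSITIVE_RPE


def _streams(schedule: TrialSchedule):
    """Yield (block, stakes, trial indices) for each choice stream.

    Consecutive choices are only comparable where the same fractal pair is
    on screen, i.e. within one block x stakes level.
    """
    streams: dict[tuple[int, str], list[int]] = {}
    for i, t in enumerate(schedule.trials):
        streams.setdefault((t.block, t.stakes), []).append(i)
    for (block, stakes), idx in sorted(streams.items()):
        yield block, stakes, idx


def simulate_behavior(
    schedule: TrialSchedule,
    congruence_bias: float = 0.5545,
    query_accuracy: float = 0.6295,
    seed: int = 0,
    bias_sd: float = 0.0486,
) -> BehaviorLog:
    """Simulate an outcome-sensitive agent on a fixed schedule.

    On each scoreable transition the agent acts congruently (stay after a
    positive-RPE outcome, shift after a negative one) with probability
    ``congruence_bias``; each block-end query names the chance-better key
    with probability ``query_accuracy``.  ``bias_sd`` adds participant-level
    variability: the effective bias is drawn once per call from a normal
    distribution truncated to [0, 1] (pass 0 for an exact bias).
    """
    for name, p in (("congruence_bias", congruence_bias),
                    ("query_accuracy", query_accuracy)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    bias = congruence_bias
    if bias_sd > 0:
        bias = float(np.clip(rng.normal(congruence_bias, bias_sd), 0.0, 1.0))

    chosen: dict[int, str] = {}
    for _block, _stakes, idx in _streams(schedule):
        key = rng.choice(["A", "B"])
        chosen[idx[0]] = key
        for prev, cur in zip(idx, idx[1:]):
            congruent = rng.random() < bias
            stay = congruent if _is_win(schedule.trials[prev]) else not congruent
            if not stay:
                key = "B" if key == "A" else "A"
            chosen[cur] = key

    queries = []
    for block, stakes, idx in _streams(schedule):
        better = _chance_better_key(schedule, idx, {i: chosen[i] for i in idx})
        if better is None:
            answer = rng.choice(["A", "B"])
        elif rng.random() < query_accuracy:
            answer = better
        else:
            answer = "B" if better == "A" else "A"
        queries.append((block, stakes, str(answer), better))
    return BehaviorLog(
        tuple(str(chosen[i]) for i in range(len(schedule))), tuple(queries)
    )


def _chance_better_key(
    schedule: TrialSchedule, idx: list[int], chosen: dict[int, str]
) -> str | None:
    """Key with the lower realized mean shock intensity, None on a tie."""
    sums = {"A": 0.0, "B": 0.0}
    counts = {"A": 0, "B": 0}
    for i in idx:
        k = chosen[i]
        sums[k] += INTENSITY_STEP[schedule.trials[i].outcome_level]
        counts[k] += 1
    # a key never chosen delivered no shock evidence: treat as a tie
    if counts["A"] == 0 or counts["B"] == 0:
        return None
    mean_a, mean_b = sums["A"] / counts["A"], sums["B"] / counts["B"]
    if mean_a == mean_b:
        return None
    return "A" if mean_a < mean_b else "B"


def score_behavior(
    schedule: TrialSchedule, log: BehaviorLog
) -> dict[str, int]:
    """Win-stay/lose-shift congruence and block-query accuracy differences.

    Transitions are scored between consecutive trials of the same block x
    stakes stream.  Returns signed counts: ``congruence_difference`` =
    congruent - incongruent and ``query_difference`` = correct - incorrect,
    plus the underlying counts.
    """
    if len(log.chosen_key) != len(schedule):
        raise ValueError(
            f"log has {len(log.chosen_key)} choices for {len(schedule)} trials"
        )
    congruent = incongruent = 0
    for _block, _stakes, idx in _streams(schedule):
        for prev, cur in zip(idx, idx[1:]):
            stayed = log.chosen_key[cur] == log.chosen_key[prev]
            ok = stayed if _is_win(schedule.trials[prev]) else not stayed
            congruent += ok
            incongruent += not ok

    correct = incorrect = 0
    for _block, _stakes, queried, better in log.queries:
        if better is None:  # tie: unscoreable
            continue
        if queried == better:
            correct += 1
        else:
            incorrect += 1
    return {
        "congruent_count": congruent,
        "incongruent_count": incongruent,
        "congruence_difference": congruent - incongruent,
        "query_correct": correct,
        "query_incorrect": incorrect,
        "query_difference": correct - incorrect,
    }


def n_scoreable_transitions(schedule: TrialSchedule) -> int:
    """Number of within-stream consecutive-trial transitions."""
    return sum(len(idx) - 1 for _b, _s, idx in _streams(schedule))
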