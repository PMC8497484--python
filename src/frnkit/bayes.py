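"""Bayesian evidence mapping over five condition-pattern encoders.

At every (channel, timepoint) the six pairwise contrasts of the 2x2 design
are tested with one-sample JZS Bayesian t tests (Cauchy prior on the
standardized effect, default scale sqrt(2)/2).  The Bayes factors are
converted to posterior probabilities over {greater, less, equal} per
contrast, multiplied along each encoder's predicted pattern, normalized
across the five encoders, and thresholded at 0.975 to form clusters with
the same spatial adjacency and minimum-size rule as the cluster test.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import integrate
from scipy import stats as sps

from .cluster import Cluster, _components, check_adjacency

DEFAULT_PRIOR_SCALE = np.sqrt(2.0) / 2.0

ENCODERS = ("RPE+", "RPE-", "SAL+", "SAL-", "NULL")
CONTRASTS = (
    ("HN", "HP"), ("HN", "LN"), ("HN", "LP"),
    ("HP", "LN"), ("HP", "LP"), ("LN", "LP"),
)


@dataclass(frozen=True)
class PredictionMatrix:
    """Predicted contrast directions (6 contrasts x 5 encoders)."""

    cells: dict  # {(contrast_label, encoder): ">" | "<" | "="}

    def prediction(self, contrast: tuple[str, str], encoder: str) -> str:
        return self.cells[(f"{contrast[0]}/{contrast[1]}", encoder)]

    def validate(self) -> None:
        """Structural invariants: signed encoder pairs reverse, NULL is flat."""
        flip = {">": "<", "<": ">", "=": "="}
        for a, b in (("RPE+", "RPE-"), ("SAL+", "SAL-")):
            for c in CONTRASTS:
                if self.prediction(c, a) != flip[self.prediction(c, b)]:
                    raise ValueError(f"{a}/{b} not direction-reversed at {c}")
        for c in CONTRASTS:
            if self.prediction(c, "NULL") != "=":
                raise ValueError("NULL encoder must predict no effect")


def load_prediction_matrix() -> PredictionMatrix:
    text = resources.files("frnkit.data").joinpath(
        "encoder_predictions.tsv"
    ).read_text()
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    header = lines[0].split("\t")
    cells = {}
    for line in lines[1:]:
        parts = line.split("\t")
        for enc, cell in zip(header[1:], parts[1:]):
            if cell not in (">", "<", "="):
                raise ValueError(f"bad cell {cell!r} in prediction table")
            cells[(parts[0], enc)] = cell
    pm = PredictionMatrix(cells)
    pm.validate()
    return pm


# ---------------------------------------------------------------------------
# JZS Bayes factors


def _summary(values, t, n):
    if values is not None:
        x = np.asarray(values, float)
        if x.ndim != 1 or len(x) < 2:
            raise ValueError("need a 1-D sample with n >= 2")
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance sample: t statistic undefined")
        return float(x.mean() / (sd / np.sqrt(len(x)))), len(x)
    if t is None or n is None:
        raise ValueError("provide values or both t and n")
    return float(t), int(n)


def jzs_bayes_factor(
    values=None, *, t: float | None = None, n: int | None = None,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    direction: str = "two_sided",
) -> float:
    """JZS Bayes factor BF10 for a one-sample design.

    The alternative places a Cauchy(0, ``prior_scale``) prior on the
    standardized effect delta; directional variants truncate the prior to
    the stated half-line and renormalize.  Computed by adaptive quadrature
    of the noncentral-t marginal likelihood over the substitution
    delta = prior_scale * tan(theta).
    """
    if prior_scale <= 0:
        raise ValueError("prior_scale must be > 0")
    if direction not in ("two_sided", "positive", "negative"):
        raise ValueError(f"unknown direction {direction!r}")
    t, n = _summary(values, t, n)
    df = n - 1
    rootn = np.sqrt(n)

    def integrand(theta: float) -> float:
        delta = prior_scale * np.tan(theta)
        return sps.nct.pdf(t, df, delta * rootn)

    peak = float(np.arctan((t / rootn) / prior_scale))
    if direction == "two_sided":
        lo, hi, scale = -np.pi / 2, np.pi / 2, 1.0 / np.pi
        points = [peak]
    elif direction == "positive":
        lo, hi, scale = 0.0, np.pi / 2, 2.0 / np.pi
        points = [peak] if peak > 0 else None
    else:
        lo, hi, scale = -np.pi / 2, 0.0, 2.0 / np.pi
        points = [peak] if peak < 0 else None
    m1, _ = integrate.quad(integrand, lo, hi, points=points, limit=200)
    m0 = sps.t.pdf(t, df)
    return float(scale * m1 / m0)


def _bf_grid(
    t: np.ndarray, n: int, prior_scale: float, direction: str,
    n_nodes: int = 151,
) -> np.ndarray:
    """Vectorized fixed-order Gauss-Legendre version of the JZS integral."""
    t = np.asarray(t, float)
    df = n - 1
    rootn = np.sqrt(n)
    if direction == "two_sided":
        a, b, scale = -np.pi / 2, np.pi / 2, 1.0 / np.pi
    elif direction == "positive":
        a, b, scale = 0.0, np.pi / 2, 2.0 / np.pi
    else:
        a, b, scale = -np.pi / 2, 0.0, 2.0 / np.pi
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    theta = 0.5 * (b - a) * nodes + 0.5 * (b + a)
    w = 0.5 * (b - a) * weights
    ncp = prior_scale * np.tan(theta) * rootn
    pdf = sps.nct.pdf(t.ravel()[None, :], df, ncp[:, None])
    m1 = (w[:, None] * pdf).sum(axis=0)
    m0 = sps.t.pdf(t.ravel(), df)
    return (scale * m1 / m0).reshape(t.shape)


def contrast_hypothesis_probs(
    values=None, *, t: float | None = None, n: int | None = None,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    scheme: str = "three_way",
) -> dict[str, float]:
    """Posterior probabilities over {greater, less, equal} for one contrast.

    ``three_way`` (default): equal prior mass 1/3 on each hypothesis, with
    p_greater : p_less : p_equal = BF+ : BF- : 1 (BF+- are the one-sided
    JZS factors against the point null).  ``two_way`` instead scores each
    hypothesis against its complement pairwise: p_dir = BF_dir/(1+BF_dir),
    p_equal = 1/(1+BF10), then renormalizes the triple.
    """
    t, n = _summary(values, t, n)
    bf_pos = jzs_bayes_factor(t=t, n=n, prior_scale=prior_scale,
                              direction="positive")
    bf_neg = jzs_bayes_factor(t=t, n=n, prior_scale=prior_scale,
                              direction="negative")
    if scheme == "three_way":
        raw = np.array([bf_pos, bf_neg, 1.0])
    elif scheme == "two_way":
        bf_two = 0.5 * (bf_pos + bf_neg)
        raw = np.array([bf_pos / (1 + bf_pos), bf_neg / (1 + bf_neg),
                        1.0 / (1 + bf_two)])
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    probs = raw / raw.sum()
    return {"p_greater": float(probs[0]), "p_less": float(probs[1]),
            "p_equal": float(probs[2])}


def encoder_evidence(
    contrast_probs: dict[tuple[str, str], dict[str, float]],
    matrix: PredictionMatrix | None = None,
) -> dict[str, float]:
    """Normalized compound probability per encoder.

    The compound is the product over the six contrasts of the probability
    assigned to the encoder's predicted outcome; normalization divides by
    the sum of the five compounds.
    """
    matrix = matrix or load_prediction_matrix()
    key = {">": "p_greater", "<": "p_less", "=": "p_equal"}
    compounds = {}
    for enc in ENCODERS:
        prod = 1.0
        for c in CONTRASTS:
            prod *= contrast_probs[c][key[matrix.prediction(c, enc)]]
        compounds[enc] = prod
    total = sum(compounds.values())
    if total <= 0:
        raise ValueError("all compound probabilities vanished")
    return {enc: compounds[enc] / total for enc in ENCODERS}


# ---------------------------------------------------------------------------
# whole-map evidence


@dataclass
class EncoderEvidenceMap:
    """Per-sample normalized encoder probabilities plus thresholded clusters."""

    probabilities: dict  # encoder -> (n_channels, n_times) array
    clusters: dict  # encoder -> list[Cluster]
    channel_names: tuple[str, ...]
    times: np.ndarray
    threshold: float

    def winning(self) -> np.ndarray:
        """Index into ENCODERS of the most probable encoder per sample."""
        stack = np.stack([self.probabilities[e] for e in ENCODERS])
        return stack.argmax(axis=0)


def encoder_map(
    condition_averages: list[dict],
    channel_names,
    times,
    adjacency: np.ndarray,
    matrix: PredictionMatrix | None = None,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    threshold: float = 0.975,
    min_size: int = 25,
    scheme: str = "three_way",
) -> EncoderEvidenceMap:
    """Evidence map over the five encoders from per-participant averages.

    ``condition_averages`` holds one dict per participant mapping condition
    labels LP/LN/HP/HN to (channels x times) arrays; participants missing
    any condition are excluded.  Thresholded samples (normalized
    probability > ``threshold``) are clustered per encoder with the shared
    adjacency/minimum-size machinery.
    """
    matrix = matrix or load_prediction_matrix()
    adjacency = check_adjacency(adjacency)
    usable = [
        p for p in condition_averages
        if all(p.get(c) is not None for c in ("LP", "LN", "HP", "HN"))
    ]
    if len(usable) < 2:
        raise ValueError("need condition averages from at least 2 participants")
    n = len(usable)
    shape = np.asarray(usable[0]["LP"]).shape

    key = {">": 0, "<": 1, "=": 2}
    triples = {}  # contrast -> (3, *shape) probability stack
    for a, b in CONTRASTS:
        diffs = np.stack([np.asarray(p[a]) - np.asarray(p[b]) for p in usable])
        sd = diffs.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError(
                f"zero variance in contrast {a}/{b}: Bayes factor undefined"
            )
        t = diffs.mean(axis=0) / (sd / np.sqrt(n))
        bf_pos = _bf_grid(t, n, prior_scale, "positive")
        bf_neg = _bf_grid(t, n, prior_scale, "negative")
        if scheme == "three_way":
            raw = np.stack([bf_pos, bf_neg, np.ones_like(t)])
        elif scheme == "two_way":
            bf_two = 0.5 * (bf_pos + bf_neg)
            raw = np.stack([bf_pos / (1 + bf_pos), bf_neg / (1 + bf_neg),
                            1.0 / (1 + bf_two)])
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        triples[(a, b)] = raw / raw.sum(axis=0, keepdims=True)

    probabilities = {}
    compounds = {}
    for enc in ENCODERS:
        prod = np.ones(shape)
        for c in CONTRASTS:
            prod = prod * triples[c][key[matrix.prediction(c, enc)]]
        compounds[enc] = prod
    total = sum(compounds.values())
    for enc in ENCODERS:
        probabilities[enc] = compounds[enc] / total

    clusters = {}
    for enc in ENCODERS:
        mask = probabilities[enc] > threshold
        clusters[enc] = _components(
            probabilities[enc], mask, adjacency, sign=1, min_size=min_size
        )
    return EncoderEvidenceMap(
        probabilities=probabilities,
        clusters=clusters,
        channel_names=tuple(channel_names),
        times=np.asarray(times),
        threshold=threshold,
    )


def evidence_map_to_dict(emap: EncoderEvidenceMap) -> dict:
    """JSON-ready summary (cluster members as channel/time lists)."""
    out = {"threshold": emap.threshold, "encoders": {}}
    for enc in ENCODERS:
        out["encoders"][enc] = {
            "max_probability": float(emap.probabilities[enc].max()),
            "clusters": [
                {
                    "size": c.size,
                    "peak_channel": emap.channel_names[c.peak[0]],
                    "peak_time_ms": float(emap.times[c.peak[1]]),
                    "members": [
                        {"channel": emap.channel_names[ch],
                         "time_ms": float(emap.times[t])}
                        for ch, t in c.members
                    ],
                }
                for c in emap.clusters[enc]
            ],
        }
    return out
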