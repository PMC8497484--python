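"""Spatiotemporal cluster-randomisation test for within-participant contrasts.

One-sample t tests over participants mark significant (channel, timepoint)
samples; clusters of spatially/temporally adjacent same-sign samples
(minimum size 25) are scored by their summed t mass against a Monte-Carlo
null built from whole-map sign flips, and the resulting Monte-Carlo p is
Bonferroni-corrected by the number of clusters found at the initial stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components


@dataclass
class ContrastWave:
    """Per-participant channels x timepoints difference maps for one contrast."""

    data: np.ndarray  # (n_participants, n_channels, n_times)
    label: str
    channel_names: tuple[str, ...]
    times: np.ndarray  # ms

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("data must be (participants, channels, times)")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 participants")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names/data mismatch")

    @property
    def n(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class ClusterConfig:
    n_perm: int = 5_000
    alpha_sample: float = 0.05  # two-sided sample-level threshold
    min_size: int = 25
    seed: int = 0
    p_estimator: str = "add_one"  # (b+1)/(m+1); "plain" gives b/m


@dataclass
class Cluster:
    members: list  # [(channel_index, time_index), ...]
    sign: int
    mass: float  # sum of member t values (signed)
    peak: tuple  # (channel_index, time_index) of max |t|
    mc_p: float = np.nan
    corrected_p: float = np.nan

    @property
    def size(self) -> int:
        return len(self.members)


def check_adjacency(adjacency: np.ndarray) -> np.ndarray:
    adj = np.asarray(adjacency, bool)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not (adj == adj.T).all():
        raise ValueError("adjacency must be symmetric")
    if adj.diagonal().any():
        raise ValueError("adjacency must be irreflexive")
    return adj


def samplewise_t(contrast: ContrastWave) -> np.ndarray:
    """One-sample t at every (channel, timepoint), df = N - 1.

    Zero-variance samples get t = 0 when the mean is zero (non-significant
    by convention) and +-inf when it is not (degenerate, always
    significant with the sign of the mean).
    """
    return _t_map(contrast.data)


def _t_map(data: np.ndarray) -> np.ndarray:
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_sd = sd == 0
    if zero_sd.any():
        t[zero_sd & (mean > 0)] = np.inf
        t[zero_sd & (mean < 0)] = -np.inf
        t[zero_sd & (mean == 0)] = 0.0
    return t


def form_clusters(
    t_map: np.ndarray,
    adjacency: np.ndarray,
    alpha_sample: float,
    df: int,
    min_size: int,
) -> list[Cluster]:
    """Connected components of same-sign significant samples.

    Samples with two-sided p < ``alpha_sample`` enter; (c, t) is adjacent
    to (c, t +- 1) and to (c', t) for neighbouring channels c, c';
    components smaller than ``min_size`` are discarded.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    adjacency = check_adjacency(adjacency)
    t_crit = sps.t.ppf(1.0 - alpha_sample / 2.0, df)
    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = (sign * t_map) > t_crit
        clusters.extend(
            _components(t_map, mask, adjacency, sign, min_size)
        )
    return clusters


def _components(
    t_map: np.ndarray, mask: np.ndarray, adjacency: np.ndarray,
    sign: int, min_size: int,
) -> list[Cluster]:
    n_ch, n_t = mask.shape
    idx = np.flatnonzero(mask.ravel())
    if idx.size < min_size:  # no component can reach the minimum size
        return []
    # sample graph: temporal neighbours along rows, spatial within columns
    lookup = -np.ones(n_ch * n_t, dtype=int)
    lookup[idx] = np.arange(idx.size)
    rows, cols = [], []
    ch_of, t_of = np.divmod(idx, n_t)
    # temporal edges
    right = idx + 1
    ok = (t_of < n_t - 1) & (lookup[np.minimum(right, n_ch * n_t - 1)] >= 0)
    rows.extend(np.flatnonzero(ok))
    cols.extend(lookup[right[ok]])
    # spatial edges
    nbr_i, nbr_j = np.nonzero(adjacency)
    for a, b in zip(nbr_i, nbr_j):
        if a < b:
            both = mask[a] & mask[b]
            tt = np.flatnonzero(both)
            rows.extend(lookup[a * n_t + tt])
            cols.extend(lookup[b * n_t + tt])
    graph = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(idx.size, idx.size)
    )
    n_comp, labels = connected_components(graph, directed=False)
    clusters = []
    for k in range(n_comp):
        sel = idx[labels == k]
        if sel.size < min_size:
            continue
        ch, tt = np.divmod(sel, n_t)
        tvals = t_map[ch, tt]
        peak = int(np.argmax(np.abs(tvals)))
        finite = tvals[np.isfinite(tvals)]
        mass = float(finite.sum()) if finite.size else float(sign * np.inf)
        if not np.isfinite(tvals).all():
            mass = float(sign * np.inf)
        clusters.append(
            Cluster(
                members=list(zip(ch.tolist(), tt.tolist())),
                sign=sign,
                mass=mass,
                peak=(int(ch[peak]), int(tt[peak])),
            )
        )
    return clusters


def permutation_null(
    contrast: ContrastWave,
    adjacency: np.ndarray,
    config: ClusterConfig | None = None,
) -> np.ndarray:
    """Null distribution of the maximum |cluster mass| under sign flips.

    Each permutation flips the sign of each participant's whole difference
    map independently (the one-sample randomisation scheme), reclusters,
    and records the maximum cluster-mass magnitude (0 when no cluster
    survives).
    """
    config = config or ClusterConfig()
    if config.n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(config.seed)
    signs = rng.choice([-1.0, 1.0], size=(config.n_perm, contrast.n))
    return _null_from_signs(contrast, adjacency, config, signs)


def _null_from_signs(
    contrast: ContrastWave, adjacency: np.ndarray,
    config: ClusterConfig, signs: np.ndarray,
) -> np.ndarray:
    """Max |cluster mass| for each row of a sign matrix (vectorized t maps)."""
    adjacency = check_adjacency(adjacency)
    n, n_ch, n_t = contrast.data.shape
    flat = contrast.data.reshape(n, -1)
    sumsq = (flat**2).sum(axis=0)
    df = n - 1
    out = np.empty(signs.shape[0])
    chunk = max(1, int(2e7 // max(flat.shape[1], 1)))
    for start in range(0, signs.shape[0], chunk):
        s = signs[start : start + chunk]
        mean = (s @ flat) / n
        var = np.maximum(sumsq - n * mean**2, 0.0) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / n)
        t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
        for j in range(s.shape[0]):
            clusters = form_clusters(
                t[j].reshape(n_ch, n_t), adjacency,
                config.alpha_sample, df, config.min_size,
            )
            out[start + j] = max(
                (abs(c.mass) for c in clusters), default=0.0
            )
    return out


def run_cluster_test(
    contrast: ContrastWave,
    adjacency: np.ndarray,
    config: ClusterConfig | None = None,
) -> list[Cluster]:
    """Full cluster-randomisation test with Bonferroni-corrected p values.

    mc_p = (1 + #{null maxima >= |mass|}) / (n_perm + 1) by default
    (``p_estimator="plain"`` uses b/m); corrected_p = min(1, mc_p x number
    of initial clusters).  Results are sorted by corrected p.
    """
    config = config or ClusterConfig()
    t_map = samplewise_t(contrast)
    clusters = form_clusters(
        t_map, adjacency, config.alpha_sample, contrast.n - 1, config.min_size
    )
    if not clusters:
        return []
    null = permutation_null(contrast, adjacency, config)
    n_initial = len(clusters)
    for c in clusters:
        b = int((null >= abs(c.mass)).sum())
        if config.p_estimator == "add_one":
            c.mc_p = (b + 1) / (config.n_perm + 1)
        else:
            c.mc_p = b / config.n_perm
        c.corrected_p = min(1.0, c.mc_p * n_initial)
    return sorted(clusters, key=lambda c: (c.corrected_p, -abs(c.mass)))


def clusters_to_dict(
    clusters: list[Cluster], channel_names, times
) -> list[dict]:
    """JSON-ready summary of cluster results."""
    out = []
    for c in clusters:
        out.append(
            {
                "sign": "+" if c.sign > 0 else "-",
                "size": c.size,
                "mass": c.mass,
                "mc_p": c.mc_p,
                "corrected_p": c.corrected_p,
                "peak_channel": channel_names[c.peak[0]],
                "peak_time_ms": float(times[c.peak[1]]),
                "members": [
                    {"channel": channel_names[ch], "time_ms": float(times[t])}
                    for ch, t in c.members
                ],
            }
        )
    return out
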