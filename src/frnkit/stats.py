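"""Shared statistical primitives: one-sample t summaries and power.

These back both the behavioural scoring and the ERP/startle group tests.
``one_sample_t`` accepts raw values or printed summary statistics so
published results can be recomputed directly from their reported mean/sd/n.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TTestSummary:
    mean: float
    sd: float
    n: int
    t: float
    df: int
    p: float  # two-sided
    d: float  # Cohen's d = mean / sd
    ci_low: float
    ci_high: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


def one_sample_t(
    values=None, *, mean: float | None = None, sd: float | None = None,
    n: int | None = None, ci: float = 0.95,
) -> TTestSummary:
    """One-sample (or paired-difference) t test against zero.

    Pass either ``values`` (raw sample) or the summary triple
    ``mean, sd, n``.  The CI is the central-t interval for the mean.
    """
    if values is not None:
        x = np.asarray(values, float)
        if x.ndim != 1 or len(x) < 2:
            raise ValueError("need a 1-D sample with n >= 2")
        mean, sd, n = float(x.mean()), float(x.std(ddof=1)), len(x)
    if mean is None or sd is None or n is None:
        raise ValueError("provide values or all of mean, sd, n")
    if n < 2:
        raise ValueError("n must be >= 2")
    df = n - 1
    if sd <= 0:
        return TTestSummary(mean, sd, n, np.inf * np.sign(mean), df,
                            0.0 if mean else 1.0, np.inf * np.sign(mean),
                            mean, mean, degenerate=True)
    se = sd / np.sqrt(n)
    t = mean / se
    p = 2.0 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(0.5 + ci / 2.0, df)
    return TTestSummary(mean, sd, n, t, df, p, mean / sd,
                        mean - tcrit * se, mean + tcrit * se)


def power_one_sample_t(
    n: int, d: float, alpha: float = 0.05, tails: str = "one"
) -> float:
    """Power of the one-sample t test via the noncentral t distribution.

    ``d`` is the standardized effect size; the noncentrality parameter is
    ``d * sqrt(n)``.  ``tails`` is "one" (directional, default for the
    FRN-direction analyses) or "two".
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if d <= 0:
        raise ValueError("d must be > 0")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    df = n - 1
    ncp = d * np.sqrt(n)
    if tails == "one":
        tcrit = sps.t.ppf(1.0 - alpha, df)
        return float(sps.nct.sf(tcrit, df, ncp))
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def minimal_n(
    power_target: float, d: float, alpha: float = 0.05,
    tails: str = "one", n_cap: int = 10_000,
) -> int:
    """Smallest n whose one-sample-t power reaches ``power_target``."""
    if not 0.0 < power_target < 1.0:
        raise ValueError("power_target must be in (0, 1)")
    for n in range(2, n_cap + 1):
        if power_one_sample_t(n, d, alpha, tails) >= power_target:
            return n
    raise ValueError(
        f"power {power_target} unreachable below n = {n_cap} at d = {d}"
    )


def p_from_r(r: float, n: int) -> float:
    """Two-sided p for a correlation via t = r sqrt(n-2) / sqrt(1-r^2)."""
    if n < 4:
        raise ValueError("n must be >= 4")
    if not -1.0 < r < 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), n - 2))
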