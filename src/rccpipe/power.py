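"""Exact t-test power and sample-size analysis via the noncentral t.

Post-hoc style: from a standardized effect size (Cohen's d for two
independent means, dz for matched pairs), the power of the two-sided
(default) t-test is P(|T'| > t_crit) where T' follows a noncentral t
distribution with noncentrality delta and the test's degrees of freedom.
Calibration utilities invert the power function for the effect size, and
search the smallest per-group n reaching a target power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

N_CAP = 10**6


@dataclass(frozen=True)
class PowerSpec:
    test: str = "two_sample"  # or "paired"
    alpha: float = 0.05
    tails: int = 2
    pair_correlation: float = 0.5  # paired only

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")
        if not -1 < self.pair_correlation < 1:
            raise ValueError("pair_correlation must be in (-1, 1)")


@dataclass(frozen=True)
class PowerResult:
    power: float
    effect_size_d: float
    n: int  # per group (two_sample) or number of pairs (paired)
    noncentrality: float
    df: float

    # alias matching the paired naming
    @property
    def n_pairs(self) -> int:
        return self.n

    @property
    def n_per_group(self) -> int:
        return self.n


def _nct_sf(x: float, df: float, delta: float) -> float:
    """P(T' > x); retries via symmetry where the far tail returns NaN."""
    v = stats.nct.sf(x, df, delta)
    if math.isnan(v):
        v = stats.nct.cdf(-x, df, -delta)
    if math.isnan(v):
        # deep negligible tail: the mass beyond x is numerically zero
        v = 0.0 if x > delta else 1.0
    return float(v)


def _nct_power(delta: float, df: float, alpha: float, tails: int) -> float:
    if tails == 2:
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        power = (_nct_sf(tcrit, df, delta)
                 + (1.0 - _nct_sf(-tcrit, df, delta)))
    else:
        tcrit = stats.t.ppf(1 - alpha, df)
        power = _nct_sf(tcrit, df, delta)
    return float(min(max(power, 0.0), 1.0))


def power_two_sample(d: float, n1: int, n2: int,
                     spec: PowerSpec = PowerSpec()) -> PowerResult:
    """Power of the two-independent-means t-test at effect size d."""
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    delta = d * math.sqrt(n1 * n2 / (n1 + n2))
    df = n1 + n2 - 2
    return PowerResult(
        power=_nct_power(delta, df, spec.alpha, spec.tails),
        effect_size_d=d, n=min(n1, n2), noncentrality=delta, df=df,
    )


def power_paired(mean_diff: float, sd1: float, sd2: float, r: float,
                 n_pairs: int, spec: PowerSpec = PowerSpec()) -> PowerResult:
    """Power of the matched-pairs t-test.

    The SD of the pair differences is sqrt(sd1^2 + sd2^2 - 2 r sd1 sd2);
    with equal SDs and r = 0.5 it reduces to that common SD.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("sds must be positive")
    sd_diff_sq = sd1**2 + sd2**2 - 2 * r * sd1 * sd2
    if sd_diff_sq <= 0:
        raise ValueError("difference SD is zero; dz undefined")
    dz = mean_diff / math.sqrt(sd_diff_sq)
    delta = dz * math.sqrt(n_pairs)
    df = n_pairs - 1
    return PowerResult(
        power=_nct_power(delta, df, spec.alpha, spec.tails),
        effect_size_d=dz, n=n_pairs, noncentrality=delta, df=df,
    )


def solve_effect_size(target_power: float, n1: int, n2: int,
                      spec: PowerSpec = PowerSpec()) -> float:
    """Smallest d >= 0 with two-sample power equal to ``target_power``."""
    if not spec.alpha <= target_power < 1:
        raise ValueError("target_power must be in [alpha, 1)")

    def gap(d):
        return power_two_sample(d, n1, n2, spec).power - target_power

    if gap(0.0) >= -1e-9:
        return 0.0
    hi = 1.0
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e6:
            raise RuntimeError("effect-size search failed to bracket")
    return float(optimize.brentq(gap, 0.0, hi, xtol=1e-10, rtol=1e-12))


def solve_n(target_power: float, d: float,
            spec: PowerSpec = PowerSpec()) -> int:
    """Smallest per-group n with two-sample power >= ``target_power``."""
    if d <= 0:
        raise ValueError("d must be positive")
    if not spec.alpha < target_power < 1:
        raise ValueError("target_power must be in (alpha, 1)")
    n = 2
    while power_two_sample(d, n, n, spec).power < target_power:
        n += 1
        if n > N_CAP:
            raise RuntimeError(
                f"no n <= {N_CAP} reaches power {target_power} at d = {d}"
            )
    return n


def power_curve(d: float, n_values,
                spec: PowerSpec = PowerSpec()) -> "np.ndarray":
    """Power at each per-group n in ``n_values`` (for CSV/plot export)."""
    return np.array([power_two_sample(d, n, n, spec).power
                     for n in n_values])
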