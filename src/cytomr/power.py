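"""Closed-form power for two-sample MR with a binary outcome.

The IVW (or Wald) estimate behaves asymptotically like a normal test
statistic whose non-centrality grows with the outcome sample size, the
case fraction, the variance in the exposure explained by the instruments
(R^2) and the log odds ratio under the alternative:

    ncp = sqrt(N * R^2 * p * (1 - p)) * |ln OR|

Power at a two-sided level alpha is then
Phi(ncp - z_{1-alpha/2}) + Phi(-ncp - z_{1-alpha/2}).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    """One power scenario for a binary-outcome MR analysis.

    n_total/n_cases give the outcome GWAS size and case count; or_alt is
    the odds ratio per SD of the exposure under the alternative; r2 is the
    variance in the exposure explained by the instruments.
    """

    n_total: float
    n_cases: float
    or_alt: float
    r2: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.n_cases < self.n_total):
            raise ValueError(f"need 0 < n_cases < n_total, got {self.n_cases}/{self.n_total}")
        if self.or_alt <= 0:
            raise ValueError(f"or_alt must be positive, got {self.or_alt}")
        if not (0 < self.r2 < 1):
            raise ValueError(f"r2 must lie in (0,1), got {self.r2}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must lie in (0,1), got {self.alpha}")

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total


def binary_outcome_power(spec: PowerSpec) -> float:
    """Power to detect ``spec.or_alt`` per SD of exposure at level ``spec.alpha``."""
    p = spec.case_fraction
    b = abs(np.log(spec.or_alt))
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    ncp = np.sqrt(spec.n_total * spec.r2 * p * (1.0 - p)) * b
    return float(stats.norm.cdf(ncp - z) + stats.norm.cdf(-ncp - z))


def power_grid(specs: Iterable[PowerSpec]) -> pd.DataFrame:
    """Power for each scenario, one row per spec, ordered by (r2, or_alt)."""
    rows = [
        {
            "n_total": s.n_total,
            "n_cases": s.n_cases,
            "r2": s.r2,
            "or_alt": s.or_alt,
            "alpha": s.alpha,
            "power": binary_outcome_power(s),
        }
        for s in specs
    ]
    df = pd.DataFrame(rows, columns=["n_total", "n_cases", "r2", "or_alt", "alpha", "power"])
    if len(df):
        df = df.sort_values(["r2", "or_alt"], kind="mergesort").reset_index(drop=True)
    return df
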