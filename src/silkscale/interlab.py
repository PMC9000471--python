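"""Round-robin (interlaboratory) consistency and precision statistics.

Implements the h/k consistency statistics, their critical values, and
the repeatability/reproducibility precision statistics of the
ASTM-E691-style analysis used to assess chip-parallelized microfluidic
nanoparticle manufacture:

- h_i = (mean_i − grand mean) / s_d, with s_d the SD of participant
  means about the grand mean — flags discrepant participant averages;
- k_i = SD_i / s_r, with s_r the pooled (df-weighted) within-participant
  SD — flags discrepant participant spreads;
- repeatability SD s_r, between-participant SD s_L, reproducibility SD
  s_R = √(s_r² + s_L²), and the 95% limits 2.8·s_r and 2.8·s_R (the
  largest difference expected between two results with 95% probability).

The design may be unbalanced (participants with different replicate
counts): pooled SDs weight by degrees of freedom while the grand average
weights participants equally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RoundRobinTable",
    "CellSummaries",
    "ConsistencyStats",
    "PrecisionStats",
    "cell_summaries",
    "h_statistics",
    "k_statistics",
    "critical_h",
    "critical_k",
    "consistency",
    "precision_limits",
    "LIMIT_FACTOR_95",
]

#: 95% limit factor ≈ 1.96·√2 by interlaboratory-study convention.
LIMIT_FACTOR_95 = 2.8


@dataclass(frozen=True)
class RoundRobinTable:
    """Per-participant replicate measurements of one property."""

    cells: dict[str, np.ndarray]
    property_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        cells = {k: np.asarray(v, dtype=float) for k, v in self.cells.items()}
        if len(cells) < 2:
            raise ValueError("round-robin design needs >= 2 participants")
        for pid, values in cells.items():
            if values.ndim != 1 or values.size < 2:
                raise ValueError(
                    f"participant {pid!r} needs >= 2 replicates, got {values.size}"
                )
        object.__setattr__(self, "cells", cells)

    @classmethod
    def from_dataframe(
        cls, df, value_col: str = "value", participant_col: str = "participant_id",
        property_name: str = "", units: str = "",
    ) -> "RoundRobinTable":
        cells = {
            str(pid): group[value_col].to_numpy(dtype=float)
            for pid, group in df.groupby(participant_col, sort=True)
        }
        return cls(cells, property_name, units)

    @property
    def participants(self) -> tuple[str, ...]:
        return tuple(self.cells)

    @property
    def n_participants(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class CellSummaries:
    participants: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    ns: np.ndarray
    grand_average: float


@dataclass(frozen=True)
class ConsistencyStats:
    participants: tuple[str, ...]
    h: np.ndarray
    k: np.ndarray
    critical_h: float
    critical_k: float
    h_flags: np.ndarray
    k_flags: np.ndarray
    degenerate: bool  # zero between- or within-participant spread


@dataclass(frozen=True)
class PrecisionStats:
    grand_average: float
    s_r: float
    s_L: float
    s_R: float
    limit_r95: float
    limit_R95: float


def cell_summaries(table: RoundRobinTable) -> CellSummaries:
    """Participant means and sample SDs (n−1) plus the grand average
    (equal participant weight, not weighted by replicate count)."""
    pids = table.participants
    means = np.array([table.cells[p].mean() for p in pids])
    sds = np.array([table.cells[p].std(ddof=1) for p in pids])
    ns = np.array([table.cells[p].size for p in pids])
    return CellSummaries(pids, means, sds, ns, float(means.mean()))


def _pooled_sd(summ: CellSummaries) -> float:
    df = summ.ns - 1
    return float(np.sqrt(np.sum(df * summ.sds**2) / np.sum(df)))


def h_statistics(table: RoundRobinTable) -> np.ndarray:
    """h_i = (mean_i − grand)/s_d; all zero (degenerate) when the
    participant means are identical."""
    summ = cell_summaries(table)
    dev = summ.means - summ.grand_average
    s_d = dev.std(ddof=1)
    if s_d == 0:
        return np.zeros_like(dev)
    return dev / s_d


def k_statistics(table: RoundRobinTable) -> np.ndarray:
    """k_i = SD_i/s_r with s_r the df-weighted pooled within SD; NaN
    (degenerate) when every replicate is identical."""
    summ = cell_summaries(table)
    s_r = _pooled_sd(summ)
    if s_r == 0:
        return np.full(summ.sds.shape, np.nan)
    return summ.sds / s_r


def critical_h(p: int, alpha: float = 0.005) -> float:
    """Critical h: (p−1)·t/√(p·(t² + p − 2)) with t the two-tailed
    Student-t critical value at significance ``alpha``, df = p − 2."""
    if p < 3:
        raise ValueError("critical h needs >= 3 participants (df = p - 2 >= 1)")
    t = stats.t.ppf(1.0 - alpha / 2.0, p - 2)
    return (p - 1) * t / np.sqrt(p * (t * t + p - 2))


def critical_k(p: int, n: int, alpha: float = 0.005) -> float:
    """Critical k: √(p/(1 + (p−1)/F)) with F the upper-``alpha`` critical
    value at df₁ = (p−1)(n−1), df₂ = n−1 (standard-practice convention;
    ``n`` is the replicates per participant, the mean cell size rounded
    for unbalanced designs)."""
    if p < 2 or n < 2:
        raise ValueError("critical k needs p >= 2 and n >= 2")
    f = stats.f.ppf(1.0 - alpha, (p - 1) * (n - 1), n - 1)
    return np.sqrt(p / (1.0 + (p - 1) / f))


def consistency(table: RoundRobinTable, alpha: float = 0.005) -> ConsistencyStats:
    """h and k per participant with critical values and outlier flags."""
    summ = cell_summaries(table)
    h = h_statistics(table)
    k = k_statistics(table)
    n_bar = int(round(summ.ns.mean()))
    h_crit = critical_h(table.n_participants, alpha)
    k_crit = critical_k(table.n_participants, n_bar, alpha)
    degenerate = bool(np.all(h == 0) or np.any(np.isnan(k)))
    k_safe = np.nan_to_num(k, nan=0.0)
    return ConsistencyStats(
        summ.participants, h, k, float(h_crit), float(k_crit),
        np.abs(h) > h_crit, k_safe > k_crit, degenerate,
    )


def precision_limits(
    table: RoundRobinTable, estimator: str = "anova"
) -> PrecisionStats:
    """Repeatability/reproducibility SDs and their 95% limits.

    ``estimator="anova"`` (default) removes the within-cell sampling
    contribution from the spread of participant means,
    s_L² = max(0, s_d² − s_r²/n̄), clamped at zero; ``"direct"`` takes
    s_L = s_d, the raw SD of participant means.
    """
    summ = cell_summaries(table)
    s_r = _pooled_sd(summ)
    s_d = float(summ.means.std(ddof=1))
    n_bar = float(summ.ns.mean())
    if estimator == "anova":
        s_l = float(np.sqrt(max(0.0, s_d**2 - s_r**2 / n_bar)))
    elif estimator == "direct":
        s_l = s_d
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    s_R = float(np.sqrt(s_r**2 + s_l**2))
    return PrecisionStats(
        grand_average=summ.grand_average,
        s_r=s_r,
        s_L=s_l,
        s_R=s_R,
        limit_r95=LIMIT_FACTOR_95 * s_r,
        limit_R95=LIMIT_FACTOR_95 * s_R,
    )
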