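"""Mendelian segregation statistics and incidence arithmetic.

Chi-square goodness-of-fit of observed progeny counts against an expected
ratio (3:1 for a recessive trait in selfed carrier families, 1:2:1 for
genotype classes), with no continuity correction, plus the incidence
percentages of the screening trials and the table-style p-value brackets
used when p is reported from a printed chi-square table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._round import round_half_up

# standard chi-square-table column grid
_BUCKET_BOUNDS = (0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 0.8, 0.9, 0.95)


@dataclass(frozen=True)
class SegregationObservation:
    labels: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.counts):
            raise ValueError("labels and counts must have equal arity")
        if any(c < 0 for c in self.counts) or sum(self.counts) <= 0:
            raise ValueError("counts must be >= 0 with a positive total")

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class RatioHypothesis:
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights):
            raise ValueError("ratio weights must be positive")

    @classmethod
    def parse(cls, text: str) -> "RatioHypothesis":
        """Parse '3:1' or '1:2:1' style ratio strings."""
        return cls(tuple(float(w) for w in text.split(":")))


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    p_bucket: str
    significant_at_0_05: bool

    @property
    def statistic_display(self) -> float:
        return round_half_up(self.statistic, 3)


def incidence_percent(albino_count: int, total_count: int) -> float:
    """Percent incidence, half-up to 3 decimals (e.g. 74/5438 -> 1.361)."""
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if not (0 <= albino_count <= total_count):
        raise ValueError("albino_count must lie in [0, total_count]")
    return round_half_up(100.0 * albino_count / total_count, 3)


def chi_square_gof(obs: SegregationObservation, hyp: RatioHypothesis) -> ChiSquareResult:
    """Pearson chi-square against an expected ratio, no continuity correction."""
    if len(obs.counts) != len(hyp.weights):
        raise ValueError(
            f"arity mismatch: {len(obs.counts)} categories vs {len(hyp.weights)} weights"
        )
    weights = np.asarray(hyp.weights, dtype=float)
    expected = obs.total * weights / weights.sum()
    if np.any(expected <= 0):
        raise ValueError("every expected count must be positive")
    statistic, p = stats.chisquare(np.asarray(obs.counts, dtype=float), expected)
    df = len(obs.counts) - 1
    return ChiSquareResult(
        statistic=float(statistic),
        df=df,
        p_value=float(p),
        p_bucket=p_bucket(float(p)),
        significant_at_0_05=bool(p <= 0.05),
    )


def p_bucket(p_value: float) -> str:
    """Printed-style bracket on the chi-square-table grid; boundary values
    fall into the lower bracket."""
    if not (0.0 <= p_value <= 1.0):
        raise ValueError("p_value must be in [0, 1]")
    if p_value <= _BUCKET_BOUNDS[0]:
        return f"p < {_BUCKET_BOUNDS[0]}"
    for lo, hi in zip(_BUCKET_BOUNDS, _BUCKET_BOUNDS[1:]):
        if p_value <= hi:
            return f"{lo} < p < {hi}"
    return f"p > {_BUCKET_BOUNDS[-1]}"


def segregation_table(
    rows: Sequence[tuple[str, Sequence[int]]], hyp: RatioHypothesis
) -> "pd.DataFrame":
    """Chi-square table for several families against one ratio hypothesis."""
    import pandas as pd

    labels = tuple(str(i + 1) for i in range(len(hyp.weights)))
    out = []
    for name, counts in rows:
        res = chi_square_gof(SegregationObservation(labels, tuple(counts)), hyp)
        out.append(
            {
                "line": name,
                "total": int(sum(counts)),
                **{f"n{i+1}": c for i, c in enumerate(counts)},
                "chi_square": res.statistic_display,
                "p_value": res.p_value,
                "p_bucket": res.p_bucket,
                "significant_at_0.05": res.significant_at_0_05,
            }
        )
    return pd.DataFrame(out)
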