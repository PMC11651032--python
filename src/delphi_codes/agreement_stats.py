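"""Per-code agreement statistics: median, quartiles, IQR, IPRAS, status.

A panel's scores for one code in one round are summarized by the median
and the interquartile range (IQR, the spread between the 0.25 and 0.75
quantiles).  Dispersion is judged against the RAND/UCLA appropriateness
method's disagreement threshold, the Inter-Percentile Range Adjusted
for Symmetry::

    IPRAS = 2.35 + 1.5 * |5 - (q1 + q3) / 2|

i.e. a baseline tolerance of 2.35 score units that grows by 1.5 units
per unit the panel's interquartile midpoint departs from the scale
midpoint 5.  The constants live in :class:`AgreementConfig`, not in
code, so they can be varied.

The round outcome is tripartite:

* ``AGREE_HIGH`` — median ≥ 7 and IQR ≤ IPRAS: the panel endorses the
  proposed classification;
* ``AGREE_LOW``  — median < 4: the panel rejects it;
* ``NO_AGREEMENT`` — median in [4, 7) (the middle band), or median ≥ 7
  with IQR exceeding IPRAS (a polarized panel): the code is re-voted in
  the next round.

A tie IQR == IPRAS counts as agreement: disagreement is triggered only
when the spread is strictly greater than the threshold.  By default a
low median yields agreement regardless of dispersion; set
``symmetric_low_rule`` to subject it to the same IQR test as the high
band.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

from .panel_votes import VoteSet

__all__ = [
    "AgreementConfig",
    "AgreementResult",
    "RoundStatus",
    "quartiles",
    "ipras",
    "classify_round",
]


class RoundStatus(str, enum.Enum):
    AGREE_HIGH = "agree_high"
    AGREE_LOW = "agree_low"
    NO_AGREEMENT = "no_agreement"

    @property
    def is_agreement(self) -> bool:
        return self is not RoundStatus.NO_AGREEMENT


_QUANTILE_METHODS = {"linear": "linear", "nearest": "nearest"}


@dataclass(frozen=True)
class AgreementConfig:
    """Tunable constants of the agreement rule.

    Defaults follow the study conventions: quartiles at (0.25, 0.75)
    with linear interpolation at fractional rank ``1 + (n-1)p``, the
    RAND/UCLA IPRAS constants (base 2.35, slope 1.5, center 5), median
    cut points 4 and 7, and no dispersion condition on low medians.
    """

    quantile_lo: float = 0.25
    quantile_hi: float = 0.75
    quantile_method: str = "linear"
    ipras_base: float = 2.35
    ipras_slope: float = 1.5
    ipras_center: float = 5.0
    median_low_cut: float = 4.0
    median_high_cut: float = 7.0
    symmetric_low_rule: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.quantile_lo <= self.quantile_hi <= 1.0:
            raise ValueError("quantile pair must satisfy 0 <= lo <= hi <= 1")
        if self.quantile_method not in _QUANTILE_METHODS:
            raise ValueError(
                f"quantile_method {self.quantile_method!r} not in "
                f"{sorted(_QUANTILE_METHODS)}"
            )
        if self.median_low_cut > self.median_high_cut:
            raise ValueError("median_low_cut must not exceed median_high_cut")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AgreementConfig":
        """Load a flat key-value YAML config; absent keys keep defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown agreement config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class AgreementResult:
    """Summary statistics and tripartite status for one vote set."""

    median: float
    q1: float
    q3: float
    iqr: float
    iprcp: float  # interquartile midpoint (q1 + q3) / 2
    asymmetry: float  # |center - iprcp|
    ipras: float
    status: RoundStatus


def _quantile_sorted(values: Sequence[float], p: float, method: str) -> float:
    """p-quantile of an ascending sequence at fractional rank 1 + (n-1)p."""
    h = (len(values) - 1) * p
    if method == "nearest":
        return float(values[round(h)])
    lo = int(h)
    frac = h - lo
    if frac == 0.0:
        return float(values[lo])
    return float(values[lo] + frac * (values[lo + 1] - values[lo]))


def quartiles(
    scores: Sequence[int], config: AgreementConfig | None = None
) -> tuple[float, float, float]:
    """(q1, median, q3) of a non-empty score multiset.

    Under the default ``linear`` convention the p-quantile of n sorted
    values sits at fractional rank ``1 + (n-1)p``, interpolating
    linearly between neighbors; ``nearest`` rounds to the closest rank
    (ties to the even rank).
    """
    config = config or AgreementConfig()
    values = sorted(scores)
    if not values:
        raise ValueError("cannot compute quartiles of an empty vote set")
    method = config.quantile_method
    return (
        _quantile_sorted(values, config.quantile_lo, method),
        _quantile_sorted(values, 0.5, method),
        _quantile_sorted(values, config.quantile_hi, method),
    )


def ipras(q1: float, q3: float, config: AgreementConfig | None = None) -> float:
    """Disagreement threshold for quartiles (q1, q3).

    Equals ``base + slope * |center - (q1+q3)/2|``; its minimum (the
    base, 2.35 by default) is attained exactly when the interquartile
    midpoint sits on the scale center.
    """
    config = config or AgreementConfig()
    if q1 > q3:
        raise ValueError(f"q1 ({q1}) exceeds q3 ({q3})")
    midpoint = (q1 + q3) / 2.0
    return config.ipras_base + config.ipras_slope * abs(config.ipras_center - midpoint)


def classify_round(
    votes: VoteSet | Sequence[int], config: AgreementConfig | None = None
) -> AgreementResult:
    """Classify one round of panel votes on one code.

    Accepts a :class:`~delphi_codes.panel_votes.VoteSet` or a bare score
    sequence.  The result is exactly one of the three statuses; it is
    invariant under panelist permutation because only the score multiset
    enters.
    """
    config = config or AgreementConfig()
    scores = votes.score_list() if isinstance(votes, VoteSet) else list(votes)
    q1, med, q3 = quartiles(scores, config)
    thr = ipras(q1, q3, config)
    iqr = q3 - q1
    dispersed = iqr > thr
    if med < config.median_low_cut:
        status = (
            RoundStatus.NO_AGREEMENT
            if (config.symmetric_low_rule and dispersed)
            else RoundStatus.AGREE_LOW
        )
    elif med < config.median_high_cut:
        status = RoundStatus.NO_AGREEMENT
    else:
        status = RoundStatus.NO_AGREEMENT if dispersed else RoundStatus.AGREE_HIGH
    return AgreementResult(
        median=med,
        q1=q1,
        q3=q3,
        iqr=iqr,
        iprcp=(q1 + q3) / 2.0,
        asymmetry=abs(config.ipras_center - (q1 + q3) / 2.0),
        ipras=thr,
        status=status,
    )
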