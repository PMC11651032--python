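"""Summary surfaces: flow tallies, chapter breakdowns, rounded percentages.

Reports always carry counts and recompute percentages from them at
report time; a percentage is never an input, so internal count
inconsistencies in external sources cannot propagate.  The default
rounding is half-away-from-zero at the requested number of decimals;
a ``truncate`` mode is available for reproducing figures produced by
truncation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .delphi_engine import ConsensusOutcome
from .icd_registry import ChapterTable, ICDCode
from .panel_votes import Classification

__all__ = [
    "FlowSummary",
    "ChapterBreakdown",
    "percent",
    "flow_summary",
    "chapter_breakdown",
    "consistency_warnings",
    "write_report",
]


def percent(
    numerator: int,
    denominator: int,
    decimals: int = 1,
    mode: str = "round",
) -> float:
    """``100 * numerator / denominator`` rounded to ``decimals`` places.

    ``round`` rounds half away from zero (so 18.2833 → 18.28 at two
    decimals); ``truncate`` drops the excess digits (47.0588 → 47.05).
    Computed on exact rationals, so printed-precision reproduction does
    not depend on binary floating point.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    if mode not in ("round", "truncate"):
        raise ValueError(f"unknown rounding mode {mode!r}")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    rounding = ROUND_HALF_UP if mode == "round" else ROUND_DOWN
    return float(value.quantize(quantum, rounding=rounding))


@dataclass(frozen=True)
class FlowSummary:
    """Flow-chart tallies of one consensus run."""

    total_codes: int
    round1_agreed: int
    round1_included: int
    round1_excluded: int
    contested: int
    final_included: int
    final_excluded: int
    rounds_used: int
    unresolved: int = 0

    def __post_init__(self) -> None:
        if self.round1_included + self.round1_excluded != self.round1_agreed:
            raise ValueError(
                "round-1 include/exclude split does not sum to round-1 "
                "agreements"
            )
        if self.round1_agreed + self.contested != self.total_codes:
            raise ValueError(
                "round-1 agreements plus contested codes do not sum to the "
                "codes evaluated"
            )
        if self.final_included + self.final_excluded + self.unresolved != self.total_codes:
            raise ValueError(
                "final include/exclude split (plus unresolved) does not sum "
                "to the total"
            )

    def to_dict(self) -> dict:
        return {
            "total_codes": self.total_codes,
            "round1_agreed": self.round1_agreed,
            "round1_included": self.round1_included,
            "round1_excluded": self.round1_excluded,
            "contested": self.contested,
            "final_included": self.final_included,
            "final_excluded": self.final_excluded,
            "rounds_used": self.rounds_used,
            "unresolved": self.unresolved,
            "final_included_percent": percent(
                self.final_included, self.total_codes, 2
            ),
        }


@dataclass(frozen=True)
class ChapterBreakdown:
    """Per-chapter (count, percent-of-subset) for a labelled code subset."""

    label: str
    total: int
    counts: Mapping[str, int]  # chapter_id -> count, descending count order

    def percents(self, decimals: int = 1, mode: str = "round") -> dict[str, float]:
        return {
            cid: percent(n, self.total, decimals, mode)
            for cid, n in self.counts.items()
        }


def flow_summary(outcome: ConsensusOutcome, strict: bool = True) -> FlowSummary:
    """Tally a consensus outcome into its flow-chart counts.

    In strict mode an incomplete outcome (unresolved codes) is
    rejected; pass ``strict=False`` to tally the resolved portion of a
    partial run.
    """
    if outcome.unresolved and strict:
        raise ValueError(
            f"outcome has {len(outcome.unresolved)} unresolved code(s); "
            "flow summary requires a complete run (or strict=False)"
        )
    if not outcome.history:
        raise ValueError("outcome has no round history")
    round1 = outcome.history[0]
    r1_included = sum(
        1
        for code, rnd in outcome.settling_round.items()
        if rnd == 1 and outcome.final_classification[code] is Classification.INCLUDE
    )
    r1_excluded = sum(
        1
        for code, rnd in outcome.settling_round.items()
        if rnd == 1 and outcome.final_classification[code] is Classification.EXCLUDE
    )
    return FlowSummary(
        total_codes=len(round1.evaluated_codes),
        round1_agreed=r1_included + r1_excluded,
        round1_included=r1_included,
        round1_excluded=r1_excluded,
        contested=len(round1.carried_forward),
        final_included=len(outcome.included_codes()),
        final_excluded=len(outcome.excluded_codes()),
        rounds_used=outcome.rounds_used,
        unresolved=len(outcome.unresolved),
    )


def chapter_breakdown(
    codes: Iterable[str | ICDCode],
    table: ChapterTable | None = None,
    label: str = "subset",
) -> ChapterBreakdown:
    """Partition a non-empty code subset over chapters.

    Accepts code identifiers (chapter-assigned via the table) or
    :class:`~delphi_codes.icd_registry.ICDCode` objects (their stored
    assignment is used).  Counts always sum to the subset size.
    """
    table = table if table is not None else ChapterTable.bundled()
    counts: dict[str, int] = {}
    total = 0
    for item in codes:
        chapter_id = item.chapter_id if isinstance(item, ICDCode) else table.assign(item)
        counts[chapter_id] = counts.get(chapter_id, 0) + 1
        total += 1
    if total == 0:
        raise ValueError("cannot break down an empty code subset")
    ordered = dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return ChapterBreakdown(label=label, total=total, counts=ordered)


def consistency_warnings(
    declared_total: int | None, summary: FlowSummary
) -> list[str]:
    """Surface count inconsistencies between a declared universe and a run.

    The tool never decides which figure is authoritative; it reports
    the discrepancy.
    """
    warnings = []
    if declared_total is not None and declared_total != summary.total_codes:
        warnings.append(
            f"declared code universe has {declared_total} codes but "
            f"{summary.total_codes} were evaluated in round 1 "
            f"(difference {declared_total - summary.total_codes:+d})"
        )
    return warnings


def _breakdown_frame(
    breakdown: ChapterBreakdown, table: ChapterTable
) -> pd.DataFrame:
    pct = breakdown.percents(1, "round")
    return pd.DataFrame(
        {
            "chapter_id": list(breakdown.counts),
            "name": [table.chapter(c).name for c in breakdown.counts],
            "count": list(breakdown.counts.values()),
            "percent": [pct[c] for c in breakdown.counts],
        }
    )


def _text_summary(
    summary: FlowSummary,
    breakdowns: Sequence[ChapterBreakdown],
    table: ChapterTable,
    warnings: Sequence[str],
) -> str:
    lines = [
        f"Codes evaluated: {summary.total_codes}",
        f"Rounds required: {summary.rounds_used}",
        (
            f"First round: agreement on {summary.round1_agreed} codes "
            f"({summary.round1_included} for inclusion, "
            f"{summary.round1_excluded} for exclusion); "
            f"{summary.contested} codes re-voted"
        ),
        (
            f"Final: {summary.final_included} codes for inclusion "
            f"({percent(summary.final_included, summary.total_codes, 1)}%), "
            f"{summary.final_excluded} for exclusion"
        ),
    ]
    for b in breakdowns:
        lines.append("")
        lines.append(f"Chapter breakdown of {b.label} (n={b.total}):")
        pct = b.percents(1, "round")
        for cid, n in b.counts.items():
            lines.append(
                f"  {table.chapter(cid).name}: {n}/{b.total} ({pct[cid]}%)"
            )
    for w in warnings:
        lines.append("")
        lines.append(f"WARNING: {w}")
    return "\n".join(lines) + "\n"


def write_report(
    outcome: ConsensusOutcome,
    codes: Sequence[ICDCode],
    outdir: str | Path,
    table: ChapterTable | None = None,
    declared_total: int | None = None,
) -> Path:
    """Emit ``flow_summary.json``, per-subset chapter CSVs, and a text summary.

    Deterministic output: re-running on the same outcome is
    byte-identical.  Subsets reported: the final inclusion set and the
    contested (re-voted) codes; if any code is flagged as a SARS-CoV-2
    addition, the inclusion tally of that subset is added to the JSON.
    """
    table = table if table is not None else ChapterTable.bundled()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_code = {c.code: c for c in codes}
    summary = flow_summary(outcome, strict=False)
    warnings = consistency_warnings(declared_total, summary)
    warnings.extend(outcome.warnings)

    breakdowns = []
    included = [by_code.get(c, c) for c in outcome.included_codes()]
    if included:
        breakdowns.append(chapter_breakdown(included, table, label="final_included"))
    contested = (
        [by_code.get(c, c) for c in outcome.history[0].carried_forward]
        if outcome.history
        else []
    )
    if contested:
        breakdowns.append(chapter_breakdown(contested, table, label="contested"))

    payload = summary.to_dict()
    payload["warnings"] = list(warnings)
    covid = [c for c in codes if c.is_covid]
    if covid:
        covid_included = sum(
            1
            for c in covid
            if outcome.final_classification.get(c.code) is Classification.INCLUDE
        )
        payload["covid_codes"] = {
            "total": len(covid),
            "included": covid_included,
            "included_percent": percent(covid_included, len(covid), 2, "truncate"),
        }
    (outdir / "flow_summary.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    for b in breakdowns:
        _breakdown_frame(b, table).to_csv(
            outdir / f"chapter_breakdown_{b.label}.csv",
            index=False,
            lineterminator="\n",
        )
    (outdir / "summary.txt").write_text(
        _text_summary(summary, breakdowns, table, warnings)
    )
    return outdir
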