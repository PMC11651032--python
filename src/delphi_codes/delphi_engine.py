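"""Multi-round Delphi consensus engine.

Orchestrates the full procedure: adjudicated proposals in, rounds of
panel voting iterated until every code reaches agreement (or a round
cap is hit), final inclusion/exclusion out.

Votes score the *proposal*, not inclusion directly (endorsement
semantics): a high-median agreement endorses the proposed
classification, a low-median agreement rejects it.  Under the default
``overturn`` policy a rejected proposal is flipped
(include ↔ exclude); the alternative ``reclassify_exclude`` policy
sends every rejected proposal to exclusion.

Codes that fail agreement are carried forward: round r+1 evaluates
exactly the codes that round r left unresolved.  The engine never loops
forever — after ``max_rounds`` any still-pending codes are reported as
an explicit partial outcome, never silently classified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Protocol, Sequence

import pandas as pd

from .agreement_stats import (
    AgreementConfig,
    AgreementResult,
    RoundStatus,
    classify_round,
)
from .panel_votes import (
    Classification,
    PanelRoster,
    ReviewProposal,
    VoteSet,
    read_votes,
)

__all__ = [
    "EngineConfig",
    "EngineError",
    "RoundRecord",
    "ConsensusOutcome",
    "VoteSource",
    "FileVoteSource",
    "resolve_direction",
    "run_round",
    "run_delphi",
    "write_outcome",
    "read_outcome",
]

_LOW_POLICIES = ("overturn", "reclassify_exclude")


class EngineError(ValueError):
    """A structural violation of the consensus procedure."""


@dataclass(frozen=True)
class EngineConfig:
    """Engine behavior knobs on top of the agreement rule."""

    agreement: AgreementConfig = field(default_factory=AgreementConfig)
    max_rounds: int = 10
    low_agreement: str = "overturn"
    strict: bool = True

    def __post_init__(self) -> None:
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.low_agreement not in _LOW_POLICIES:
            raise ValueError(
                f"low_agreement {self.low_agreement!r} not in {_LOW_POLICIES}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EngineConfig":
        """Flat YAML: agreement keys plus max_rounds/low_agreement/strict."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        engine_keys = {"max_rounds", "low_agreement", "strict"}
        agreement_kwargs = {k: v for k, v in data.items() if k not in engine_keys}
        known = set(AgreementConfig.__dataclass_fields__)
        unknown = set(agreement_kwargs) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            agreement=AgreementConfig(**agreement_kwargs),
            **{k: data[k] for k in engine_keys if k in data},
        )

    def to_dict(self) -> dict:
        return {
            "max_rounds": self.max_rounds,
            "low_agreement": self.low_agreement,
            "strict": self.strict,
            "agreement": self.agreement.to_dict(),
        }


def resolve_direction(
    proposal: Classification,
    result: AgreementResult,
    low_agreement: str = "overturn",
) -> Classification:
    """Compose the proposed classification with the panel's verdict.

    AGREE_HIGH endorses the proposal; AGREE_LOW rejects it (flip under
    ``overturn``, force exclusion under ``reclassify_exclude``).
    """
    if low_agreement not in _LOW_POLICIES:
        raise ValueError(f"low_agreement {low_agreement!r} not in {_LOW_POLICIES}")
    if result.status is RoundStatus.NO_AGREEMENT:
        raise EngineError("cannot resolve direction without agreement")
    if result.status is RoundStatus.AGREE_HIGH:
        return proposal
    if low_agreement == "overturn":
        return proposal.flipped()
    return Classification.EXCLUDE


@dataclass(frozen=True)
class RoundRecord:
    """Everything that happened in one voting round."""

    round_number: int
    evaluated_codes: tuple[str, ...]
    results: Mapping[str, AgreementResult]
    carried_forward: tuple[str, ...]

    @property
    def n_agreed(self) -> int:
        return len(self.evaluated_codes) - len(self.carried_forward)


@dataclass(frozen=True)
class ConsensusOutcome:
    """Final classification of every code plus the per-round history."""

    final_classification: Mapping[str, Classification]
    settling_round: Mapping[str, int]
    history: tuple[RoundRecord, ...]
    unresolved: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    @property
    def complete(self) -> bool:
        return not self.unresolved

    @property
    def rounds_used(self) -> int:
        return len(self.history)

    def included_codes(self) -> list[str]:
        return sorted(
            c
            for c, cls in self.final_classification.items()
            if cls is Classification.INCLUDE
        )

    def excluded_codes(self) -> list[str]:
        return sorted(
            c
            for c, cls in self.final_classification.items()
            if cls is Classification.EXCLUDE
        )


class VoteSource(Protocol):
    """Provider of panel votes for one round over the pending codes."""

    def votes_for_round(
        self, round_number: int, pending: Sequence[str]
    ) -> Sequence[VoteSet]:
        ...


class FileVoteSource:
    """Vote source backed by one vote file per round, in round order."""

    def __init__(
        self,
        paths: Sequence[str | Path],
        roster: PanelRoster | None = None,
        mode: str = "strict",
    ):
        self.paths = [Path(p) for p in paths]
        self.roster = roster
        self.mode = mode

    def votes_for_round(
        self, round_number: int, pending: Sequence[str]
    ) -> list[VoteSet]:
        if round_number > len(self.paths):
            raise EngineError(
                f"round {round_number} votes requested but only "
                f"{len(self.paths)} vote file(s) supplied"
            )
        path = self.paths[round_number - 1]
        votes, _ = read_votes(path, roster=self.roster, mode=self.mode)
        wrong_round = [v for v in votes if v.round_number != round_number]
        if wrong_round:
            raise EngineError(
                f"{path}: expected round {round_number} votes, found round "
                f"{wrong_round[0].round_number} (code {wrong_round[0].code})"
            )
        return votes


def run_round(
    round_number: int,
    pending: Sequence[str],
    votes: Sequence[VoteSet],
    config: EngineConfig | None = None,
) -> RoundRecord:
    """Classify one round of votes over exactly the pending codes.

    Votes for non-pending codes are always rejected; pending codes
    without votes are rejected in strict mode and carried forward with
    a warning otherwise (handled by :func:`run_delphi`).
    """
    config = config or EngineConfig()
    pending_set = set(pending)
    by_code: dict[str, VoteSet] = {}
    for vs in votes:
        if vs.code not in pending_set:
            raise EngineError(
                f"round {round_number}: votes for code {vs.code}, which is "
                "not pending"
            )
        if vs.code in by_code:
            raise EngineError(
                f"round {round_number}: duplicate vote set for code {vs.code}"
            )
        by_code[vs.code] = vs
    missing = sorted(pending_set - set(by_code))
    if missing and config.strict:
        raise EngineError(
            f"round {round_number}: no votes for pending code(s) "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    results = {
        code: classify_round(vs, config.agreement) for code, vs in by_code.items()
    }
    carried = tuple(
        sorted(
            [c for c, r in results.items() if r.status is RoundStatus.NO_AGREEMENT]
            + missing
        )
    )
    return RoundRecord(
        round_number=round_number,
        evaluated_codes=tuple(sorted(pending_set)),
        results=results,
        carried_forward=carried,
    )


def run_delphi(
    proposals: Sequence[ReviewProposal],
    vote_source: VoteSource,
    config: EngineConfig | None = None,
) -> ConsensusOutcome:
    """Iterate voting rounds until full agreement or the round cap.

    Deterministic: identical proposals, votes, and config yield an
    identical outcome.  Conservation holds by construction — every
    proposed code ends in exactly one of final-include, final-exclude,
    or the unresolved list.
    """
    config = config or EngineConfig()
    by_code = {p.code: p for p in proposals}
    if len(by_code) != len(proposals):
        raise EngineError("duplicate codes among proposals")
    pending: list[str] = sorted(by_code)
    final: dict[str, Classification] = {}
    settling: dict[str, int] = {}
    history: list[RoundRecord] = []
    warnings: list[str] = []
    round_number = 0
    while pending and round_number < config.max_rounds:
        round_number += 1
        votes = vote_source.votes_for_round(round_number, tuple(pending))
        record = run_round(round_number, pending, votes, config)
        for code, result in record.results.items():
            if result.status.is_agreement:
                final[code] = resolve_direction(
                    by_code[code].final_proposal, result, config.low_agreement
                )
                settling[code] = round_number
        missing = set(record.carried_forward) - set(record.results)
        if missing:
            warnings.append(
                f"round {round_number}: {len(missing)} pending code(s) "
                "received no votes and were carried forward"
            )
        history.append(record)
        pending = list(record.carried_forward)
    if pending:
        warnings.append(
            f"max_rounds={config.max_rounds} exhausted with {len(pending)} "
            "unresolved code(s); partial outcome"
        )
    return ConsensusOutcome(
        final_classification=final,
        settling_round=settling,
        history=tuple(history),
        unresolved=tuple(sorted(pending)),
        warnings=tuple(warnings),
    )


# --------------------------------------------------------------------------
# outcome persistence

_ROUND_COLUMNS = ["code", "median", "q1", "q3", "iqr", "ipras", "status"]


def write_outcome(
    outcome: ConsensusOutcome,
    outdir: str | Path,
    config: EngineConfig | None = None,
) -> Path:
    """Write ``final_classification.csv``, per-round results, and a manifest.

    Output is deterministic (sorted, no timestamps) so repeated writes
    of the same outcome are byte-identical.
    """
    config = config or EngineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = sorted(
        (code, cls.value, outcome.settling_round[code])
        for code, cls in outcome.final_classification.items()
    )
    pd.DataFrame(rows, columns=["code", "classification", "settling_round"]).to_csv(
        outdir / "final_classification.csv", index=False, lineterminator="\n"
    )
    for record in outcome.history:
        rrows = [
            (
                code,
                r.median,
                r.q1,
                r.q3,
                r.iqr,
                r.ipras,
                r.status.value,
            )
            for code, r in sorted(record.results.items())
        ]
        pd.DataFrame(rrows, columns=_ROUND_COLUMNS).to_csv(
            outdir / f"round_{record.round_number}_results.csv",
            index=False,
            lineterminator="\n",
        )
    manifest = {
        "config": config.to_dict(),
        "counts": {
            "total_codes": len(outcome.final_classification)
            + len(outcome.unresolved),
            "final_included": len(outcome.included_codes()),
            "final_excluded": len(outcome.excluded_codes()),
            "unresolved": len(outcome.unresolved),
            "rounds_used": outcome.rounds_used,
            "per_round_evaluated": [
                len(r.evaluated_codes) for r in outcome.history
            ],
            "per_round_carried_forward": [
                len(r.carried_forward) for r in outcome.history
            ],
        },
        "unresolved": list(outcome.unresolved),
        "warnings": list(outcome.warnings),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return outdir


def read_outcome(outdir: str | Path) -> ConsensusOutcome:
    """Rebuild a :class:`ConsensusOutcome` from a :func:`write_outcome` directory.

    Vote-level detail is not persisted, so rebuilt round records carry
    the summary statistics only; that is sufficient for reporting.
    """
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    final_frame = pd.read_csv(outdir / "final_classification.csv", dtype=str)
    final = {
        row.code: Classification.from_text(row.classification)
        for row in final_frame.itertuples(index=False)
    }
    settling = {
        row.code: int(row.settling_round)
        for row in final_frame.itertuples(index=False)
    }
    history: list[RoundRecord] = []
    for round_number in range(1, manifest["counts"]["rounds_used"] + 1):
        frame = pd.read_csv(
            outdir / f"round_{round_number}_results.csv", dtype={"code": str}
        )
        results = {}
        for row in frame.itertuples(index=False):
            status = RoundStatus(row.status)
            results[str(row.code)] = AgreementResult(
                median=float(row.median),
                q1=float(row.q1),
                q3=float(row.q3),
                iqr=float(row.iqr),
                iprcp=(float(row.q1) + float(row.q3)) / 2.0,
                asymmetry=abs(5.0 - (float(row.q1) + float(row.q3)) / 2.0),
                ipras=float(row.ipras),
                status=status,
            )
        carried = tuple(
            sorted(
                c
                for c, r in results.items()
                if r.status is RoundStatus.NO_AGREEMENT
            )
        )
        history.append(
            RoundRecord(
                round_number=round_number,
                evaluated_codes=tuple(sorted(results)),
                results=results,
                carried_forward=carried,
            )
        )
    return ConsensusOutcome(
        final_classification=final,
        settling_round=settling,
        history=tuple(history),
        unresolved=tuple(manifest.get("unresolved", ())),
        warnings=tuple(manifest.get("warnings", ())),
    )
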