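"""Data model and file I/O for reviewer proposals and panel Likert votes.

The pre-voting stage is a dual independent review: two specialists each
classify every code as *for inclusion* or *for exclusion* (inclusion
meaning a clinical condition for which systemic antimicrobial therapy
is administered in at least 60% of hospital stays); a third reviewer
adjudicates discordant pairs.  The panel then scores its agreement with
each proposed classification on a 9-point Likert scale (1 = totally
disagree, 9 = totally agree), one vote per panelist per code per round.

Missing votes are surfaced, never imputed: in strict mode an incomplete
panel is an error, in permissive mode a completeness report lists the
absent ``(round, code, panelist)`` triples — mirroring a study workflow
in which missing responses are chased until completion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .icd_registry import parse_code

__all__ = [
    "Classification",
    "ReviewProposal",
    "VoteSet",
    "PanelRoster",
    "VoteFileError",
    "ProposalFileError",
    "MissingVote",
    "adjudicate",
    "read_votes",
    "write_votes",
    "read_proposals",
    "write_proposals",
]

SCORE_MIN, SCORE_MAX = 1, 9


class Classification(str, enum.Enum):
    """The binary proposal/outcome label for one code."""

    INCLUDE = "include"
    EXCLUDE = "exclude"

    def flipped(self) -> "Classification":
        return (
            Classification.EXCLUDE
            if self is Classification.INCLUDE
            else Classification.INCLUDE
        )

    @classmethod
    def from_text(cls, text: str) -> "Classification":
        try:
            return cls(text.strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown classification {text!r}; expected 'include' or 'exclude'"
            ) from None


class VoteFileError(ValueError):
    """A vote file violates the schema or the Likert bounds."""


class ProposalFileError(ValueError):
    """A proposal file violates the schema or the adjudication invariant."""


@dataclass(frozen=True)
class ReviewProposal:
    """The adjudicated pre-Delphi include/exclude proposal for one code.

    Invariant: a concordant reviewer pair carries no third review and is
    not adjudicated; a discordant pair requires a third review whose
    classification becomes the final proposal.
    """

    code: str
    reviewer1: Classification
    reviewer2: Classification
    reviewer3: Classification | None
    final_proposal: Classification
    adjudicated: bool

    def __post_init__(self) -> None:
        if self.reviewer1 == self.reviewer2:
            if self.reviewer3 is not None:
                raise ProposalFileError(
                    f"code {self.code}: concordant reviewers must not carry a "
                    "third review"
                )
            if self.adjudicated or self.final_proposal != self.reviewer1:
                raise ProposalFileError(
                    f"code {self.code}: concordant pair must yield its own "
                    "classification without adjudication"
                )
        else:
            if self.reviewer3 is None:
                raise ProposalFileError(
                    f"code {self.code}: adjudication required for discordant "
                    "reviewers"
                )
            if not self.adjudicated or self.final_proposal != self.reviewer3:
                raise ProposalFileError(
                    f"code {self.code}: discordant pair must be adjudicated to "
                    "the third reviewer's classification"
                )


def adjudicate(
    code: str,
    r1: Classification,
    r2: Classification,
    r3: Classification | None = None,
) -> ReviewProposal:
    """Combine two independent reviews (and a third where discordant).

    A concordant pair stands as proposed; a discordant pair is resolved
    by the third reviewer.  Supplying a third review for a concordant
    pair, or omitting it for a discordant one, is rejected.
    """
    if r1 == r2:
        if r3 is not None:
            raise ProposalFileError(
                f"code {code}: third review supplied but reviewers agree"
            )
        return ReviewProposal(code, r1, r2, None, r1, adjudicated=False)
    if r3 is None:
        raise ProposalFileError(
            f"code {code}: adjudication required (reviewers disagree)"
        )
    return ReviewProposal(code, r1, r2, r3, r3, adjudicated=True)


@dataclass(frozen=True)
class VoteSet:
    """One code's panel scores in one round (panelist id → score 1–9)."""

    code: str
    round_number: int
    scores: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.round_number < 1:
            raise VoteFileError(
                f"code {self.code}: round_number must be positive"
            )
        if not self.scores:
            raise VoteFileError(f"code {self.code}: empty vote set")
        for panelist, score in self.scores.items():
            if not isinstance(score, int) or isinstance(score, bool):
                raise VoteFileError(
                    f"code {self.code}, panelist {panelist}: score {score!r} "
                    "is not an integer"
                )
            if not SCORE_MIN <= score <= SCORE_MAX:
                raise VoteFileError(
                    f"code {self.code}, panelist {panelist}: score {score} "
                    f"outside [{SCORE_MIN}, {SCORE_MAX}]"
                )

    @property
    def n_votes(self) -> int:
        return len(self.scores)

    def score_list(self) -> list[int]:
        return list(self.scores.values())


@dataclass(frozen=True)
class PanelRoster:
    """The expected voting panel: unique panelist ids."""

    panelists: tuple[str, ...]
    expected_size: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.panelists)) != len(self.panelists):
            raise ValueError("duplicate panelist ids in roster")
        object.__setattr__(
            self,
            "expected_size",
            self.expected_size if self.expected_size is not None else len(self.panelists),
        )
        if self.expected_size != len(self.panelists):
            raise ValueError(
                f"roster has {len(self.panelists)} panelists, expected "
                f"{self.expected_size}"
            )

    @classmethod
    def default(cls, size: int = 18) -> "PanelRoster":
        """The study-replication roster: ``size`` anonymous panelists."""
        width = max(2, len(str(size)))
        return cls(tuple(f"P{i:0{width}d}" for i in range(1, size + 1)))


class MissingVote(NamedTuple):
    round_number: int
    code: str
    panelist: str


_SCORE_OK = {str(s) for s in range(SCORE_MIN, SCORE_MAX + 1)}


def read_votes(
    path: str | Path,
    roster: PanelRoster | None = None,
    mode: str = "strict",
) -> tuple[list[VoteSet], list[MissingVote]]:
    """Parse a vote file into one :class:`VoteSet` per (round, code) pair.

    Expected header: ``round,code,panelist,score``.  Scores must be
    integers in [1, 9]; anything else is rejected with the offending
    line number — no silent coercion.  When a roster is given, the
    returned completeness report lists every (round, code, panelist)
    triple missing relative to it; in ``strict`` mode (the default) an
    incomplete panel raises instead.
    """
    if mode not in ("strict", "permissive"):
        raise ValueError(f"unknown mode {mode!r}; expected strict or permissive")
    frame = pd.read_csv(path, dtype=str).fillna("")
    required = {"round", "code", "panelist", "score"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise VoteFileError(
            f"{path}: missing columns {sorted(missing_cols)}"
        )
    groups: dict[tuple[int, str], dict[str, int]] = {}
    for line, row in enumerate(frame.itertuples(index=False), start=2):
        score_text = str(row.score).strip()
        if score_text not in _SCORE_OK:
            raise VoteFileError(
                f"{path}, line {line}: score {row.score!r} is not an integer "
                f"in [{SCORE_MIN}, {SCORE_MAX}]"
            )
        try:
            round_number = int(str(row.round).strip())
        except ValueError:
            raise VoteFileError(
                f"{path}, line {line}: round {row.round!r} is not an integer"
            ) from None
        code = parse_code(str(row.code))
        panelist = str(row.panelist).strip()
        if not panelist:
            raise VoteFileError(f"{path}, line {line}: empty panelist id")
        key = (round_number, code)
        scores = groups.setdefault(key, {})
        if panelist in scores:
            raise VoteFileError(
                f"{path}, line {line}: duplicate vote for round {round_number}, "
                f"code {code}, panelist {panelist}"
            )
        scores[panelist] = int(score_text)
    votes = [
        VoteSet(code=code, round_number=rnd, scores=dict(sorted(scores.items())))
        for (rnd, code), scores in sorted(groups.items())
    ]
    report: list[MissingVote] = []
    if roster is not None:
        expected = set(roster.panelists)
        for vs in votes:
            extra = set(vs.scores) - expected
            if extra:
                raise VoteFileError(
                    f"{path}: round {vs.round_number}, code {vs.code}: "
                    f"votes from panelists absent from the roster: {sorted(extra)}"
                )
            for absent in sorted(expected - set(vs.scores)):
                report.append(MissingVote(vs.round_number, vs.code, absent))
        if report and mode == "strict":
            head = ", ".join(
                f"(round {m.round_number}, {m.code}, {m.panelist})"
                for m in report[:5]
            )
            raise VoteFileError(
                f"{path}: {len(report)} missing vote(s) relative to the roster "
                f"of {len(expected)}: {head}{'...' if len(report) > 5 else ''}"
            )
    return votes, report


def write_votes(votes: Iterable[VoteSet], path: str | Path) -> None:
    """Serialize vote sets as CSV rows sorted by (round, code, panelist).

    Round-trips exactly through :func:`read_votes`.
    """
    rows = []
    for vs in votes:
        for panelist, score in vs.scores.items():
            rows.append((vs.round_number, vs.code, panelist, score))
    rows.sort()
    frame = pd.DataFrame(rows, columns=["round", "code", "panelist", "score"])
    frame.to_csv(path, index=False, lineterminator="\n")


def read_proposals(path: str | Path) -> list[ReviewProposal]:
    """Parse a proposal file (``code,reviewer1,reviewer2,reviewer3,final_proposal``).

    ``reviewer3`` is blank for concordant pairs.  The adjudication
    invariant is enforced row by row; an optional ``comment`` column is
    ignored.
    """
    frame = pd.read_csv(path, dtype=str).fillna("")
    required = {"code", "reviewer1", "reviewer2", "reviewer3", "final_proposal"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise ProposalFileError(f"{path}: missing columns {sorted(missing_cols)}")
    proposals = []
    seen: set[str] = set()
    for line, row in enumerate(frame.itertuples(index=False), start=2):
        code = parse_code(str(row.code))
        if code in seen:
            raise ProposalFileError(f"{path}, line {line}: duplicate code {code}")
        seen.add(code)
        r3_text = str(row.reviewer3).strip()
        try:
            proposal = ReviewProposal(
                code=code,
                reviewer1=Classification.from_text(row.reviewer1),
                reviewer2=Classification.from_text(row.reviewer2),
                reviewer3=Classification.from_text(r3_text) if r3_text else None,
                final_proposal=Classification.from_text(row.final_proposal),
                adjudicated=bool(r3_text),
            )
        except (ValueError, ProposalFileError) as exc:
            raise ProposalFileError(f"{path}, line {line}: {exc}") from None
        proposals.append(proposal)
    return proposals


def write_proposals(proposals: Iterable[ReviewProposal], path: str | Path) -> None:
    """Serialize proposals as CSV sorted by code; round-trips exactly."""
    rows = sorted(
        (
            p.code,
            p.reviewer1.value,
            p.reviewer2.value,
            p.reviewer3.value if p.reviewer3 is not None else "",
            p.final_proposal.value,
        )
        for p in proposals
    )
    frame = pd.DataFrame(
        rows,
        columns=["code", "reviewer1", "reviewer2", "reviewer3", "final_proposal"],
    )
    frame.to_csv(path, index=False, lineterminator="\n")
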