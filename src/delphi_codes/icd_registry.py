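"""ICD-9-CM code parsing, validation, and chapter classification.

ICD-9-CM identifiers come in three syntactic families:

* numeric — three digits plus an optional one- or two-digit decimal
  extension (``008``, ``008.45``);
* V codes — ``V`` plus two digits and an optional decimal extension,
  used for the supplementary classification of factors influencing
  health status and contact with health services (``V09.0``);
* E codes — ``E`` plus three digits and an optional single decimal
  digit, used for the supplementary classification of external causes
  of injury and poisoning (``E878.8``).

Every code belongs to exactly one chapter, determined by its
three-character prefix.  The 17 numeric chapter ranges plus the V and E
supplementary classifications ship as a data table
(``data/chapters.csv``) rather than being hard-coded, so the mapping
can be corrected without touching logic.  Codes are treated as opaque
leaves: ``008`` and ``008.45`` are distinct codes that happen to share
a chapter, and no hierarchy expansion is performed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "InvalidCodeError",
    "ICDCode",
    "Chapter",
    "ChapterTable",
    "parse_code",
    "code_family",
    "code_prefix",
    "is_supplementary",
    "load_code_list",
    "write_code_list",
    "bundled_example_codes",
]

_FAMILY_PATTERNS = {
    "numeric": re.compile(r"^\d{3}(\.\d{1,2})?$"),
    "V": re.compile(r"^V\d{2}(\.\d{1,2})?$"),
    "E": re.compile(r"^E\d{3}(\.\d)?$"),
}

_FAMILY_SYNTAX = (
    "numeric 'NNN[.N[N]]', V code 'VNN[.N[N]]', or E code 'ENNN[.N]'"
)


class InvalidCodeError(ValueError):
    """Raised when text does not parse as an ICD-9-CM identifier."""


def parse_code(raw: str) -> str:
    """Normalize ``raw`` into a canonical ICD-9-CM identifier.

    Normalization strips surrounding whitespace and uppercases the V/E
    prefix; the decimal point is preserved as written.  The function is
    idempotent, so ``parse_code(parse_code(x)) == parse_code(x)``.

    Raises
    ------
    InvalidCodeError
        If the text matches none of the three syntactic families.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise InvalidCodeError(
            f"empty or non-text code {raw!r}; expected {_FAMILY_SYNTAX}"
        )
    code = raw.strip().upper()
    if code_family(code) is None:
        raise InvalidCodeError(
            f"malformed ICD-9-CM code {raw!r}; expected {_FAMILY_SYNTAX}"
        )
    return code


def code_family(code: str) -> str | None:
    """Return ``'numeric'``, ``'V'`` or ``'E'``, or None if no family matches."""
    for family, pattern in _FAMILY_PATTERNS.items():
        if pattern.match(code):
            return family
    return None


def code_prefix(code: str) -> str:
    """Three-character chapter prefix: ``008.45`` → ``008``, ``E878.8`` → ``E878``.

    For E codes the prefix is four characters (``E`` + three digits);
    "three-character" refers to the significant digits.
    """
    return code.split(".", 1)[0]


def is_supplementary(code: str) -> bool:
    """True iff the code belongs to the V or E supplementary classification."""
    return code[:1] in ("V", "E")


@dataclass(frozen=True)
class Chapter:
    """One chapter of the ICD-9-CM, defined by an inclusive prefix interval."""

    chapter_id: str
    name: str
    prefix_start: str
    prefix_end: str
    family: str

    def __post_init__(self) -> None:
        if self.prefix_start > self.prefix_end:
            raise ValueError(
                f"chapter {self.chapter_id}: prefix_start {self.prefix_start!r} "
                f"exceeds prefix_end {self.prefix_end!r}"
            )

    def contains(self, prefix: str) -> bool:
        # fixed-width prefixes within a family compare correctly as strings
        return self.prefix_start <= prefix <= self.prefix_end


class ChapterTable:
    """The chapter partition of the ICD-9-CM code space.

    Prefix intervals must be disjoint within each family, so every
    prefix resolves to at most one chapter.
    """

    def __init__(self, chapters: Sequence[Chapter]):
        self._chapters = tuple(chapters)
        self._by_id = {c.chapter_id: c for c in self._chapters}
        if len(self._by_id) != len(self._chapters):
            raise ValueError("duplicate chapter_id in chapter table")
        self._validate_disjoint()

    def _validate_disjoint(self) -> None:
        for family in ("numeric", "V", "E"):
            spans = sorted(
                (c.prefix_start, c.prefix_end, c.chapter_id)
                for c in self._chapters
                if c.family == family
            )
            for (_, prev_end, prev_id), (start, _, cur_id) in zip(spans, spans[1:]):
                if start <= prev_end:
                    raise ValueError(
                        f"overlapping chapter ranges: {prev_id} and {cur_id}"
                    )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ChapterTable":
        required = {"chapter_id", "name", "prefix_start", "prefix_end", "family"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"chapter table missing columns: {sorted(missing)}")
        return cls(
            [
                Chapter(
                    chapter_id=row.chapter_id,
                    name=row.name,
                    prefix_start=str(row.prefix_start),
                    prefix_end=str(row.prefix_end),
                    family=row.family,
                )
                for row in frame.itertuples(index=False)
            ]
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChapterTable":
        return cls.from_frame(pd.read_csv(path, dtype=str))

    @classmethod
    def bundled(cls) -> "ChapterTable":
        """The chapter table shipped with the package."""
        with resources.files("delphi_codes.data").joinpath("chapters.csv").open() as fh:
            return cls.from_frame(pd.read_csv(fh, dtype=str))

    def __iter__(self) -> Iterator[Chapter]:
        return iter(self._chapters)

    def __len__(self) -> int:
        return len(self._chapters)

    @property
    def chapter_ids(self) -> tuple[str, ...]:
        return tuple(c.chapter_id for c in self._chapters)

    def chapter(self, chapter_id: str) -> Chapter:
        try:
            return self._by_id[chapter_id]
        except KeyError:
            raise KeyError(f"unknown chapter_id {chapter_id!r}") from None

    def assign(self, code: str) -> str:
        """Chapter id of a normalized code; stable under decimal extension."""
        prefix = code_prefix(code)
        family = code_family(code)
        if family is None:
            raise InvalidCodeError(
                f"malformed ICD-9-CM code {code!r}; expected {_FAMILY_SYNTAX}"
            )
        for chapter in self._chapters:
            if chapter.family == family and chapter.contains(prefix):
                return chapter.chapter_id
        raise InvalidCodeError(
            f"code {code!r} (prefix {prefix}) falls outside every chapter range"
        )


@dataclass(frozen=True)
class ICDCode:
    """One ICD-9-CM code with its chapter assignment and flags.

    ``is_covid`` marks the SARS-CoV-2 codes added to the classification
    in 2020; it is carried as input metadata, never inferred from the
    identifier.
    """

    code: str
    description: str
    chapter_id: str
    is_supplementary: bool
    is_covid: bool = False

    @classmethod
    def from_raw(
        cls,
        code: str,
        description: str = "",
        *,
        table: ChapterTable | None = None,
        is_covid: bool = False,
    ) -> "ICDCode":
        table = table if table is not None else ChapterTable.bundled()
        normalized = parse_code(code)
        return cls(
            code=normalized,
            description=description,
            chapter_id=table.assign(normalized),
            is_supplementary=is_supplementary(normalized),
            is_covid=bool(is_covid),
        )


def _sniff_sep(path: str | Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


_TRUTHY = {"1", "true", "yes", "y"}


def load_code_list(
    path: str | Path, table: ChapterTable | None = None
) -> list[ICDCode]:
    """Read a delimited code-list file (``code,description[,is_covid]``).

    The delimiter (comma or tab) is auto-detected from the header line.
    Every code is normalized and chapter-assigned; a malformed or
    unassignable code aborts the load.
    """
    table = table if table is not None else ChapterTable.bundled()
    frame = pd.read_csv(path, sep=_sniff_sep(path), dtype=str).fillna("")
    if "code" not in frame.columns:
        raise ValueError(f"code-list file {path} lacks a 'code' column")
    has_covid = "is_covid" in frame.columns
    codes = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        covid = str(getattr(row, "is_covid", "")).strip().lower() in _TRUTHY
        try:
            codes.append(
                ICDCode.from_raw(
                    row.code,
                    getattr(row, "description", ""),
                    table=table,
                    is_covid=covid if has_covid else False,
                )
            )
        except InvalidCodeError as exc:
            raise InvalidCodeError(f"{path}, line {row_number}: {exc}") from None
    seen: set[str] = set()
    for icd in codes:
        if icd.code in seen:
            raise ValueError(f"duplicate code {icd.code!r} in {path}")
        seen.add(icd.code)
    return codes


def write_code_list(codes: Iterable[ICDCode], path: str | Path) -> None:
    """Write codes as CSV with columns ``code,description,is_covid``."""
    rows = list(codes)
    frame = pd.DataFrame(
        {
            "code": [c.code for c in rows],
            "description": [c.description for c in rows],
            "is_covid": [int(c.is_covid) for c in rows],
        }
    )
    frame.to_csv(path, index=False, lineterminator="\n")


def bundled_example_codes() -> list[ICDCode]:
    """A small illustrative sample of well-known ICD-9-CM codes."""
    path = resources.files("delphi_codes.data").joinpath("example_codes.csv")
    return load_code_list(str(path))
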