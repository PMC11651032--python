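"""Synthetic code universes, reviewer proposals, and panel votes.

The real panel votes behind the consensus code list are not published,
so every stage of the pipeline is exercised against a generative model
with the statistical structure the procedure assumes:

* each code carries a latent probability ``p_abx`` that an admission
  under it receives systemic antimicrobial therapy, drawn from a
  two-component Beta mixture — a low mode for codes unlikely to involve
  antimicrobials and a high mode for infection-like conditions, with
  the high mode weighted up in infection-like chapters (infectious and
  parasitic diseases, injury and poisoning, pregnancy complications);
* two simulated reviewers classify each code *for inclusion* iff
  ``p_abx`` ≥ 0.60 (the "at least 60% of stays" rule), each flipping
  independently with a small error rate; discordant pairs receive an
  error-free third adjudication;
* panelists score their agreement with each proposal on the 9-point
  scale.  For non-controversial codes a panelist endorsing a correct
  proposal draws from a high-score distribution (mass on {7,8,9}, mode
  8) and rejects an incorrect one from a low-score distribution (mass
  on {1,2,3}, mode 2).  A small configured fraction of codes is
  *controversial*: their first-round scores come either from a
  polarized mixture — a split drawn uniformly between 30% and 50% of
  the panel in the low tail, the rest in the high tail, so both tails
  are substantially occupied — or from a centered distribution (mass
  on {4,5,6}); either regime fails first-round agreement (with
  certainty at the study panel size of 18);
* in later rounds contested codes contract toward consensus: each
  panelist draws from the majority-side distribution with probability
  ``1 - 0.5 * (1 - convergence) ** (round - 1)`` and otherwise casts a
  moderated dissent at the scale point adjacent to the agreement band
  (6 when the majority endorses, 4 when it rejects).

All score sampling is integer-valued from explicit discrete
distributions, so a seed fixes the full output exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .icd_registry import ChapterTable, ICDCode
from .panel_votes import (
    Classification,
    PanelRoster,
    ReviewProposal,
    VoteSet,
    adjudicate,
)

__all__ = [
    "CodeLatent",
    "PanelistProfile",
    "SimulationConfig",
    "DEFAULT_CHAPTER_MIX",
    "simulate_codes",
    "simulate_reviewers",
    "simulate_votes",
    "default_profiles",
    "SimulatedVoteSource",
    "simulate_study",
]

# Stylized chapter composition of a 16k-code universe.  Proportions are
# a design choice, not an estimate from any deposited code list; they
# put roughly a quarter of the universe in the infection-like chapters
# so that the implied final inclusion fraction lands near one in five.
DEFAULT_CHAPTER_MIX: dict[str, float] = {
    "infectious_parasitic": 0.07,
    "neoplasms": 0.09,
    "endocrine_metabolic": 0.04,
    "blood": 0.02,
    "mental": 0.04,
    "nervous_sense": 0.06,
    "circulatory": 0.08,
    "respiratory": 0.04,
    "digestive": 0.06,
    "genitourinary": 0.05,
    "pregnancy": 0.06,
    "skin": 0.03,
    "musculoskeletal": 0.06,
    "congenital": 0.04,
    "perinatal": 0.03,
    "symptoms_illdefined": 0.04,
    "injury_poisoning": 0.12,
    "supplementary_v": 0.05,
    "supplementary_e": 0.02,
}

# Explicit score distributions over 1..9 (probability vectors).
ENDORSE_PMF = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.25, 0.50, 0.25)
REJECT_PMF = (0.25, 0.50, 0.25, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
CENTERED_PMF = (0.0, 0.0, 0.0, 0.25, 0.50, 0.25, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class CodeLatent:
    """Latent generative state of one code.

    ``controversy`` > 0 marks the code as genuinely contested: its
    first-round votes are drawn from the polarized/centered regimes
    instead of the concordant one.
    """

    code: str
    p_abx: float
    controversy: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_abx <= 1.0:
            raise ValueError(f"p_abx must lie in [0, 1], got {self.p_abx}")
        if self.controversy < 0.0:
            raise ValueError("controversy must be non-negative")


@dataclass(frozen=True)
class PanelistProfile:
    """Voting behavior of one simulated panelist."""

    panelist_id: str
    concordance: float = 1.0
    severity_shift: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.concordance <= 1.0:
            raise ValueError("concordance must lie in [0, 1]")
        if not -2 <= self.severity_shift <= 2:
            raise ValueError("severity_shift must lie in [-2, 2]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for the synthetic universe.

    The defaults mirror the study setting: a 16,227-code universe voted
    on by 18 panelists, the ≥60% inclusion threshold, and a controversy
    fraction of 69/16,227 ≈ 0.43% of codes failing first-round
    agreement.
    """

    n_codes: int = 16227
    chapter_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHAPTER_MIX)
    )
    p_abx_low: tuple[float, float] = (1.5, 8.0)
    p_abx_high: tuple[float, float] = (8.0, 2.5)
    infectious_like_chapters: tuple[str, ...] = (
        "infectious_parasitic",
        "injury_poisoning",
        "pregnancy",
    )
    infectious_high_weight: float = 0.60
    other_high_weight: float = 0.10
    proposal_threshold: float = 0.60
    reviewer_error_rate: float = 0.02
    n_panelists: int = 18
    controversy_fraction: float = 69 / 16227
    controversy_centered_share: float = 0.5
    convergence: float = 0.8
    n_covid: int = 17
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codes < 1:
            raise ValueError("n_codes must be positive")
        total = float(sum(self.chapter_mix.values()))
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(
                f"chapter_mix proportions must sum to 1, got {total:.6f}"
            )
        if any(p < 0 for p in self.chapter_mix.values()):
            raise ValueError("chapter_mix proportions must be non-negative")
        if not 0.0 <= self.controversy_fraction <= 1.0:
            raise ValueError("controversy_fraction must lie in [0, 1]")
        if not 0.0 <= self.convergence <= 1.0:
            raise ValueError("convergence must lie in [0, 1]")
        if not 0.0 <= self.reviewer_error_rate <= 1.0:
            raise ValueError("reviewer_error_rate must lie in [0, 1]")
        if self.n_panelists < 1:
            raise ValueError("n_panelists must be positive")
        if self.n_covid > self.n_codes:
            raise ValueError("n_covid cannot exceed n_codes")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        for key in ("p_abx_low", "p_abx_high", "infectious_like_chapters"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _largest_remainder_counts(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Apportion n codes over chapters, exact at divisible proportions."""
    items = sorted(mix.items())
    raw = [(cid, n * p) for cid, p in items]
    counts = {cid: int(math.floor(x)) for cid, x in raw}
    shortfall = n - sum(counts.values())
    remainders = sorted(raw, key=lambda t: (-(t[1] - math.floor(t[1])), t[0]))
    for cid, _ in remainders[:shortfall]:
        counts[cid] += 1
    return counts


def _chapter_prefixes(chapter, table: ChapterTable) -> list[str]:
    """All syntactically valid three-character prefixes of a chapter."""
    if chapter.family == "numeric":
        lo, hi = int(chapter.prefix_start), int(chapter.prefix_end)
        return [f"{i:03d}" for i in range(lo, hi + 1)]
    if chapter.family == "V":
        lo, hi = int(chapter.prefix_start[1:]), int(chapter.prefix_end[1:])
        # real V codes stop at V91 even though the table spans V00-V99
        lo, hi = max(lo, 1), min(hi, 91)
        return [f"V{i:02d}" for i in range(lo, hi + 1)]
    lo, hi = int(chapter.prefix_start[1:]), int(chapter.prefix_end[1:])
    return [f"E{i:03d}" for i in range(lo, hi + 1)]


def _extend(prefix: str, family: str, rng: np.random.Generator) -> str:
    if family == "E":
        # E codes allow at most one decimal digit
        kind = rng.choice(2, p=[0.3, 0.7])
        return prefix if kind == 0 else f"{prefix}.{rng.integers(0, 10)}"
    kind = rng.choice(3, p=[0.15, 0.55, 0.30])
    if kind == 0:
        return prefix
    if kind == 1:
        return f"{prefix}.{rng.integers(0, 10)}"
    return f"{prefix}.{rng.integers(0, 10)}{rng.integers(0, 10)}"


def simulate_codes(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    table: ChapterTable | None = None,
) -> tuple[list[ICDCode], dict[str, CodeLatent]]:
    """Draw a synthetic code universe with latent antimicrobial probabilities.

    Codes are syntactically valid, unique, distributed over chapters by
    largest-remainder apportionment of the configured mix, and fully
    reproducible under the config seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    table = table if table is not None else ChapterTable.bundled()
    unknown = set(config.chapter_mix) - set(table.chapter_ids)
    if unknown:
        raise ValueError(f"chapter_mix references unknown chapters: {sorted(unknown)}")
    counts = _largest_remainder_counts(config.n_codes, config.chapter_mix)
    codes: list[ICDCode] = []
    latents: dict[str, CodeLatent] = {}
    seen: set[str] = set()
    for chapter_id in sorted(counts):
        n_chapter = counts[chapter_id]
        if n_chapter == 0:
            continue
        chapter = table.chapter(chapter_id)
        prefixes = _chapter_prefixes(chapter, table)
        high_w = (
            config.infectious_high_weight
            if chapter_id in config.infectious_like_chapters
            else config.other_high_weight
        )
        made = 0
        while made < n_chapter:
            prefix = prefixes[int(rng.integers(0, len(prefixes)))]
            code = _extend(prefix, chapter.family, rng)
            if code in seen:
                continue
            seen.add(code)
            if rng.random() < high_w:
                a, b = config.p_abx_high
            else:
                a, b = config.p_abx_low
            p_abx = float(rng.beta(a, b))
            controversial = rng.random() < config.controversy_fraction
            codes.append(
                ICDCode(
                    code=code,
                    description=f"synthetic condition {code}",
                    chapter_id=chapter_id,
                    is_supplementary=chapter.family in ("V", "E"),
                )
            )
            latents[code] = CodeLatent(
                code=code,
                p_abx=p_abx,
                controversy=1.0 if controversial else 0.0,
            )
            made += 1
    if config.n_covid:
        covid_idx = rng.choice(len(codes), size=config.n_covid, replace=False)
        for i in sorted(int(j) for j in covid_idx):
            codes[i] = replace(codes[i], is_covid=True)
    return codes, latents


def simulate_reviewers(
    latents: Mapping[str, CodeLatent],
    error_rate: float,
    rng: np.random.Generator | int,
    threshold: float = 0.60,
) -> list[ReviewProposal]:
    """Dual independent review of every code, with third-review adjudication.

    Each reviewer applies the threshold rule (include iff
    ``p_abx`` ≥ threshold — the boundary itself is included, "at least
    60%") and errs independently with ``error_rate``; the third
    reviewer is error-free.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    proposals = []
    for code in sorted(latents):
        latent = latents[code]
        truth = (
            Classification.INCLUDE
            if latent.p_abx >= threshold
            else Classification.EXCLUDE
        )
        r1 = truth.flipped() if rng.random() < error_rate else truth
        r2 = truth.flipped() if rng.random() < error_rate else truth
        r3 = truth if r1 != r2 else None
        proposals.append(adjudicate(code, r1, r2, r3))
    return proposals


def default_profiles(
    roster: PanelRoster | None = None,
    concordance: float = 1.0,
    severity_shift: int = 0,
) -> list[PanelistProfile]:
    """Homogeneous panel profiles over a roster (default: 18 panelists)."""
    roster = roster if roster is not None else PanelRoster.default()
    return [
        PanelistProfile(pid, concordance=concordance, severity_shift=severity_shift)
        for pid in roster.panelists
    ]


def _shift_clip(scores: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    return np.clip(scores + shifts, 1, 9)


def _draw(pmf: Sequence[float], size: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(np.arange(1, 10), size=size, p=np.asarray(pmf))


def simulate_votes(
    proposals: Sequence[ReviewProposal],
    latents: Mapping[str, CodeLatent],
    profiles: Sequence[PanelistProfile],
    round_number: int,
    config: SimulationConfig,
    rng: np.random.Generator | int,
    previous: Mapping[str, VoteSet] | None = None,
) -> list[VoteSet]:
    """Draw one round of panel votes for the given proposals.

    Round 1 applies the concordant / polarized / centered regimes per
    code; rounds > 1 require the previous round's votes and apply the
    convergence mechanism described in the module docstring.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if len(profiles) != config.n_panelists:
        raise ValueError(
            f"{len(profiles)} profiles supplied but config.n_panelists is "
            f"{config.n_panelists}"
        )
    if round_number > 1 and previous is None:
        raise ValueError("previous-round votes required for rounds > 1")
    n = len(profiles)
    shifts = np.array([p.severity_shift for p in profiles])
    concordances = np.array([p.concordance for p in profiles])
    ids = [p.panelist_id for p in profiles]
    out: list[VoteSet] = []
    for proposal in proposals:
        latent = latents[proposal.code]
        if round_number == 1:
            if latent.controversy > 0:
                if rng.random() < config.controversy_centered_share:
                    scores = _draw(CENTERED_PMF, n, rng)
                else:
                    # polarized: 30-50% of the panel in the low tail keeps
                    # the median out of the agreement bands (or the IQR
                    # above IPRAS), so the code is genuinely contested
                    k_lo = max(1, math.ceil(0.3 * n))
                    k_hi = max(k_lo, n // 2)
                    k = int(rng.integers(k_lo, k_hi + 1))
                    low_idx = rng.choice(n, size=k, replace=False)
                    scores = _draw(ENDORSE_PMF, n, rng)
                    scores[low_idx] = _draw(REJECT_PMF, k, rng)
            else:
                truth = (
                    Classification.INCLUDE
                    if latent.p_abx >= config.proposal_threshold
                    else Classification.EXCLUDE
                )
                correct = proposal.final_proposal == truth
                endorse = (rng.random(n) < concordances) == correct
                scores = np.where(
                    endorse, _draw(ENDORSE_PMF, n, rng), _draw(REJECT_PMF, n, rng)
                )
        else:
            prev = previous[proposal.code]
            majority_high = float(np.mean(prev.score_list())) >= 5.0
            dissent_p = 0.5 * (1.0 - config.convergence) ** (round_number - 1)
            dissent = rng.random(n) < dissent_p
            majority_scores = _draw(
                ENDORSE_PMF if majority_high else REJECT_PMF, n, rng
            )
            moderated = 6 if majority_high else 4
            scores = np.where(dissent, moderated, majority_scores)
        scores = _shift_clip(scores, shifts)
        out.append(
            VoteSet(
                code=proposal.code,
                round_number=round_number,
                scores={pid: int(s) for pid, s in zip(ids, scores)},
            )
        )
    return out


class SimulatedVoteSource:
    """Engine-facing vote provider that draws each round on demand.

    Caches every round it generates so the emitted vote files and the
    engine's view are identical, and remembers the previous round per
    code to drive convergence.
    """

    def __init__(
        self,
        proposals: Sequence[ReviewProposal],
        latents: Mapping[str, CodeLatent],
        config: SimulationConfig,
        profiles: Sequence[PanelistProfile] | None = None,
        rng: np.random.Generator | None = None,
    ):
        self.proposals = {p.code: p for p in proposals}
        self.latents = latents
        self.config = config
        self.profiles = (
            list(profiles)
            if profiles is not None
            else default_profiles(PanelRoster.default(config.n_panelists))
        )
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.rounds: dict[int, list[VoteSet]] = {}
        self._last: dict[str, VoteSet] = {}

    def votes_for_round(
        self, round_number: int, pending: Sequence[str]
    ) -> list[VoteSet]:
        proposals = [self.proposals[c] for c in sorted(pending)]
        votes = simulate_votes(
            proposals,
            self.latents,
            self.profiles,
            round_number,
            self.config,
            self.rng,
            previous=self._last if round_number > 1 else None,
        )
        self.rounds[round_number] = votes
        for vs in votes:
            self._last[vs.code] = vs
        return votes


def simulate_study(
    config: SimulationConfig | None = None,
    table: ChapterTable | None = None,
) -> tuple[list[ICDCode], dict[str, CodeLatent], list[ReviewProposal], SimulatedVoteSource]:
    """One call producing every input the consensus engine needs.

    A single generator seeded by ``config.seed`` drives code
    generation, the reviewer stage, and all voting rounds, so the whole
    study-shaped dataset is reproducible from the seed alone.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    codes, latents = simulate_codes(config, rng, table=table)
    proposals = simulate_reviewers(
        latents, config.reviewer_error_rate, rng, threshold=config.proposal_threshold
    )
    source = SimulatedVoteSource(proposals, latents, config, rng=rng)
    return codes, latents, proposals, source
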