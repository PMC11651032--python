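import pytest

from delphi_codes.agreement_stats import AgreementConfig, RoundStatus, classify_round
from delphi_codes.delphi_engine import (
    ConsensusOutcome,
    EngineConfig,
    EngineError,
    FileVoteSource,
    read_outcome,
    resolve_direction,
    run_delphi,
    run_round,
    write_outcome,
)
from delphi_codes.panel_votes import (
    Classification,
    VoteSet,
    adjudicate,
    write_votes,
)
from delphi_codes.synthetic_panel import (
    SimulationConfig,
    simulate_study,
)

INC, EXC = Classification.INCLUDE, Classification.EXCLUDE


def _votes(code, scores, round_number=1):
    return VoteSet(code, round_number, {f"P{i:02d}": s for i, s in enumerate(scores, 1)})


class StaticSource:
    """Vote source replaying fixed per-round score vectors."""

    def __init__(self, rounds):
        # rounds: {round_number: {code: [scores]}}
        self.rounds = rounds

    def votes_for_round(self, round_number, pending):
        table = self.rounds[round_number]
        return [_votes(c, table[c], round_number) for c in pending if c in table]


class TestResolveDirection:
    def test_high_agreement_endorses_proposal(self):
        high = classify_round([9] * 18)
        assert resolve_direction(INC, high) is INC
        assert resolve_direction(EXC, high) is EXC

    def test_low_agreement_overturns_proposal(self):
        low = classify_round([1] * 18)
        assert resolve_direction(INC, low) is EXC
        assert resolve_direction(EXC, low) is INC

    def test_low_agreement_reclassify_exclude_policy(self):
        low = classify_round([1] * 18)
        assert resolve_direction(INC, low, "reclassify_exclude") is EXC
        assert resolve_direction(EXC, low, "reclassify_exclude") is EXC

    def test_no_agreement_rejected(self):
        contested = classify_round([5] * 18)
        with pytest.raises(EngineError):
            resolve_direction(INC, contested)


class TestRunRound:
    def test_unanimous_panels_leave_nothing_carried_forward(self):
        codes = ["001.1", "002", "003.0", "004.9", "005"]
        votes = [_votes(c, [9] * 18) for c in codes]
        record = run_round(1, codes, votes)
        assert record.carried_forward == ()
        assert record.n_agreed == 5

    def test_polarized_panel_alone_is_carried_forward(self):
        codes = ["001.1", "002", "003.0", "004.9", "005"]
        votes = [_votes(c, [9] * 18) for c in codes[:-1]]
        votes.append(_votes("005", [1] * 6 + [9] * 12))
        record = run_round(1, codes, votes)
        assert record.carried_forward == ("005",)

    def test_votes_for_non_pending_code_rejected(self):
        votes = [_votes("001.1", [9] * 18), _votes("999", [9] * 18)]
        with pytest.raises(EngineError, match="not pending"):
            run_round(1, ["001.1"], votes)

    def test_missing_votes_rejected_in_strict_mode(self):
        votes = [_votes("001.1", [9] * 18)]
        with pytest.raises(EngineError, match="no votes"):
            run_round(1, ["001.1", "002"], votes)
        permissive = EngineConfig(strict=False)
        record = run_round(1, ["001.1", "002"], votes, permissive)
        assert record.carried_forward == ("002",)


class TestRunDelphi:
    def test_two_round_study_shape(self):
        proposals = [adjudicate(c, INC, INC) for c in ["001.1", "002", "003.0"]]
        source = StaticSource(
            {
                1: {
                    "001.1": [9] * 18,
                    "002": [9] * 18,
                    "003.0": [1] * 6 + [9] * 12,  # polarized -> re-voted
                },
                2: {"003.0": [8] * 18},
            }
        )
        outcome = run_delphi(proposals, source)
        assert outcome.rounds_used == 2
        assert outcome.complete
        assert outcome.settling_round == {"001.1": 1, "002": 1, "003.0": 2}
        assert outcome.history[0].carried_forward == ("003.0",)
        assert outcome.history[1].evaluated_codes == ("003.0",)
        assert set(outcome.final_classification.values()) == {INC}

    def test_all_unanimous_needs_single_round(self):
        proposals = [adjudicate("486", INC, INC), adjudicate("487.0", EXC, EXC)]
        source = StaticSource({1: {"486": [9] * 18, "487.0": [9] * 18}})
        outcome = run_delphi(proposals, source)
        assert outcome.rounds_used == 1
        assert outcome.final_classification == {"486": INC, "487.0": EXC}

    def test_perpetually_contested_code_yields_partial_outcome(self):
        proposals = [adjudicate("486", INC, INC)]
        source = StaticSource({r: {"486": [5] * 18} for r in range(1, 4)})
        outcome = run_delphi(proposals, source, EngineConfig(max_rounds=3))
        assert not outcome.complete
        assert outcome.unresolved == ("486",)
        assert outcome.rounds_used == 3
        assert any("max_rounds" in w for w in outcome.warnings)

    def test_conservation_and_history_consistency(self, small_sim_config):
        codes, latents, proposals, source = simulate_study(small_sim_config)
        outcome = run_delphi(proposals, source)
        n = len(outcome.included_codes()) + len(outcome.excluded_codes()) + len(
            outcome.unresolved
        )
        assert n == len(proposals)
        for code, rnd in outcome.settling_round.items():
            for record in outcome.history:
                if record.round_number < rnd:
                    assert code in record.carried_forward
                elif record.round_number == rnd:
                    assert record.results[code].status is not RoundStatus.NO_AGREEMENT

    def test_determinism_identical_inputs_identical_outcome(self, small_sim_config):
        def once():
            _, _, proposals, source = simulate_study(small_sim_config)
            return run_delphi(proposals, source)

        a, b = once(), once()
        assert a.final_classification == b.final_classification
        assert a.settling_round == b.settling_round
        assert a.rounds_used == b.rounds_used
        for ra, rb in zip(a.history, b.history):
            assert ra.results == rb.results

    def test_duplicate_proposals_rejected(self):
        proposals = [adjudicate("486", INC, INC), adjudicate("486", EXC, EXC)]
        with pytest.raises(EngineError, match="duplicate"):
            run_delphi(proposals, StaticSource({1: {"486": [9] * 18}}))


class TestFileVoteSource:
    def test_reads_rounds_in_order_and_checks_round_column(self, tmp_path):
        r1 = tmp_path / "round_1.csv"
        write_votes([_votes("486", [9] * 3, 1)], r1)
        source = FileVoteSource([r1])
        [vs] = source.votes_for_round(1, ["486"])
        assert vs.scores == {"P01": 9, "P02": 9, "P03": 9}
        with pytest.raises(EngineError, match="only 1 vote file"):
            source.votes_for_round(2, ["486"])
        wrong = tmp_path / "wrong.csv"
        write_votes([_votes("486", [9] * 3, 2)], wrong)
        with pytest.raises(EngineError, match="expected round 1"):
            FileVoteSource([wrong]).votes_for_round(1, ["486"])


class TestOutcomePersistence:
    def test_write_read_round_trip(self, tmp_path, small_sim_config):
        _, _, proposals, source = simulate_study(small_sim_config)
        outcome = run_delphi(proposals, source)
        outdir = write_outcome(outcome, tmp_path / "out")
        back = read_outcome(outdir)
        assert back.final_classification == outcome.final_classification
        assert back.settling_round == outcome.settling_round
        assert back.rounds_used == outcome.rounds_used
        assert [r.carried_forward for r in back.history] == [
            r.carried_forward for r in outcome.history
        ]

    def test_repeated_writes_are_byte_identical(self, tmp_path, small_sim_config):
        _, _, proposals, source = simulate_study(small_sim_config)
        outcome = run_delphi(proposals, source)
        d1 = write_outcome(outcome, tmp_path / "a")
        d2 = write_outcome(outcome, tmp_path / "b")
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()
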