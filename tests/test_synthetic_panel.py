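import numpy as np
import pytest

from delphi_codes.agreement_stats import RoundStatus, classify_round
from delphi_codes.delphi_engine import run_delphi
from delphi_codes.panel_votes import Classification, PanelRoster
from delphi_codes.synthetic_panel import (
    CodeLatent,
    PanelistProfile,
    SimulationConfig,
    default_profiles,
    simulate_codes,
    simulate_reviewers,
    simulate_study,
    simulate_votes,
)

INC, EXC = Classification.INCLUDE, Classification.EXCLUDE


class TestSimulateCodes:
    def test_exact_chapter_counts_at_divisible_mix(self, chapter_table):
        config = SimulationConfig(
            n_codes=100,
            chapter_mix={"infectious_parasitic": 0.5, "injury_poisoning": 0.5},
            n_covid=0,
            seed=7,
        )
        codes, latents = simulate_codes(config, table=chapter_table)
        assert len(codes) == 100
        counts = {}
        for c in codes:
            counts[c.chapter_id] = counts.get(c.chapter_id, 0) + 1
        assert counts == {"infectious_parasitic": 50, "injury_poisoning": 50}
        assert set(latents) == {c.code for c in codes}

    def test_seeded_determinism(self, chapter_table, small_sim_config):
        a = simulate_codes(small_sim_config, table=chapter_table)
        b = simulate_codes(small_sim_config, table=chapter_table)
        assert a == b

    def test_mix_not_summing_to_one_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(
                chapter_mix={"infectious_parasitic": 0.5, "injury_poisoning": 0.4}
            )

    def test_unknown_chapter_in_mix_rejected(self, chapter_table):
        config = SimulationConfig(chapter_mix={"oncology": 1.0}, n_codes=10, n_covid=0)
        with pytest.raises(ValueError, match="unknown chapters"):
            simulate_codes(config, table=chapter_table)

    def test_codes_unique_valid_and_covid_flagged(self, chapter_table, small_sim_config):
        codes, _ = simulate_codes(small_sim_config, table=chapter_table)
        assert len({c.code for c in codes}) == len(codes)
        for c in codes:
            assert chapter_table.assign(c.code) == c.chapter_id
        assert sum(c.is_covid for c in codes) == small_sim_config.n_covid


class TestSimulateReviewers:
    def test_zero_error_rate_reproduces_threshold_rule(self):
        latents = {
            f"{i:03d}": CodeLatent(f"{i:03d}", p)
            for i, p in enumerate([0.1, 0.59, 0.60, 0.61, 0.95], start=1)
        }
        proposals = simulate_reviewers(latents, 0.0, rng=0)
        by_code = {p.code: p for p in proposals}
        assert by_code["001"].final_proposal is EXC
        assert by_code["002"].final_proposal is EXC
        # the boundary itself is included: "at least 60%"
        assert by_code["003"].final_proposal is INC
        assert by_code["004"].final_proposal is INC
        assert not any(p.adjudicated for p in proposals)

    def test_adjudicated_fraction_matches_discordance_probability(self):
        # P(discordant) = 2 e (1 - e) = 0.5 at e = 0.5
        n = 4000
        codes = [f"{100 + i // 100:03d}.{i % 100:02d}" for i in range(n)]
        latents = {code: CodeLatent(code, 0.9) for code in codes}
        proposals = simulate_reviewers(latents, 0.5, rng=11)
        frac = sum(p.adjudicated for p in proposals) / len(proposals)
        assert frac == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / n))

    def test_adjudication_restores_truth(self):
        latents = {"486": CodeLatent("486", 0.95)}
        rng = np.random.default_rng(3)
        for _ in range(50):
            [p] = simulate_reviewers(latents, 0.5, rng)
            if p.adjudicated:
                assert p.final_proposal is INC  # third reviewer is error-free


class TestSimulateVotes:
    def test_degenerate_concordant_regime_all_agree_high(self, small_sim_config):
        from dataclasses import replace

        config = replace(
            small_sim_config, controversy_fraction=0.0, reviewer_error_rate=0.0
        )
        codes, latents, proposals, source = simulate_study(config)
        votes = source.votes_for_round(1, [p.code for p in proposals])
        statuses = {classify_round(v).status for v in votes}
        assert statuses == {RoundStatus.AGREE_HIGH}

    def test_controversial_codes_fail_first_round_agreement(self):
        config = SimulationConfig(
            n_codes=60,
            chapter_mix={"infectious_parasitic": 1.0},
            controversy_fraction=1.0,
            n_covid=0,
            seed=5,
        )
        codes, latents, proposals, source = simulate_study(config)
        votes = source.votes_for_round(1, [p.code for p in proposals])
        statuses = [classify_round(v).status for v in votes]
        # at the study panel size both controversial regimes are genuinely
        # contested: centered medians sit in [4, 6] and polarized splits
        # keep 30-50% of the panel in the low tail
        assert set(statuses) == {RoundStatus.NO_AGREEMENT}

    def test_carried_forward_count_tracks_controversy_fraction(self):
        config = SimulationConfig(
            n_codes=4000,
            chapter_mix={"infectious_parasitic": 0.5, "injury_poisoning": 0.5},
            controversy_fraction=0.02,
            n_covid=0,
            seed=9,
        )
        _, _, proposals, source = simulate_study(config)
        outcome = run_delphi(proposals, source)
        contested = len(outcome.history[0].carried_forward)
        expected = config.n_codes * config.controversy_fraction
        assert contested == pytest.approx(expected, abs=3 * np.sqrt(expected))

    def test_profile_count_must_match_config(self, small_sim_config):
        codes, latents, proposals, _ = simulate_study(small_sim_config)
        profiles = default_profiles(PanelRoster.default(5))
        with pytest.raises(ValueError, match="n_panelists"):
            simulate_votes(
                proposals, latents, profiles, 1, small_sim_config, rng=0
            )

    def test_rounds_after_first_require_previous_votes(self, small_sim_config):
        codes, latents, proposals, _ = simulate_study(small_sim_config)
        profiles = default_profiles(PanelRoster.default(small_sim_config.n_panelists))
        with pytest.raises(ValueError, match="previous"):
            simulate_votes(
                proposals, latents, profiles, 2, small_sim_config, rng=0
            )

    def test_severity_shift_clips_to_scale(self, small_sim_config):
        codes, latents, proposals, _ = simulate_study(small_sim_config)
        profiles = default_profiles(
            PanelRoster.default(small_sim_config.n_panelists), severity_shift=2
        )
        votes = simulate_votes(
            proposals[:20], latents, profiles, 1, small_sim_config, rng=0
        )
        scores = [s for v in votes for s in v.scores.values()]
        assert max(scores) <= 9 and min(scores) >= 1


class TestPlantedTruthRecovery:
    def test_noise_free_regime_recovers_threshold_rule_exactly(self, chapter_table):
        config = SimulationConfig(
            n_codes=2000,
            chapter_mix={
                "infectious_parasitic": 0.4,
                "injury_poisoning": 0.3,
                "respiratory": 0.3,
            },
            reviewer_error_rate=0.0,
            controversy_fraction=0.0,
            n_covid=0,
            seed=13,
        )
        _, latents, proposals, source = simulate_study(config)
        outcome = run_delphi(proposals, source)
        assert outcome.rounds_used == 1
        for code, latent in latents.items():
            expected = INC if latent.p_abx >= 0.60 else EXC
            assert outcome.final_classification[code] is expected


def test_profile_validation():
    with pytest.raises(ValueError):
        PanelistProfile("A", concordance=1.5)
    with pytest.raises(ValueError):
        PanelistProfile("A", severity_shift=3)


def test_latent_validation():
    with pytest.raises(ValueError):
        CodeLatent("486", p_abx=1.2)
    with pytest.raises(ValueError):
        CodeLatent("486", p_abx=0.5, controversy=-1)
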