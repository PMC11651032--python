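import pytest
from hypothesis import settings

from delphi_codes.icd_registry import ChapterTable
from delphi_codes.synthetic_panel import SimulationConfig

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def chapter_table() -> ChapterTable:
    return ChapterTable.bundled()


@pytest.fixture
def small_sim_config() -> SimulationConfig:
    """A fast simulation: a few hundred codes, study-shaped otherwise."""
    return SimulationConfig(
        n_codes=400,
        chapter_mix={
            "infectious_parasitic": 0.25,
            "injury_poisoning": 0.25,
            "respiratory": 0.25,
            "supplementary_v": 0.25,
        },
        n_covid=4,
        seed=2024,
    )
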