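from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from icatq.proteome import ProteinRecord
from icatq.simulate import (
    GroundTruthProtein,
    MixtureModelParams,
    NoiseModel,
    TruthClass,
    assign_ground_truth,
    simulate_proteome,
)


@pytest.fixture
def tiny_proteome() -> list[ProteinRecord]:
    """Four hand-written proteins with Cys counts 0, 2, 1, 2."""
    return [
        ProteinRecord("P1", "GGGG"),
        ProteinRecord("P2", "CCGG"),
        ProteinRecord("P3", "ACKR"),
        ProteinRecord("P4", "CMCM"),
    ]


@pytest.fixture
def fasta_file(tmp_path):
    path = tmp_path / "proteome.fasta"
    path.write_text(">P1 desc\nGGGG\n>P2\nCCGG\n>P3\nacKR\n>P4\nCMCM*\n")
    return path


@pytest.fixture(scope="session")
def sim_proteome():
    """A moderate random proteome shared across simulation tests."""
    return simulate_proteome(60, length_range=(60, 200), seed=11)


@pytest.fixture(scope="session")
def sim_truth(sim_proteome):
    mix = {
        TruthClass.HET_EXCLUSIVE: 0.1,
        TruthClass.HET_ENRICHED: 0.25,
        TruthClass.EQUAL: 0.3,
        TruthClass.FIL_ENRICHED: 0.25,
        TruthClass.VEG_EXCLUSIVE: 0.1,
    }
    return assign_ground_truth(sim_proteome, mix, fold_range=(2.5, 8.0), seed=12)


@pytest.fixture
def params() -> MixtureModelParams:
    return MixtureModelParams(0.075)


@pytest.fixture
def noiseless() -> NoiseModel:
    return NoiseModel(lognormal_sigma=0.0, detection_limit=0.0, seed=5)
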