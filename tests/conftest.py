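import pytest

from twinconn.io import Block, TaskDesign, TwinManifest, TwinPair
from twinconn.synth import (AceSpec, CohortShape, StatePlan, block_correlation,
                            simulate_ace_phenotypes)

NETWORKS6 = ("Visual", "Somatomotor", "DorsalAttention", "VentralAttention",
             "Frontoparietal", "Default")


@pytest.fixture(scope="session")
def roi12():
    """12 synthetic ROI labels mapped 2-per-network to six Yeo networks."""
    labels = [f"R{i:02d}" for i in range(12)]
    nets = [n for n in NETWORKS6 for _ in range(2)]
    return labels, dict(zip(labels, nets))


@pytest.fixture
def small_manifest():
    return TwinManifest(
        [TwinPair(f"MZP{i}", f"mz{i}a", f"mz{i}b", "MZ") for i in range(5)]
        + [TwinPair(f"DZP{i}", f"dz{i}a", f"dz{i}b", "DZ") for i in range(5)]
    )


@pytest.fixture
def simple_design():
    return TaskDesign([
        Block(0.0, 2.5, "cue"), Block(2.5, 25.0, "0bk"),
        Block(27.5, 2.5, "cue"), Block(30.0, 25.0, "2bk"),
        Block(55.0, 25.0, "0bk"), Block(80.0, 25.0, "2bk"),
    ])


@pytest.fixture
def ace_pairs():
    """A mid-size cohort drawn under ACE truth (0.5, 0.1, 0.4)."""
    return simulate_ace_phenotypes(AceSpec(0.5, 0.1, 0.4),
                                   CohortShape(400, 400, seed=11))


@pytest.fixture(scope="session")
def two_state_plan(roi12):
    labels, nmap = roi12
    nets = [nmap[l] for l in labels]
    return StatePlan(
        [0.9, 0.9],
        [block_correlation(nets, 0.55, 0.05),
         block_correlation(nets, 0.10, 0.05)],
    )
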