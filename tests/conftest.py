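import numpy as np
import pytest

from mirenrich import (SimulationConfig, TargetPredictionMap, generate_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def small_predictions():
    return TargetPredictionMap(
        family_targets={
            "famA": frozenset({"g1", "g2", "g3"}),
            "famB": frozenset({"g4", "g5", "g6"}),
        },
        family_members={
            "famA": frozenset({"miR-a-5p"}),
            "famB": frozenset({"miR-b-5p", "miR-b2-3p"}),
        },
    )


@pytest.fixture
def planted_dataset():
    """Default study conditions: 2000 genes, 50 families of 40 targets,
    5 active families with a 3-sigma planted repression."""
    return generate_dataset(SimulationConfig(seed=11))


def write_tsv(path, text):
    path.write_text(text, encoding="utf-8")
    return str(path)
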