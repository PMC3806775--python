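import numpy as np
import pytest

from metaloc.core import GoldStandard, PredictorOutput


@pytest.fixture
def tiny_gold() -> GoldStandard:
    """Four proteins, one multi-localized."""
    return GoldStandard(
        positives={
            "prot1": {"mito"},
            "prot2": {"plast"},
            "prot3": {"mito", "nucl"},
            "prot4": {"vacu"},
        }
    )


@pytest.fixture
def tiny_outputs() -> list[PredictorOutput]:
    """Two predictors with different coverage over the four tiny proteins."""
    cov_a = frozenset({"mito", "plast", "nucl", "vacu"})
    cov_b = frozenset({"mito", "plast"})
    return [
        PredictorOutput("predA", "prot1", {"mito": 0.9, "plast": 0.2, "nucl": 0.1, "vacu": 0.15}, cov_a),
        PredictorOutput("predA", "prot2", {"mito": 0.3, "plast": 0.8, "nucl": 0.2, "vacu": 0.1}, cov_a),
        PredictorOutput("predA", "prot3", {"mito": 0.7, "plast": 0.1, "nucl": 0.6, "vacu": 0.05}, cov_a),
        PredictorOutput("predA", "prot4", {"mito": 0.2, "plast": 0.3, "nucl": 0.25, "vacu": 0.75}, cov_a),
        PredictorOutput("predB", "prot1", {"mito": 0.85, "plast": 0.4}, cov_b),
        PredictorOutput("predB", "prot2", {"mito": 0.35, "plast": 0.9}, cov_b),
        PredictorOutput("predB", "prot3", {"mito": 0.6, "plast": 0.3}, cov_b),
        # predB emitted nothing for prot4 (miss)
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
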