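import numpy as np
import pytest

from hjdnet.genomics import AlterationMatrix, SurvivalRecord
from hjdnet.synthetic_data import GeneratorConfig, write_fixtures


@pytest.fixture
def small_matrix() -> AlterationMatrix:
    """4 samples x 3 genes: A altered in s1,s2; B in s2; C never."""
    return AlterationMatrix(
        samples=["s1", "s2", "s3", "s4"],
        genes=["A", "B", "C"],
        events={
            ("s1", "A"): frozenset({"missense_mutation"}),
            ("s2", "A"): frozenset({"amplification"}),
            ("s2", "B"): frozenset({"deep_deletion"}),
        },
    )


def exponential_arm(rng: np.random.Generator, n: int, hazard: float,
                    censor_hazard: float, prefix: str) -> list[SurvivalRecord]:
    """Exponential event times with independent exponential censoring."""
    t = rng.exponential(1.0 / hazard, n)
    c = rng.exponential(1.0 / censor_hazard, n)
    return [SurvivalRecord(f"{prefix}{i}", float(min(a, b)), int(a <= b))
            for i, (a, b) in enumerate(zip(t, c))]


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A complete set of synthetic pipeline inputs at seed 42."""
    out = tmp_path_factory.mktemp("fixtures")
    truth = write_fixtures(GeneratorConfig(seed=42), out)
    return out, truth
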