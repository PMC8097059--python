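import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from kinsig import GeneratorConfig, PlantedKinase, QuantMatrix, SampleDesign

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def two_group_design() -> SampleDesign:
    rows = [(f"case_{i}", "case", i, "case") for i in range(1, 4)]
    rows += [(f"control_{i}", "control", i, "control") for i in range(1, 4)]
    return SampleDesign(pd.DataFrame(
        rows, columns=["sample_id", "condition", "replicate", "group_role"]))


@pytest.fixture
def small_matrix(two_group_design) -> QuantMatrix:
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.normal(25.0, 1.0, (20, 6)),
        index=[f"P{i:03d}" for i in range(20)],
        columns=two_group_design.sample_ids)
    return QuantMatrix(data)


@pytest.fixture
def planted_config() -> GeneratorConfig:
    return GeneratorConfig(
        n_proteins=150, n_sites=400, n_kinases=12,
        planted_kinases=(PlantedKinase("KIN_A", 1.0, 16),),
        frac_diff_proteins=0.1, missing_rate=0.0)
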