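import numpy as np
import pytest

from twinmd.ace import JointPairTable, joint_table_from_pairs
from twinmd.simulate import (
    CriterionParams,
    expected_cell_probabilities,
    pair_covariance,
    simulate_dichotomized_pairs,
)
from twinmd.tetrachoric import PairTable


@pytest.fixture
def rng():
    return np.random.default_rng(20230901)


def expected_univariate_tables(
    a2: float, c2: float, prevalence: float, n: int = 100_000
) -> dict[str, PairTable]:
    """Infinite-data (expected-count) MZ/DZ tables for one binary trait."""
    p = CriterionParams(a2, c2, prevalence, a2, c2, prevalence)
    return {
        zyg: PairTable(*(expected_cell_probabilities(p, zyg, "in-in") * n), n_pairs_raw=n)
        for zyg in ("MZ", "DZ")
    }


def expected_joint_tables(params: CriterionParams, n: int = 100_000) -> dict[str, JointPairTable]:
    return {
        zyg: JointPairTable(
            expected_cell_probabilities(params, zyg, "joint") * n, n_pairs_raw=n
        )
        for zyg in ("MZ", "DZ")
    }


def simulated_joint_tables(
    params: CriterionParams, n_pairs: int, rng: np.random.Generator
) -> dict[str, JointPairTable]:
    tables = {}
    for zyg in ("MZ", "DZ"):
        sigma = pair_covariance(params, zyg)
        x = simulate_dichotomized_pairs(
            sigma, [params.prevalence_in, params.prevalence_out], n_pairs, rng
        )
        tables[zyg] = joint_table_from_pairs(x, zygosity=zyg)
    return tables
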