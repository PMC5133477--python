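import numpy as np
import pytest

from bvsri import (
    GenotypeMatrix,
    PhenotypeVector,
    SimulationScenario,
    default_maf_spectrum,
    filter_data,
    partition_by_maf,
    simulate_dataset,
)


@pytest.fixture
def tiny_genotypes():
    """4 individuals x 3 variants, no missing data, already minor-oriented."""
    return GenotypeMatrix(
        values=np.array(
            [
                [0, 1, 0],
                [1, 0, 0],
                [2, 0, 1],
                [0, 1, 1],
            ],
            dtype=float,
        ),
        variant_ids=["1_100", "1_200", "1_300"],
        positions=np.array([100, 200, 300]),
    )


@pytest.fixture
def small_study():
    """Seeded n=200, p=8 dataset (2 common + 6 rare) with two causal variants.

    Small enough for exact posterior enumeration, large enough that least
    squares is well conditioned.
    """
    maf = np.array([0.30, 0.15, 0.04, 0.03, 0.02, 0.02, 0.01, 0.01])
    scenario = SimulationScenario(
        n=200, maf_spectrum=maf, causal_ids=(0, 4), effect_sizes=(0.4, 0.9), seed=7
    )
    gm, ph = simulate_dataset(scenario)
    gm, ph, _ = filter_data(gm, ph)
    grouping = partition_by_maf(gm, 0.05)
    return gm, ph, grouping


@pytest.fixture
def recovery_scenario():
    """The two-causal-variant study design used for power checks.

    One common causal variant (MAF 0.3, effect 0.3 trait SD), one rare
    causal variant (MAF 0.005, effect 1.0 trait SD) and 20 noise variants
    on the default log-uniform MAF spectrum, n = 1000.
    """
    maf = np.concatenate([[0.30, 0.005], default_maf_spectrum(p=20)])
    return SimulationScenario(
        n=1000, maf_spectrum=maf, causal_ids=(0, 1), effect_sizes=(0.3, 1.0)
    )
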