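"""Shared fixtures: small simulated crosses and genotype probabilities.

Everything is generated programmatically with fixed seeds; heavy objects
are session-scoped so the cost is paid once.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mvqtlmap import (
    CrossData,
    GeneticMap,
    ModelSpec,
    calc_genoprob,
    simulate_cross,
    simulate_study,
)
from mvqtlmap.simulate import PhenotypeSpec, SimSpec, default_sim_spec


@pytest.fixture(scope="session")
def bench_cross():
    """The benchmark design: 400 F2s, 3 x 100 cM x 11 markers, 4 phenotypes."""
    return simulate_study(seed=11)


@pytest.fixture(scope="session")
def bench_probs(bench_cross):
    return calc_genoprob(bench_cross, step=2.0)


@pytest.fixture(scope="session")
def big_cross():
    """Large cross (n=10,000) for effect-recovery checks; marker-only grid."""
    return simulate_cross(default_sim_spec(n_males=5000, n_females=5000, seed=42))


@pytest.fixture(scope="session")
def big_probs(big_cross):
    return calc_genoprob(big_cross, step=50.0)


@pytest.fixture
def toy_cross():
    """3 individuals x 2 markers, one phenotype, hand-checkable."""
    gmap = GeneticMap(("1",), {"1": (("m1", 0.0), ("m2", 10.0))})
    geno = np.array([[0, 1], [2, 0], [1, -1]], dtype=np.int8)
    pheno = pd.DataFrame({"y": [1.5, -0.2, 0.7]})
    return CrossData(cross_type="f2", map=gmap, genotypes=geno, phenotypes=pheno)


@pytest.fixture
def null_cross():
    """Single-chromosome pure-noise cross (n=200), for calibration work."""
    spec = SimSpec(
        n_males=100,
        n_females=100,
        chromosomes=((100.0, 11),),
        seed=5,
        phenotypes=(PhenotypeSpec(name="noise"),),
    )
    return simulate_cross(spec)


@pytest.fixture
def sex_spec():
    return ModelSpec(
        phenotype="phenotype2", mean_covariates=("sex",), var_covariates=("sex",)
    )
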