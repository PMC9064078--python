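import numpy as np
import pytest

from mtme import (
    PhenotypeRecord,
    PhenotypeTable,
    RunConfig,
    assemble,
    build_model_spec,
    default_rice_scenario,
    run_gibbs,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def rice_design_truth():
    return default_rice_scenario(1)


@pytest.fixture(scope="session")
def rice_table(rice_design_truth):
    design, truth = rice_design_truth
    return simulate_phenotypes(design, truth, seed=1)


@pytest.fixture(scope="session")
def rice_fit(rice_table):
    """One moderately sized full-model fit shared across tests."""
    model = assemble(rice_table, build_model_spec("full", rice_table.traits))
    cfg = RunConfig(
        n_iter=6000, burn_in=1000, thin=5, seed=11, store_effects=True
    )
    return run_gibbs(model, cfg), model


@pytest.fixture
def tiny_table():
    """Smallest valid design: 2 genotypes x 1 env x 2 blocks x 1 trait."""
    recs = [
        PhenotypeRecord("g1", "E1", "1", "yield", 10.0),
        PhenotypeRecord("g2", "E1", "1", "yield", 12.0),
        PhenotypeRecord("g1", "E1", "2", "yield", 11.0),
        PhenotypeRecord("g2", "E1", "2", "yield", 13.0),
    ]
    return PhenotypeTable(recs)


def make_table(G=4, E=1, B=2, traits=("t1",), seed=0, loc=0.0, scale=1.0):
    rng = np.random.default_rng(seed)
    recs = []
    for e in range(E):
        for b in range(B):
            for g in range(G):
                for t in traits:
                    recs.append(
                        PhenotypeRecord(
                            f"g{g}", f"E{e}", str(b), t,
                            float(loc + scale * rng.standard_normal()),
                        )
                    )
    return PhenotypeTable(recs)
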