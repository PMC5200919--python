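import dataclasses

import numpy as np
import pytest

from padnet.simulate import (
    SimulationConfig,
    generate_gene_annotation,
    generate_pathways,
    simulate,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic study with a planted risk pathway and planted,
    PPI-supported epistatic pairs inside that pathway's genes."""
    base = SimulationConfig(
        n_cases=300,
        n_controls=400,
        n_genes=40,
        snps_per_gene=(2, 4),
        n_pathways=6,
        pathway_size_range=(4, 8),
        risk_pathways={"PW01": 0.45},
        missing_rate=0.02,
        ppi_background_prob=0.02,
        seed=11,
    )
    genes = generate_gene_annotation(base)
    pathways = generate_pathways(base, genes)
    g = pathways["PW01"]
    pairs = [
        (f"{g[0]}_S01", f"{g[1]}_S01", 1.2),
        (f"{g[1]}_S01", f"{g[2]}_S01", 1.2),
        (f"{g[2]}_S01", f"{g[3]}_S01", 1.2),
    ]
    cfg = dataclasses.replace(base, epistatic_pairs=pairs)
    return simulate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
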