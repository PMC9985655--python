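import math

import numpy as np
import pandas as pd
import pytest

import phylocomm as pc

NEWICK_3TIP = "((A:1,B:1):1,C:2);"


@pytest.fixture(scope="session")
def tree3():
    return pc.read_tree(NEWICK_3TIP)


@pytest.fixture(scope="session")
def basis3(tree3):
    return pc.build_balance_basis(tree3)


@pytest.fixture(scope="session")
def tree32():
    return pc.simulate_tree(32, seed=7)


@pytest.fixture(scope="session")
def neutral_sigma():
    return {s: math.inf for s in ("CC", "MM", "WP", "DB")}


@pytest.fixture(scope="session")
def small_bundle():
    """Small default-design synthetic dataset shared across IO/pipeline tests."""
    design = pc.SyntheticDesign(
        n_taxa=32, samples_per_cell=1, controls_per_cell=1, seed=4
    )
    bundle, truth = pc.simulate_communities(design)
    return bundle, truth


def random_metadata(n, rng, sites=("CC", "MM", "WP", "DB")):
    """Balanced-ish random transplant metadata for n samples."""
    ids = [f"S{i:03d}" for i in range(n)]
    return pd.DataFrame(
        {
            "origin_site": rng.choice(sites, n),
            "destination_site": [sites[i % len(sites)] for i in range(n)],
            "timepoint": [1 + (i % 3) for i in range(n)],
            "tissue": ["leaf" if i % 2 == 0 else "root" for i in range(n)],
            "transplant_status": ["transplant"] * n,
            "plot_id": ["p1"] * n,
        },
        index=pd.Index(ids, name="sample_id"),
    )
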