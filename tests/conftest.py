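import numpy as np
import pandas as pd
import pytest

from regnet import (IntegratedNetwork, SimulationParams, build_network_from_bundle,
                    simulate)

# desk-scale simulation used by the slower integration fixtures
SMALL = dict(n_genes=300, n_tfs_annotated=30, n_tfs_assayed=12, n_mirnas=30,
             hot_tf_count=10, n_chromosomes=2, chrom_bp=1_500_000,
             mean_gene_targets_per_tf=40.0)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate(SimulationParams(seed=11, **SMALL))


@pytest.fixture(scope="session")
def small_network(small_bundle):
    net, _ = build_network_from_bundle(small_bundle)
    return net


def random_typed_network(rng, n_nodes=40, p=0.06, signed=False) -> IntegratedNetwork:
    """Random integrated network with valid typed/signed edges."""
    types = rng.choice(["TF", "gene", "miRNA"], size=n_nodes, p=[0.3, 0.5, 0.2])
    nodes = {f"n{i:03d}": t for i, t in enumerate(types)}
    ids = sorted(nodes)
    rows = []
    for u in ids:
        for v in ids:
            if u == v or rng.random() >= p:
                continue
            tu, tv = nodes[u], nodes[v]
            if tu == "TF":
                et = {"TF": "TF>TF", "gene": "TF>gene", "miRNA": "TF>miRNA"}[tv]
            elif tu == "miRNA" and tv in ("gene", "TF"):
                et = f"miRNA>{tv}"
            else:
                continue
            sign = int(rng.choice([1, -1])) if signed else 0
            rows.append((u, v, et, sign))
    edges = pd.DataFrame(rows, columns=["source", "target", "etype", "sign"])
    return IntegratedNetwork(nodes=nodes, edges=edges).validate()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
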