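import networkx as nx
import pytest

from gwasnet.config import PipelineConfig
from gwasnet.scoring import GeneRecord
from gwasnet.simulate import SyntheticConfig, simulate_dataset, write_dataset
from gwasnet import pipeline


@pytest.fixture
def toy_records():
    """Four genes whose scores are hand-computable."""
    return [
        GeneRecord("g1", 1e-10, 1, 1, frozenset({"SBP"}),
                   {"A": 0.01, "B": 0.04}),
        GeneRecord("g2", 1e-20, 5, 2, frozenset({"SBP", "DBP"}),
                   {"A": 0.20, "B": 0.60}),
        GeneRecord("g3", 1e-30, 10, 3, frozenset({"SBP", "DBP", "PP"}),
                   {"A": 0.03, "B": 0.03}),
        GeneRecord("g4", 1e-40, 8, 2, frozenset({"DBP"})),
    ]


@pytest.fixture
def toy_network():
    """Reference network for the worked example.

    GWAS proteins {PA,PB,PC,PD}: induced edges PA-PB, PB-PC make {PA,PB,PC}
    the BN component and PD a GN at distance 2 through the non-GWAS PX.
    """
    g = nx.Graph()
    g.add_edges_from([("PA", "PB"), ("PB", "PC"), ("PD", "PX"),
                      ("PX", "PA"), ("PX", "PY"), ("PY", "PE")])
    return g


@pytest.fixture(scope="session")
def synthetic_dataset():
    return simulate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def synthetic_run(synthetic_dataset, tmp_path_factory):
    """Full pipeline run over the default synthetic study conditions."""
    root = tmp_path_factory.mktemp("synthetic")
    paths = write_dataset(synthetic_dataset, root / "bundle")
    cfg = PipelineConfig(
        gene_table=paths["gene_table"], edge_list=paths["edge_list"],
        gene_map=paths["gene_map"], gene_sets=paths["gene_sets"],
        out_dir=str(root / "out"))
    return synthetic_dataset, cfg, pipeline.run_all(cfg)
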