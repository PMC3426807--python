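import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_tables(tmp_path):
    """A 2-gene / 2-run count table with its sample sheet on disk."""
    counts = tmp_path / "counts.tsv"
    counts.write_text(
        "gene_id\tlength\trun1\trun2\n"
        "geneA\t1000\t3\t5\n"
        "geneB\t2000\t0\t7\n"
    )
    sheet = tmp_path / "sheet.tsv"
    sheet.write_text(
        "run_id\tsample_id\tlibrary_id\tlane_id\tcondition\n"
        "run1\tS1\tL1\tlane1\tA\n"
        "run2\tS2\tL2\tlane1\tB\n"
    )
    return counts, sheet


@pytest.fixture(scope="session")
def binomial_pair():
    """One pure-binomial A-vs-B comparison (no DE, D = 0), 1000 genes."""
    import depthbb as d

    cfg = d.SimulationConfig(n_genes=1000, n_pairs=1, d_scale=0.0, seed=5)
    pairs, truth = d.simulate_pairs(cfg)
    return pairs.pair(0), truth


@pytest.fixture(scope="session")
def overdispersed_set():
    """Three duplicate pairs with gamma=0.5 overdispersion, 400 genes."""
    import depthbb as d

    cfg = d.SimulationConfig(n_genes=400, n_pairs=3, gamma_true=0.5, seed=11)
    return d.simulate_pairs(cfg)
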