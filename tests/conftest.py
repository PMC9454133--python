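import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from tracm7g import SimConfig, simulate_cleavage_libraries, simulate_trna_set
from tracm7g.trnaref import mature_set


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated TRAC-seq experiment shared across tests."""
    cfg = SimConfig(
        seed=1, n_trnas=20, n_modified=8, reads_per_library=5000,
        n_genes=300, depth_per_library=300_000,
    )
    genes, truth = simulate_trna_set(cfg)
    reads, sidecar = simulate_cleavage_libraries(genes, truth, cfg)
    matures = {m.id: m.seq for m in mature_set(genes).values()}
    return {
        "config": cfg, "genes": genes, "truth": truth,
        "reads": reads, "sidecar": sidecar, "matures": matures,
    }
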