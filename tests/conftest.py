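import pytest

from isoshift.simulate import SimulationConfig, generate


@pytest.fixture(scope="session")
def small_bundle():
    """Small synthetic study: 8 miRNAs x 3 isoforms, 300 genes, 3k reads/sample."""
    cfg = SimulationConfig(n_mirnas=8, n_genes=300, depth_smallrna=3000, rng_seed=1)
    return generate(cfg)


@pytest.fixture(scope="session")
def mid_bundle():
    """Mid-size study used for end-to-end runs: 12 miRNAs, 800 genes."""
    cfg = SimulationConfig(n_mirnas=12, n_genes=800, depth_smallrna=8000, rng_seed=3)
    return generate(cfg)


@pytest.fixture(scope="session")
def mid_paths(mid_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("synth")
    return mid_bundle.write(outdir)
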