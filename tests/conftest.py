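import numpy as np
import pytest

from barscreen.barcode_io import AmpliconLayout, BarcodeCatalog, CatalogEntry
from barscreen.screen_sim import (
    PhenotypeClass,
    SimConfig,
    default_gates,
    default_gfp_models,
    demo_mutant_pool,
    random_catalog,
    simulate_screen,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def layout():
    return AmpliconLayout()


@pytest.fixture(scope="session")
def small_catalog():
    return random_catalog(40, np.random.default_rng(7))


@pytest.fixture(scope="session")
def tiny_catalog():
    """Three genes with hand-written barcodes (20 nt)."""
    return BarcodeCatalog(entries=[
        CatalogEntry(gene="G1", uptag="A" * 20, dntag="C" * 20),
        CatalogEntry(gene="G2", uptag="G" * 20, dntag="T" * 20),
        CatalogEntry(gene="G3", uptag="ACGT" * 5, dntag="TGCA" * 5),
    ])


@pytest.fixture(scope="session")
def gfp_model():
    return default_gfp_models()


@pytest.fixture(scope="session")
def gates(gfp_model):
    return default_gates(gfp_model, n_control_cells=50_000, seed=11)


@pytest.fixture(scope="session")
def mini_screen(tmp_path_factory, gfp_model, gates):
    """A small simulated screen shared by demux/enrichment/CLI tests."""
    rng = np.random.default_rng(42)
    catalog = random_catalog(80, rng)
    pool = demo_mutant_pool(
        catalog.genes,
        {PhenotypeClass.GFP_NEG: 4, PhenotypeClass.NON_INDUCER: 2,
         PhenotypeClass.HIGH_BASAL: 2},
        rng,
    )
    config = SimConfig(seed=99, n_cells_sorted=30_000, reads_per_sample=20_000,
                       replicates=2)
    outdir = tmp_path_factory.mktemp("mini_screen")
    out = simulate_screen(pool, gfp_model, gates, catalog, config, outdir)
    return {"catalog": catalog, "pool": pool, "config": config, "output": out,
            "outdir": outdir}


@pytest.fixture(scope="session")
def noise_free_screen(tmp_path_factory, gfp_model, gates):
    """Zero-noise screen: counting must recover the recorded read draws exactly."""
    rng = np.random.default_rng(5)
    catalog = random_catalog(30, rng)
    pool = demo_mutant_pool(catalog.genes, {PhenotypeClass.GFP_NEG: 2}, rng)
    config = SimConfig(seed=17, n_cells_sorted=10_000, reads_per_sample=10_000,
                       replicates=1, per_base_error_rate=0.0, pcr_noise_sd=0.0)
    outdir = tmp_path_factory.mktemp("noise_free_screen")
    out = simulate_screen(pool, gfp_model, gates, catalog, config, outdir)
    return {"catalog": catalog, "pool": pool, "config": config, "output": out,
            "outdir": outdir}
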