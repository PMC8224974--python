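import pytest

from promscape.pipeline import load_config, run_pipeline
from promscape.synthetic import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_dataset():
    """Reference synthetic study at the default scale (seeded once per session)."""
    return simulate_all(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale generator config for tests that re-simulate."""
    return SimulationConfig(
        seed=7,
        n_genes=200,
        chrom_length=4_000_000,
        n_dbps=12,
        n_reservoirs=12,
        ghost_fraction=0.5,
        reservoir_min_dbps=9,
        reservoir_max_dbps=12,
        n_reservoirs_near_expressed=4,
        n_superenhancers=6,
        reads_per_sample=20_000,
        planted_family_copies=60,
        background_peaks_per_dbp=60,
        decoy_families=(("L1", "LINE", 50, (1000, 2000)), ("Alu", "SINE", 80, (250, 350))),
    )


@pytest.fixture(scope="session")
def pipeline_dir(tmp_path_factory):
    """One full default pipeline run shared by integration tests."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = load_config(seed=11)
    run_pipeline(cfg, outdir)
    return outdir
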