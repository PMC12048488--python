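import pytest

from epiquant import SimulationConfig, simulate_ipms


def small_config(seed: int = 7) -> SimulationConfig:
    """Scaled-down full-factorial design for fast module tests."""
    config = SimulationConfig(
        n_proteins=80,
        n_true_interactors=20,
        replicates=3,
        n_igg_runs=12,
        n_epitope_pref=3,
        n_tissue_enriched=3,
        n_polyq_gain=3,
        seed=seed,
    )
    config.melt.n_proteins = 6
    config.melt.n_shifted = 2
    config.fractions.n_proteins = 30
    return config


@pytest.fixture(scope="session")
def ipms_small():
    return simulate_ipms(small_config())


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    from epiquant import write_fixture_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(small_config(), outdir)
    return outdir
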