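import pytest

from homoeopool import NoiseModel, Simulation, SimulationConfig


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A reduced-scale experiment: 144-coordinate library on 6 plates,
    50 kbp regions, 10 assays."""
    params = dict(
        region_length_bp=50_000,
        n_plates=6, rows_per_plate=4, cols_per_plate=6,
        insert_size_mean_bp=20_000, insert_size_sd_bp=2_000,
        insert_size_min_bp=5_000,
        coverage_target=5.0,
        n_assays=16,
        diagonal_modulus=5,
        off_target_fraction=0.0,
        n_masked_amplicons=0,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_sim() -> Simulation:
    return Simulation.generate(small_config())


@pytest.fixture(scope="session")
def small_noiseless_sim() -> Simulation:
    return Simulation.generate(small_config(noise=NoiseModel.noiseless()))
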