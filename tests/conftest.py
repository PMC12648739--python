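import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_lot():
    """A 2x2 seed lot with RGB frames, label maps and ground truth."""
    from germtrack.simulate import GenotypeParams, SimConfig, simulate_lot

    gp = GenotypeParams("G1", seedling_mean_h=40.0, seedling_sd_h=3.0,
                        greening_delay_mean_h=10.0, greening_delay_sd_h=2.0)
    cfg = SimConfig(rng_seed=2, n_rows=2, n_cols=2, n_frames=80,
                    genotypes=[gp])
    series, maps, truth = simulate_lot(cfg, render="rgb")
    return cfg, series, maps, truth


@pytest.fixture(scope="session")
def small_lot_result(small_lot):
    from germtrack.pipeline import RunConfig, process_lot

    cfg, series, maps, truth = small_lot
    rcfg = RunConfig(scale_mm_per_px=cfg.scale_mm_per_px,
                     interval_h=cfg.interval_h)
    return rcfg, process_lot(series, maps, truth.rois, rcfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
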