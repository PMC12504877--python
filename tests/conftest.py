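import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from marrowdcc.pipeline import PipelineConfig, evaluate_run, run_pipeline
from marrowdcc.synthetic import SceneParams, generate_case, small_scene

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_banded_case():
    """4800² scene, 3×3 tiles, one band row each; junction has 2 TOI + 1 blank."""
    params = small_scene(band_fractions=(1 / 3, 1 / 3, 1 / 3), bad_tile_fraction=0.34)
    return generate_case(params, 0)


@pytest.fixture(scope="session")
def tiny_case():
    """2400² scene with 800-px tiles; the fastest end-to-end configuration."""
    params = SceneParams(
        wsi_height=2400,
        wsi_width=2400,
        tile_size=800,
        thumb_factor=100,
        band_fractions=(1 / 3, 1 / 3, 1 / 3),
        bad_tile_fraction=0.0,
        cells_per_good_tile=10.0,
    )
    return generate_case(params, 3)


@pytest.fixture(scope="session")
def oracle_run(small_banded_case):
    report = run_pipeline(small_banded_case, PipelineConfig.all_oracle())
    bundle = evaluate_run(report, small_banded_case)
    return report, bundle


@pytest.fixture(scope="session")
def default_case():
    """The default 16000² scene at seed 0 — the package's standard test bed."""
    return generate_case(SceneParams(), 0)


@pytest.fixture(scope="session")
def reference_run(default_case):
    report = run_pipeline(default_case, PipelineConfig())
    bundle = evaluate_run(report, default_case)
    return report, bundle


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
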