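import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glowtrack.pipeline import run_pipeline, simulated_layout
from glowtrack.simulate import SimConfig, render_stack

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def control_stack():
    """Rendered 12-fly, 2-day control stack at default (moderate) SNR."""
    cfg = SimConfig(n_days=2.0, image_size=(256, 480), n_columns=12, n_rows=1,
                    col_pitch_px=32, seed=7)
    return render_stack(cfg)


@pytest.fixture(scope="session")
def control_pipeline(control_stack):
    """Full pipeline output for the shared control stack."""
    quants, records, geom = run_pipeline(
        control_stack.stack, control_stack.markers_in_frame,
        simulated_layout(control_stack.config),
    )
    return quants, records, geom


@pytest.fixture(scope="session")
def small_noise_free_stack():
    """Single-fly noise-free float stack for photon-accounting checks."""
    cfg = SimConfig(n_days=0.05, image_size=(256, 100), n_columns=1, n_rows=1,
                    background_level=0.0, tube_glow=0.0, read_noise_sd=0.0,
                    marker_counts=0.0, seed=3)
    return render_stack(cfg, noise=False, quantize=False)


def make_flat_profile(value=100.0, n=46):
    from glowtrack.quantify import TubeProfile

    return TubeProfile(bin_sum=np.full(n, float(value)),
                       bin_max=np.full(n, float(value) / 68.0))
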