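import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240911)


@pytest.fixture(scope="session")
def recovery_scene():
    """The four-cell recovery scene: counts (5, 8, 12, 20), low jitter."""
    from chlorocount import SceneSpec, generate_scene

    spec = SceneSpec(counts=(5, 8, 12, 20), jitter_px=0.5, seed=7)
    stack, truth = generate_scene(spec)
    return spec, stack, truth
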