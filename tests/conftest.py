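import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rocits import simulate as sim
from rocits.config import PipelineConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def template():
    """One synthetic 16S-ITS template: (sequence, its_start)."""
    return sim.make_template(np.random.default_rng(2))


@pytest.fixture(scope="session")
def noisy_subread_sets(cfg, template):
    """Segmented sub-read sets from 30 noisy k>=5 reads of one template."""
    from rocits.segment import segment_read

    base, _ = template
    rng = np.random.default_rng(77)
    out = []
    for i in range(30):
        k = int(rng.integers(5, 10))
        rec, _ = sim.simulate_concatemer_read(
            base, cfg.construct, k, ("ACGTT", "TTAGC"), sim.ErrorModel(), rng,
            read_id=f"r{i}",
        )
        srs = segment_read(rec, cfg.construct, cfg.segment)
        if not srs.discard_reason:
            out.append(srs)
    return out
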