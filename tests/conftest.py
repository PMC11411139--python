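import numpy as np
import pytest

from connfp import SyntheticModelSpec, fingerprint_cohort_spec, generate_edge_panel


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-group edge panel with reliable within-network edges (R=24)."""
    spec = fingerprint_cohort_spec(
        {"CU": 10, "AD": 6}, n_regions=24, seed=11, between_reliable_fraction=0.1
    )
    return generate_edge_panel(spec)


@pytest.fixture(scope="session")
def flat_spec():
    """Single-group spec with uniform sigma across all edges (true ICC 0.6)."""
    return SyntheticModelSpec(
        n_subjects_per_group={"CU": 20},
        n_regions=16,
        sigma_b=np.sqrt(0.6),
        sigma_w=np.sqrt(0.4),
        seed=5,
    )
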