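import numpy as np
import pytest

from dsnis.synthdata import SyntheticSpec, default_signal_edges, generate_cohort

# fixed master seed for every deterministic synthetic experiment in the suite
MASTER_SEED = 20180313


@pytest.fixture(scope="session")
def recovery_cohort():
    """Planted-edge cohort for the edge-recovery experiment:
    10 signal edges at effect size 0.5, 30 patients + 30 controls, T=400."""
    edges = default_signal_edges(30, 10, seed=MASTER_SEED)
    spec = SyntheticSpec(
        n_patients=30, n_controls=30, n_regions=30, n_timepoints=400,
        signal_edges=edges, effect_size=0.5, seed=MASTER_SEED,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def easy_cohort():
    """Separable cohort: 20 signal edges at effect size 0.6, 20+20, T=300."""
    edges = default_signal_edges(30, 20, seed=MASTER_SEED + 1)
    spec = SyntheticSpec(
        n_patients=20, n_controls=20, n_regions=30, n_timepoints=300,
        signal_edges=edges, effect_size=0.6, seed=MASTER_SEED + 1,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    """No group difference at all (effect size 0, no signal edges)."""
    spec = SyntheticSpec(
        n_patients=20, n_controls=20, n_regions=30, n_timepoints=300,
        signal_edges=(), effect_size=0.0, seed=MASTER_SEED + 2,
    )
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(MASTER_SEED)
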