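import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from flexsemble.structures import Structure
from flexsemble.synthetic import SyntheticEnsembleSpec, generate_fragment_ensembles

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic world: two 20-member fragment pools sharing
    domain B, with full ground truth (clash matrix, planted modes, Rg)."""
    spec = SyntheticEnsembleSpec(seed=1)
    ab, bc, truth = generate_fragment_ensembles(spec)
    return ab, bc, truth


@pytest.fixture(scope="session")
def small_world():
    """A reduced world for fast pipeline-level tests."""
    spec = SyntheticEnsembleSpec(
        seed=3, n_beads=(40, 40, 80), n_members=(8, 8), linker_len=(4, 4)
    )
    ab, bc, truth = generate_fragment_ensembles(spec)
    return ab, bc, truth


def bead_structure(coords, label="beads"):
    """Uniform carbon bead cloud around arbitrary coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return Structure(
        atom_names=np.full(n, "CA"),
        elements=np.full(n, "C"),
        res_ids=np.arange(1, n + 1),
        res_names=np.full(n, "GLY"),
        chain_ids=np.full(n, "A"),
        coords=coords,
        label=label,
    )


@pytest.fixture
def make_beads():
    return bead_structure
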