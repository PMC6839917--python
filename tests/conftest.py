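import numpy as np
import pytest

from saxstate.models import CalphaModel
from saxstate.synthetic import DumbbellSpec, build_dumbbell

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("ci")
except ImportError:  # hypothesis is an optional test dependency
    pass


def toy_model(coords, chain="A", start_resnum=1, labels=None, model_id="toy"):
    """Build a minimal single-chain model from raw coordinates."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    return CalphaModel(
        chain_ids=np.asarray([chain] * n, dtype=object),
        residue_numbers=np.arange(start_resnum, start_resnum + n),
        residue_names=np.asarray(["ALA"] * n, dtype=object),
        coords=coords,
        domain_labels=labels,
        model_id=model_id,
    )


@pytest.fixture(scope="session")
def small_bent_spec():
    return DumbbellSpec(
        lobe_radii=(12.0, 12.0),
        lobe_bead_counts=(40, 40),
        linker_length=16,
        hinge_angle=120.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_extended_spec(small_bent_spec):
    return DumbbellSpec(
        lobe_radii=small_bent_spec.lobe_radii,
        lobe_bead_counts=small_bent_spec.lobe_bead_counts,
        linker_length=small_bent_spec.linker_length,
        hinge_angle=180.0,
        seed=6,
    )


@pytest.fixture(scope="session")
def small_bent(small_bent_spec):
    return build_dumbbell(small_bent_spec)


@pytest.fixture(scope="session")
def small_extended(small_extended_spec):
    return build_dumbbell(small_extended_spec)


@pytest.fixture(scope="session")
def full_benchmark():
    """Full-size two-state benchmark at the default composition."""
    from saxstate.synthetic import make_two_state_benchmark

    return make_two_state_benchmark(weights=(0.72, 0.28), seed=11)
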