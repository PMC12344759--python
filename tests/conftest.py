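import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

from deskmd import make_fixture

_hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
_hyp_settings.load_profile("deterministic")
from deskmd.model_core import ExternalField, MicroState, SystemSpec


@pytest.fixture
def lj_fluid_100():
    return make_fixture("lj_fluid", {"n": 100}, seed=7)


@pytest.fixture
def two_particle_system():
    """Two LJ particles (A=B=4, i.e. eps=sigma=1) in a roomy box."""
    def build(cutoff=3.0, charges=(0.0, 0.0), c4=0.0, exclusions=()):
        return SystemSpec(
            masses=np.ones(2),
            charges=np.asarray(charges, float),
            types=np.zeros(2, int),
            lj_A=[[4.0]],
            lj_B=[[4.0]],
            c4=[[c4]],
            box=[12.0, 12.0, 12.0],
            cutoff=cutoff,
            exclusions=frozenset(exclusions),
        )
    return build


def harmonic_well_system(n=1, k=1.0, box=10.0, cutoff=1.0):
    """n independent particles in an isotropic harmonic well (no pair terms)."""
    return SystemSpec(
        masses=np.ones(n),
        charges=np.zeros(n),
        types=np.zeros(n, int),
        lj_A=[[0.0]],
        lj_B=[[0.0]],
        box=[box] * 3,
        cutoff=cutoff,
        external=ExternalField(kind="harmonic", k=k),
    )


def state_at(positions, box, velocities=None):
    pos = np.atleast_2d(np.asarray(positions, float))
    vel = np.zeros_like(pos) if velocities is None else np.asarray(velocities, float)
    return MicroState(pos, vel, np.asarray(box, float))
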