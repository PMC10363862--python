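import numpy as np
import pytest

from headturn.room import RoomScene, SourcePlacement

OCTAVES = [125.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0]


@pytest.fixture
def anechoic_scene():
    """Anechoic version of the modeled room with interferer front, target right."""
    return RoomScene(
        dims=(11.0, 13.0, 3.0),
        band_absorption={fc: 1.0 for fc in OCTAVES},
        listener_position=(4.0, 7.0, 1.8),
        sources=[SourcePlacement(0.0, 2.1, 70.0), SourcePlacement(90.0, 2.1, 60.0)],
        scattering=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_scene(dims, listener, sources, alpha=1.0, scattering=0.0):
    return RoomScene(
        dims=dims,
        band_absorption={fc: alpha for fc in OCTAVES},
        listener_position=listener,
        sources=[SourcePlacement(*s) for s in sources],
        scattering=scattering,
    )
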