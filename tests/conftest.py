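import numpy as np
import pytest

from calciscan.phantom import Lesion, PhantomConfig, generate_phantom, table1_fixture


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def single_lesion_phantom():
    """One noiseless coronary lesion: radius 2 mm, peak 300 HU."""
    cfg = PhantomConfig(lesions=[Lesion((20.0, 25.0, 15.0), 2.0, 300.0, "coronary")])
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def two_territory_phantom():
    """A coronary and an aortic lesion, noiseless."""
    cfg = PhantomConfig(
        lesions=[
            Lesion((20.0, 25.0, 15.0), 2.5, 400.0, "coronary"),
            Lesion((20.0, 25.0, 40.0), 3.0, 350.0, "aorta"),
        ]
    )
    return generate_phantom(cfg)


def brute_force_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """Independent flood-fill labeling oracle (BFS over explicit offsets)."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                manhattan = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and manhattan > 1:
                    continue
                if connectivity == 18 and manhattan > 2:
                    continue
                offsets.append((dz, dy, dx))
    remaining = {tuple(v) for v in np.argwhere(mask)}
    components = []
    while remaining:
        seed_voxel = remaining.pop()
        comp = {seed_voxel}
        frontier = [seed_voxel]
        while frontier:
            z, y, x = frontier.pop()
            for dz, dy, dx in offsets:
                nb = (z + dz, y + dy, x + dx)
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        components.append(comp)
    return components
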