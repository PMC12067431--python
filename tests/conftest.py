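import numpy as np
import pytest

from dendrisurf.topology import Frame, MolecularSystem, Species


def make_gas(n: int, L: float, seed: int = 0, tails: bool = False,
             charged: int = 0) -> tuple[MolecularSystem, Frame]:
    """A bare gas of beads for engine tests: WCA by default, optionally the
    first ``charged`` beads alternate +/-1 (kept neutral)."""
    assert charged % 2 == 0, "charged count must be even for neutrality"
    species = np.full(
        n,
        Species.SURFACTANT_TAIL if tails else Species.DENDRIMER_INTERIOR,
        dtype=np.int8,
    )
    charge = np.zeros(n, dtype=np.int8)
    if charged:
        half = charged // 2
        species[:half] = Species.SURFACTANT_COUNTERION
        species[half:charged] = Species.DENDRIMER_COUNTERION
        charge[:half] = 1
        charge[half:charged] = -1
    system = MolecularSystem(
        species=species,
        charge=charge,
        bonds=np.empty((0, 2), dtype=np.int64),
        molecule_id=np.arange(n, dtype=np.int64),
        dendrimer_id=np.full(n, -1, dtype=np.int64),
        n_d=0,
        n_s=0,
        N_t=0,
        N_d=0,
    )
    rng = np.random.default_rng(seed)
    # random placement with a crude push-apart so LJ overlaps are mild
    pos = rng.uniform(0, L, size=(n, 3))
    for _ in range(200):
        dr = pos[:, None, :] - pos[None, :, :]
        dr -= L * np.round(dr / L)
        d2 = np.einsum("ijk,ijk->ij", dr, dr)
        np.fill_diagonal(d2, np.inf)
        i, j = np.unravel_index(np.argmin(d2), d2.shape)
        if d2[i, j] > 0.81:
            break
        step = dr[i, j] / max(np.sqrt(d2[i, j]), 1e-6) * 0.3
        pos[i] += step
        pos[j] -= step
        pos = np.mod(pos, L)
    return system, Frame(pos, L, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
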