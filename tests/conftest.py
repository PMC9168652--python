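import numpy as np
import pytest

from butterflymd.energy import ParameterizedStructure
from butterflymd.geometry import GeometrySeries


@pytest.fixture
def rng():
    return np.random.default_rng(20241105)


@pytest.fixture
def random_series(rng):
    """1000-frame random butterfly series spanning the physically relevant ranges."""
    n = 1000
    return GeometrySeries(
        d7=rng.uniform(2.0, 6.0, n),
        d8=rng.uniform(2.0, 6.0, n),
        a7=rng.uniform(0.0, 180.0, n),
        a8=rng.uniform(0.0, 180.0, n),
    )


def make_toy_structure(rng, n_receptor_residues=5, atoms_per_residue=4, n_ligand=4, box=8.0):
    """Random parameterised ligand + receptor toy with mild charges."""
    n = n_ligand + n_receptor_residues * atoms_per_residue
    coords = rng.uniform(0.0, box, (n, 3))
    # keep atoms from overlapping (hard lower bound on pair distances)
    for _ in range(200):
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] > 1.5:
            break
        coords[i] += rng.normal(0, 0.8, 3)
    is_lig = np.zeros(n, bool)
    is_lig[:n_ligand] = True
    resid = np.concatenate([np.full(n_ligand, 900), np.repeat(np.arange(n_receptor_residues) + 1, atoms_per_residue)])
    resname = np.array(["STY"] * n_ligand + ["Leu"] * (n - n_ligand), dtype=object)
    return ParameterizedStructure(
        coords=coords,
        charges=rng.normal(0.0, 0.15, n),
        rmin_half=rng.uniform(1.3, 2.0, n),
        epsilon=rng.uniform(0.05, 0.2, n),
        gb_radius=rng.uniform(1.2, 1.8, n),
        resid=resid,
        resname=resname,
        is_ligand=is_lig,
    )


@pytest.fixture
def toy_structure(rng):
    return make_toy_structure(rng)
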