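import numpy as np
import pytest

from ifacepep.gbsa_scoring import AtomParams, ParamSet
from ifacepep.structure_io import AssemblyModel, Atom, Residue


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_complex(n_residues_receptor=2, n_ligand_atoms=4, seed=0, box=8.0):
    """Random small receptor/ligand system with generic parameters.

    Returns (topology, coords, params, receptor_idx, ligand_idx); 4 atoms
    per receptor residue, one ligand residue.
    """
    rng = np.random.default_rng(seed)
    n_rec = 4 * n_residues_receptor
    n = n_rec + n_ligand_atoms
    coords = rng.uniform(0.0, box, size=(n, 3))
    # keep pair distances away from zero so LJ stays finite
    for _ in range(200):
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(d.argmin(), d.shape)
        if d[i, j] >= 1.5:
            break
        coords[j] += (coords[j] - coords[i]) * (1.5 / d[i, j] - 1.0 + 0.1)
    asm = AssemblyModel(model_id=1)
    asm.chains["R"] = [
        Residue("R", i + 1, "", "ALA",
                [Atom(j + 1, f"C{j}", "C", coords[4 * i + j]) for j in range(4)])
        for i in range(n_residues_receptor)
    ]
    asm.chains["P"] = [
        Residue("P", 1, "", "GLY",
                [Atom(j + 1, f"C{j}", "C", coords[n_rec + j])
                 for j in range(n_ligand_atoms)])
    ]
    params = ParamSet([
        AtomParams(
            partial_charge=float(rng.uniform(-0.5, 0.5)),
            lj_rmin_half=1.9,
            lj_epsilon=0.1,
            gb_radius=float(rng.uniform(1.2, 2.0)),
            gb_screen=0.8,
            sasa_radius=1.6,
        )
        for _ in range(n)
    ])
    return asm, coords, params, np.arange(n_rec), np.arange(n_rec, n)
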