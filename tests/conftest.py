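import numpy as np
import pytest

from campsn.interactions import Residue, ResidueTopology


def micro_topology(residue_specs):
    """Build a minimal topology from (chain, resid, name, {atom: (xyz, elem)}).

    Atom order follows dict insertion order; coordinates in Å.
    """
    residues, coords = [], []
    for chain, resid, name, atoms in residue_specs:
        names = tuple(atoms.keys())
        elements = tuple(v[1] for v in atoms.values())
        residues.append(Residue(chain, resid, name, names, elements))
        coords.extend(np.asarray(v[0], dtype=float) for v in atoms.values())
    return ResidueTopology(residues, np.vstack(coords))


def leu_at(chain, resid, com_xyz):
    """A leucine whose single side-chain carbon sits at ``com_xyz``."""
    com = np.asarray(com_xyz, dtype=float)
    return (
        chain, resid, "LEU",
        {
            "CA": (com + [0.0, 0.0, 3.0], "C"),
            "CB": (com, "C"),
        },
    )


@pytest.fixture(scope="session")
def toy_topology():
    from campsn import make_toy_complex

    return make_toy_complex(20, 5, seed=1)


@pytest.fixture(scope="session")
def toy_reference_ca(toy_topology):
    return toy_topology.coordinates[toy_topology.ca_indices]
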