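import numpy as np
import pytest

from mdain.model import StructureFrame
from mdain.synthetic import make_toy_structure

# side-chain atoms (name, element) placed for each residue type in random frames
_SIDECHAINS = {
    "ALA": [],
    "SER": [("OG", "O")],
    "THR": [("OG1", "O"), ("CG2", "C")],
    "ASN": [("CG", "C"), ("OD1", "O"), ("ND2", "N")],
    "ASP": [("CG", "C"), ("OD1", "O"), ("OD2", "O")],
    "LYS": [("CG", "C"), ("CD", "C"), ("CE", "C"), ("NZ", "N")],
    "MET": [("CG", "C"), ("SD", "S"), ("CE", "C")],
}


def random_frame(n_residues: int, rng: np.random.Generator,
                 box_side: float | None = None) -> StructureFrame:
    """A random-geometry frame of template-typed residues.

    Residue centers are scattered in a cube sized for moderate density, and
    each residue's backbone + side-chain atoms sit within ~2.5 A of its
    center, so frames contain a rich mix of contacts and polar hits.
    """
    side = box_side or max(14.0, 3.2 * n_residues ** (1.0 / 3) * 2.4)
    names, elements, resids, resnames, coords = [], [], [], [], []
    types = list(_SIDECHAINS)
    for r in range(1, n_residues + 1):
        rtype = types[rng.integers(len(types))]
        center = rng.uniform(0, side, size=3)
        atoms = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")]
        atoms += _SIDECHAINS[rtype]
        for name, elem in atoms:
            names.append(name)
            elements.append(elem)
            resids.append(r)
            resnames.append(rtype)
            coords.append(center + rng.uniform(-2.5, 2.5, size=3))
    return StructureFrame(
        atom_names=np.array(names, dtype="U8"),
        elements=np.array(elements, dtype="U4"),
        residue_indices=np.array(resids, dtype=int),
        residue_names=np.array(resnames, dtype="U8"),
        chain_ids=np.array(["A"] * len(names), dtype="U4"),
        coordinates=np.array(coords),
    )


@pytest.fixture(scope="session")
def helix12() -> StructureFrame:
    return make_toy_structure(12, "helix")


@pytest.fixture(scope="session")
def extended12() -> StructureFrame:
    return make_toy_structure(12, "extended")
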