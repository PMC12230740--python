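import warnings

import numpy as np
import pytest

from bindsite import _geometry as geom
from bindsite.fixtures import ToySpec, make_toy_complex_set
from bindsite.structure import AtomRecord, ProteinChain, Residue


def make_backbone_chain(phi_psi, chain_id="A", start=1, res_name="ALA"):
    """Chain of backbone-only residues from a (phi, psi) list."""
    backbone = geom.build_backbone(phi_psi)
    residues = []
    serial = 1
    for i, bb in enumerate(backbone):
        atoms = []
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atoms.append(AtomRecord(
                serial=serial, atom_name=name, element=element, alt_loc="",
                comp_id=res_name, chain_id=chain_id, residue_number=start + i,
                insertion_code="", coords=bb[name], occupancy=1.0,
                b_factor=10.0, is_hetero=False))
            serial += 1
        residues.append(Residue(chain_id, start + i, "", res_name, atoms))
    return ProteinChain(chain_id, residues)


def make_atom(serial, coords, element="C", atom_name=None, comp_id="LIG",
              chain_id="X", residue_number=1, occupancy=1.0, is_hetero=True,
              formal_charge=0):
    return AtomRecord(
        serial=serial, atom_name=atom_name or element, element=element,
        alt_loc="", comp_id=comp_id, chain_id=chain_id,
        residue_number=residue_number, insertion_code="",
        coords=np.asarray(coords, dtype=float), occupancy=occupancy,
        b_factor=0.0, is_hetero=is_hetero, formal_charge=formal_charge)


@pytest.fixture(scope="session")
def helix_chain():
    return make_backbone_chain([geom.ALPHA_PHI_PSI] * 14)


@pytest.fixture(scope="session")
def toy_set():
    return make_toy_complex_set(ToySpec(n_structures=2, n_sites=3,
                                        ligands_per_site=2, seed=1))


@pytest.fixture(autouse=True)
def _quiet_biotite_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*pdbx_formal_charge.*")
        warnings.filterwarnings("ignore", message=".*lack full backbone.*")
        yield
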