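import numpy as np
import pytest

from bindsite.chem import classify_ligand_atom, classify_protein_atom, vdw_radius
from bindsite.contacts import (ContactParams, ContactPolicy, classify_distance,
                               binding_residues_per_ligand, detect_contacts)
from bindsite.structure import Assembly, LigandInstance, ProteinChain, Residue

from conftest import make_atom


@pytest.mark.parametrize("d,ri,rj,comp,cutoff,expected", [
    (3.2, 1.7, 1.7, 0.1, 5.0, "clash"),       # 3.2 < 3.4
    (3.45, 1.7, 1.7, 0.1, 5.0, "vdw"),        # 3.4 <= 3.45 < 3.5
    (3.5, 1.7, 1.7, 0.1, 5.0, "proximal"),
    (5.0, 1.7, 1.7, 0.1, 5.0, "proximal"),
    (5.1, 1.7, 1.7, 0.1, 5.0, None),          # beyond cutoff
])
def test_classify_distance(d, ri, rj, comp, cutoff, expected):
    assert classify_distance(d, ri, rj, comp, cutoff) == expected


def test_classify_distance_rejects_negative():
    with pytest.raises(ValueError):
        classify_distance(-0.1, 1.7, 1.7)
    with pytest.raises(ValueError):
        classify_distance(3.0, -1.0, 1.7)


def _protein_residue(coords_by_name, res_name="GLY", number=1, chain="A"):
    atoms = []
    for i, (name, (element, xyz)) in enumerate(coords_by_name.items()):
        atoms.append(make_atom(i + 1, xyz, element, atom_name=name,
                               comp_id=res_name, chain_id=chain,
                               residue_number=number, is_hetero=False))
    return Residue(chain, number, "", res_name, atoms)


def _assembly_with(residues, ligands):
    return Assembly("1", "synth", protein_chains=[ProteinChain("A", residues)],
                    ligands=ligands)


def test_far_apart_atoms_make_no_contact():
    res = _protein_residue({"CA": ("C", [0, 0, 0])})
    lig = LigandInstance("LIG", "X", 9,
                         [make_atom(10, [10, 0, 0], "C", residue_number=9)],
                         structure_id="synth")
    assert detect_contacts(_assembly_with([res], [lig])) == []


def test_hbond_typed_contact():
    # backbone O (acceptor) 3.0 A from ligand N (donor/acceptor)
    res = _protein_residue({"O": ("O", [0, 0, 0])}, res_name="ALA", number=73)
    lig = LigandInstance("ATP", "X", 400,
                         [make_atom(10, [3.0, 0, 0], "N", atom_name="N1",
                                    residue_number=400)],
                         structure_id="synth")
    contacts = detect_contacts(_assembly_with([res], [lig]))
    assert len(contacts) == 1
    c = contacts[0]
    assert "hbond" in c.interaction_types
    assert c.distance == pytest.approx(3.0)
    assert c.protein_atom.residue_number == 73


def test_ionic_contact_on_constructed_carboxylate():
    """Asp carboxylate O at 3.0 A from a +1 ligand nitrogen is ionic."""
    res = _protein_residue({"OD1": ("O", [0, 0, 0])}, res_name="ASP", number=5)
    lig = LigandInstance("LIG", "X", 9,
                         [make_atom(10, [3.0, 0, 0], "N", atom_name="N1",
                                    residue_number=9, formal_charge=1)],
                         structure_id="synth")
    contacts = detect_contacts(_assembly_with([res], [lig]))
    assert len(contacts) == 1
    assert "ionic" in contacts[0].interaction_types
    assert "hbond" in contacts[0].interaction_types  # O acceptor, N donor


def test_polar_band_between_hbond_and_4A():
    res = _protein_residue({"O": ("O", [0, 0, 0])}, res_name="ALA")
    lig = LigandInstance("LIG", "X", 9,
                         [make_atom(10, [3.8, 0, 0], "N", residue_number=9)],
                         structure_id="synth")
    (c,) = detect_contacts(_assembly_with([res], [lig]))
    assert c.interaction_types == {"polar"}


def test_hydrophobic_contact():
    res = _protein_residue({"CB": ("C", [0, 0, 0])}, res_name="LEU")
    lig = LigandInstance("LIG", "X", 9,
                         [make_atom(10, [4.2, 0, 0], "C", residue_number=9)],
                         structure_id="synth")
    (c,) = detect_contacts(_assembly_with([res], [lig]))
    assert c.interaction_types == {"hydrophobic"}


def _random_assembly(rng, n_protein, n_lig_atoms):
    residues = []
    elements = ["C", "N", "O", "S"]
    names = {"C": "CA", "N": "N", "O": "O", "S": "SG"}
    for i in range(n_protein):
        el = elements[rng.integers(len(elements))]
        residues.append(_protein_residue(
            {names[el]: (el, rng.uniform(0, 25, 3))},
            res_name="ALA", number=i + 1))
    lig_atoms = [make_atom(1000 + k, rng.uniform(0, 25, 3),
                           elements[rng.integers(len(elements))],
                           atom_name=f"L{k}", residue_number=900)
                 for k in range(n_lig_atoms)]
    lig = LigandInstance("LIG", "X", 900, lig_atoms, structure_id="synth")
    return _assembly_with(residues, [lig])


def brute_force_contacts(assembly, params=ContactParams()):
    """All-pairs distance scan, no spatial index: the contact oracle."""
    found = set()
    for chain in assembly.protein_chains:
        for res in chain.residues:
            for pa in res.atoms:
                for lig in assembly.ligands:
                    for la in lig.atoms:
                        d = float(np.linalg.norm(pa.coords - la.coords))
                        if d <= params.proximal_cutoff:
                            found.add((res.number, la.atom_name, round(d, 9)))
    return found


def test_detect_contacts_matches_brute_force_scan():
    rng = np.random.default_rng(42)
    for _ in range(25):
        assembly = _random_assembly(rng, n_protein=rng.integers(20, 120),
                                    n_lig_atoms=rng.integers(1, 8))
        got = {(c.protein_atom.residue_number, c.ligand_atom.atom_name,
                round(c.distance, 9))
               for c in detect_contacts(assembly)}
        assert got == brute_force_contacts(assembly)


def test_contact_distance_is_euclidean_norm():
    rng = np.random.default_rng(0)
    assembly = _random_assembly(rng, 50, 4)
    coords = {a.serial: a.coords for c in assembly.protein_chains
              for r in c.residues for a in r.atoms}
    lig_coords = {a.atom_name: a.coords for a in assembly.ligands[0].atoms}
    for c in detect_contacts(assembly):
        pa = assembly.protein_chains[0].residues[c.protein_atom.residue_number - 1]
        d = np.linalg.norm(pa.atoms[0].coords - lig_coords[c.ligand_atom.atom_name])
        assert abs(c.distance - d) < 1e-9


def test_shrinking_cutoff_never_adds_contacts():
    rng = np.random.default_rng(7)
    assembly = _random_assembly(rng, 80, 5)
    wide = detect_contacts(assembly, ContactParams(proximal_cutoff=5.0))
    for cutoff in (4.0, 3.0, 2.0):
        narrow = detect_contacts(assembly, ContactParams(proximal_cutoff=cutoff))
        wide_keys = {(c.protein_atom, c.ligand_atom) for c in wide}
        narrow_keys = {(c.protein_atom, c.ligand_atom) for c in narrow}
        assert narrow_keys <= wide_keys


class TestBindingResidues:
    def _contacts(self, *specs):
        """specs: (resnum, distance, element) tuples against one ligand."""
        residues = [
            _protein_residue({"O": ("O", [0, 0, 10 * i])}, number=num)
            for i, (num, _, _) in enumerate(specs)]
        lig_atoms = [make_atom(100 + i, [d, 0, 10 * i], el, atom_name=f"L{i}",
                               residue_number=900)
                     for i, (_, d, el) in enumerate(specs)]
        lig = LigandInstance("LIG", "X", 900, lig_atoms, structure_id="s")
        return detect_contacts(_assembly_with(residues, [lig]))

    def test_single_hbond_contact_admits_residue(self):
        contacts = self._contacts((73, 3.0, "N"))
        sets = binding_residues_per_ligand(contacts)
        assert list(sets.values()) == [{("A", 73)}]

    def test_untyped_proximal_excluded_by_default(self):
        # carbon 4.8 A from backbone O: proximal, no interaction type
        contacts = self._contacts((50, 4.8, "C"))
        assert contacts and contacts[0].interaction_types == frozenset()
        assert binding_residues_per_ligand(contacts) == {}
        relaxed = ContactPolicy(include_untyped_proximal=True)
        assert binding_residues_per_ligand(contacts, relaxed) != {}

    def test_two_ligands_share_a_residue(self):
        res = _protein_residue({"O": ("O", [0, 0, 0])}, number=50)
        ligs = [LigandInstance("LIG", "X", 900 + i,
                               [make_atom(100 + i, [0, 3.0 * (-1) ** i, 0], "N",
                                          residue_number=900 + i)],
                               structure_id="s") for i in range(2)]
        contacts = detect_contacts(_assembly_with([res], ligs))
        sets = binding_residues_per_ligand(contacts)
        assert len(sets) == 2
        assert all(s == {("A", 50)} for s in sets.values())


def test_chem_typing_rules():
    lys_nz = classify_protein_atom("LYS", "NZ", "N")
    assert lys_nz.is_donor and lys_nz.charge_sign == 1
    asp_od = classify_protein_atom("ASP", "OD1", "O")
    assert asp_od.is_acceptor and asp_od.charge_sign == -1
    bb_o = classify_protein_atom("GLY", "O", "O")
    assert bb_o.is_acceptor and not bb_o.is_donor
    lig_n = classify_ligand_atom("N", formal_charge=1)
    assert lig_n.is_donor and lig_n.is_acceptor and lig_n.charge_sign == 1
    assert classify_ligand_atom("C").is_hydrophobe
    assert vdw_radius("C") == 1.70 and vdw_radius("N") == 1.55
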