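import math

import numpy as np
import pytest

from bindsite import _geometry as geom
from bindsite.accessibility import (MAX_ASA_THEORETICAL, assemble_accessibility,
                                    assign_secondary_structure, compute_asa,
                                    kabsch_sander_hbonds, read_ss_table,
                                    relative_accessibility, residue_asa,
                                    ss_states_from_hbonds)
from bindsite.structure import ProteinChain, Residue

from conftest import make_atom, make_backbone_chain


def quadrature_asa_oracle(coords, radii, probe=1.4, n_points=10_000, seed=0):
    """Independent high-resolution sphere quadrature (random points)."""
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, dtype=float)
    expanded = np.asarray(radii, dtype=float) + probe
    out = []
    for i in range(len(coords)):
        v = rng.normal(size=(n_points, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = coords[i] + expanded[i] * v
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            exposed &= np.linalg.norm(pts - coords[j], axis=1) > expanded[j]
        out.append(exposed.mean() * 4 * math.pi * expanded[i] ** 2)
    return np.array(out)


class TestComputeASA:
    def test_isolated_carbon_analytic_sphere(self):
        atoms = [make_atom(1, [0, 0, 0], "C")]
        asa = compute_asa(atoms)
        analytic = 4 * math.pi * (1.70 + 1.4) ** 2  # 120.76
        assert asa[0] == pytest.approx(analytic, rel=0.01)

    def test_fully_enclosed_atom_zero(self):
        atoms = [make_atom(1, [0, 0, 0], "C")]
        for k, axis in enumerate([(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                  (0, -1, 0), (0, 0, 1), (0, 0, -1)]):
            atoms.append(make_atom(2 + k, np.array(axis) * 1.0, "C"))
        asa = compute_asa(atoms)
        assert asa[0] == pytest.approx(0.0, abs=1e-9)

    def test_two_atom_pair_matches_quadrature_oracle(self):
        atoms = [make_atom(1, [0, 0, 0], "C"), make_atom(2, [1.0, 0, 0], "O")]
        asa = compute_asa(atoms)
        oracle = quadrature_asa_oracle([[0, 0, 0], [1.0, 0, 0]], [1.70, 1.52])
        np.testing.assert_allclose(asa, oracle, rtol=0.01)

    def test_empty_input(self):
        assert compute_asa([]).size == 0

    def test_translation_invariance(self, helix_chain):
        atoms = helix_chain.atoms
        base = compute_asa(atoms)
        shifted = [make_atom(a.serial, a.coords + np.array([128.0, -64.0, 32.0]),
                             a.element, atom_name=a.atom_name, is_hetero=False)
                   for a in atoms]
        np.testing.assert_allclose(compute_asa(shifted), base, atol=1e-3)

    def test_rotation_invariance_within_quadrature_tolerance(self, helix_chain):
        atoms = helix_chain.atoms
        base = compute_asa(atoms).sum()
        rot = geom.rotation_matrix(np.array([1.0, 2.0, 3.0]), 73.0)
        rotated = [make_atom(a.serial, rot @ a.coords, a.element,
                             atom_name=a.atom_name, is_hetero=False)
                   for a in atoms]
        assert compute_asa(rotated).sum() == pytest.approx(base, rel=0.01)

    def test_residue_asa_additivity(self, helix_chain):
        per_res = residue_asa(helix_chain)
        per_atom = compute_asa(helix_chain.atoms)
        i = 0
        for res in helix_chain.residues:
            n = len(res.atoms)
            assert per_res[(res.chain_id, res.number)] \
                == pytest.approx(per_atom[i:i + n].sum(), abs=1e-12)
            i += n


class TestRSA:
    def test_half_exposed_alanine(self):
        assert relative_accessibility(64.5, "ALA") == pytest.approx(50.0)

    def test_zero_asa(self):
        assert relative_accessibility(0.0, "TRP") == 0.0

    def test_unknown_residue_errors_without_fallback(self):
        with pytest.raises(KeyError):
            relative_accessibility(10.0, "XYZ")
        assert relative_accessibility(10.0, "XYZ", fallback_max=200.0) \
            == pytest.approx(5.0)

    def test_cap_policy(self):
        assert relative_accessibility(500.0, "GLY") == 100.0
        assert relative_accessibility(500.0, "GLY", cap_at_100=False) > 100.0

    def test_linearity_in_asa(self):
        slope = 100.0 / MAX_ASA_THEORETICAL["LEU"]
        for asa in (10.0, 50.0, 120.0):
            assert relative_accessibility(asa, "LEU") \
                == pytest.approx(slope * asa)


def antiparallel_pair_chain():
    """Ideal two-strand antiparallel pair: strand dihedrals, 2-fold rotation
    about a sheet-plane axis, 3.8 A inter-strand spacing, half-step register."""
    bb1 = geom.build_backbone([geom.BETA_PHI_PSI] * 6)
    ca = np.array([r["CA"] for r in bb1])
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    center = ca.mean(axis=0)
    tmp = np.array([0.0, 0.0, 1.0])
    perp = tmp - np.dot(tmp, axis) * axis
    perp /= np.linalg.norm(perp)
    rot = geom.rotation_matrix(perp, 180.0)
    bb2 = [{k: rot @ (v - center) + center + 3.8 * perp - 2.5 * axis
            for k, v in r.items()} for r in bb1]
    chain1 = make_backbone_chain([geom.BETA_PHI_PSI] * 6)
    residues = list(chain1.residues)
    serial = 100
    for i, bb in enumerate(bb2):
        atoms = []
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atoms.append(make_atom(serial, bb[name], element, atom_name=name,
                                   chain_id="A", residue_number=101 + i,
                                   comp_id="ALA", is_hetero=False))
            serial += 1
        residues.append(Residue("A", 101 + i, "", "ALA", atoms))
    return ProteinChain("A", residues)


class TestSecondaryStructure:
    def test_ideal_alpha_helix_interior_is_H(self, helix_chain):
        ss = assign_secondary_structure(helix_chain)
        interior = [ss[("A", n)] for n in range(3, 13)]
        assert interior == ["H"] * len(interior)

    def test_two_residue_chain_all_coil(self):
        chain = make_backbone_chain([geom.ALPHA_PHI_PSI] * 2)
        assert set(assign_secondary_structure(chain).values()) == {"C"}

    def test_antiparallel_pair_strands_are_E(self):
        chain = antiparallel_pair_chain()
        ss = assign_secondary_structure(chain)
        strand1 = [ss[("A", n)] for n in (2, 3, 4, 5)]
        strand2 = [ss[("A", n)] for n in (102, 103, 104, 105)]
        assert strand1 == ["E"] * 4
        assert strand2 == ["E"] * 4

    def test_helix_hbond_ladder(self, helix_chain):
        hb, complete = kabsch_sander_hbonds(helix_chain)
        n = len(helix_chain.residues)
        assert complete == list(range(n))
        assert all(hb[i + 4, i] for i in range(n - 4))

    def test_missing_backbone_warns_coil(self):
        chain = make_backbone_chain([geom.ALPHA_PHI_PSI] * 10)
        # strip the carbonyl O from residue 5
        res = chain.residues[4]
        res.atoms = [a for a in res.atoms if a.atom_name != "O"]
        with pytest.warns(UserWarning):
            ss = assign_secondary_structure(chain)
        assert ss[("A", 5)] == "C"

    def test_rotation_invariance_of_ss(self, helix_chain):
        rot = geom.rotation_matrix(np.array([0.2, 1.0, -0.5]), 119.0)
        rotated = ProteinChain("A", [
            Residue("A", r.number, "", r.name,
                    [make_atom(a.serial, rot @ a.coords + 7.0, a.element,
                               atom_name=a.atom_name, chain_id="A",
                               residue_number=r.number, comp_id="ALA",
                               is_hetero=False) for a in r.atoms])
            for r in helix_chain.residues])
        assert assign_secondary_structure(rotated) \
            == assign_secondary_structure(helix_chain)

    def test_isolated_ladder_pattern_gives_bridge(self):
        hb = np.zeros((9, 9), dtype=bool)
        hb[1, 5] = hb[5, 1] = True  # single antiparallel bridge 1<->5... wait |i-j|>=3
        states = ss_states_from_hbonds(hb)
        assert states[1] == "B" and states[5] == "B"


def test_assemble_accessibility_on_toy(toy_set):
    access = assemble_accessibility(toy_set.assemblies[0])
    assert len(access) == 60
    values = [a for a in access.values()]
    assert all(v.ASA >= 0 for v in values)
    assert all(0 <= v.RSA <= 100 for v in values)
    assert all(v.max_asa_used == MAX_ASA_THEORETICAL["ALA"] for v in values)


def test_read_ss_table(tmp_path):
    p = tmp_path / "ss.csv"
    p.write_text("chain_id,resnum,ss_state\nA,1,H\nA,2,E\n")
    assert read_ss_table(p) == {("A", 1): "H", ("A", 2): "E"}
    bad = tmp_path / "bad.csv"
    bad.write_text("chain_id,resnum,ss_state\nA,1,Q\n")
    with pytest.raises(ValueError):
        read_ss_table(bad)
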