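import numpy as np
import pytest

from bindsite.structure import (Assembly, BatchFormatError, LigandInstance,
                                ProteinChain, Residue, default_exclusion_list,
                                filter_relevant_ligands, load_exclusion_list,
                                read_structures, validate_batch,
                                write_assembly_pdb)

from conftest import make_atom, make_backbone_chain
from bindsite import _geometry as geom

MINI_PDB = (
    "ATOM      1  CA  ALA A   1      11.104   6.134   2.100  1.00 10.00           C  \n"
    "END\n"
)


def _mini_assembly(ligands=(), waters=()):
    chain = make_backbone_chain([geom.ALPHA_PHI_PSI] * 5)
    return Assembly("1", "mini", protein_chains=[chain],
                    ligands=list(ligands), waters=list(waters))


class TestReadStructures:
    def test_single_atom_pdb(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINI_PDB)
        (assembly,) = read_structures([p])
        assert len(assembly.protein_chains) == 1
        assert assembly.n_atoms == 1
        assert assembly.ligands == []
        atom = assembly.protein_chains[0].residues[0].atoms[0]
        assert atom.atom_name == "CA" and atom.occupancy == 1.0

    def test_mmcif_ligand_partition_against_reference_parser(self, tmp_path):
        """mmCIF with a polymer chain + HETATM ATP partitions correctly and
        agrees with an independent parser (Bio.PDB) on the same file."""
        import biotite.structure as struc
        from biotite.structure.io import pdbx

        arr = struc.AtomArray(5)
        arr.coord = np.array([[0, 0, 0], [1.5, 0, 0], [2.2, 1.2, 0],
                              [2.9, 1.2, 1.1], [8, 8, 8]], dtype=np.float32)
        arr.chain_id = np.array(["A"] * 4 + ["B"])
        arr.res_id = np.array([1, 1, 1, 1, 400])
        arr.ins_code = np.array([""] * 5)
        arr.res_name = np.array(["GLY"] * 4 + ["ATP"])
        arr.atom_name = np.array(["N", "CA", "C", "O", "PA"])
        arr.element = np.array(["N", "C", "C", "O", "P"])
        arr.hetero = np.array([False] * 4 + [True])
        arr.set_annotation("occupancy", np.ones(5))
        arr.set_annotation("b_factor", np.zeros(5))
        cif = pdbx.CIFFile()
        pdbx.set_structure(cif, arr)
        path = tmp_path / "complex.cif"
        cif.write(str(path))

        (assembly,) = read_structures([path])
        assert [c.chain_id for c in assembly.protein_chains] == ["A"]
        assert [l.comp_id for l in assembly.ligands] == ["ATP"]
        assert assembly.n_atoms == 5

        from Bio.PDB.MMCIFParser import MMCIFParser
        ref = MMCIFParser(QUIET=True).get_structure("x", str(path))
        def key(name, coord):
            return (name, tuple(round(float(x), 3) for x in coord))

        ref_atoms = sorted(key(a.get_name(), a.get_coord())
                           for a in ref.get_atoms())
        ours = sorted(
            key(a.atom_name, a.coords)
            for a in assembly.protein_atoms()
            + [at for l in assembly.ligands for at in l.atoms])
        assert ours == ref_atoms

    def test_mixed_format_batch_rejected(self, tmp_path):
        p1 = tmp_path / "x.pdb"
        p1.write_text(MINI_PDB)
        p2 = tmp_path / "y.cif"
        p2.write_text("data_y\n")
        with pytest.raises(BatchFormatError):
            read_structures([p1, p2])

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structures([tmp_path / "nope.pdb"])

    def test_partition_completeness_roundtrip(self, tmp_path, toy_set):
        """Writing an assembly out and re-reading preserves the partition,
        atom names, coordinates (to PDB precision) and occupancies."""
        assembly = toy_set.assemblies[0]
        path = write_assembly_pdb(assembly, tmp_path / "rt.pdb")
        (again,) = read_structures([path])
        assert again.n_atoms == assembly.n_atoms
        assert len(again.protein_chains) == len(assembly.protein_chains)
        assert len(again.ligands) == len(assembly.ligands)
        orig = assembly.protein_atoms()
        back = again.protein_atoms()
        assert [a.atom_name for a in orig] == [a.atom_name for a in back]
        np.testing.assert_allclose(
            np.array([a.coords for a in orig]),
            np.array([a.coords for a in back]), atol=1.5e-3)
        assert [a.occupancy for a in orig] == [a.occupancy for a in back]


class TestFilterRelevantLigands:
    def _ligand(self, comp_id="ATP", occ=1.0):
        atoms = [make_atom(1, [0, 0, 0], "N", comp_id=comp_id, occupancy=occ),
                 make_atom(2, [1, 0, 0], "O", comp_id=comp_id)]
        return LigandInstance(comp_id, "X", 1, atoms)

    def test_partial_occupancy_dropped(self):
        assert filter_relevant_ligands([self._ligand(occ=0.5)], set()) == []

    def test_water_dropped(self):
        assert filter_relevant_ligands([self._ligand("HOH")], set()) == []

    def test_full_occupancy_retained_and_policy_toggle(self):
        lig = self._ligand()
        assert filter_relevant_ligands([lig], set()) == [lig]
        partial = self._ligand(occ=0.5)
        assert filter_relevant_ligands([partial], set(),
                                       require_full_occupancy=False) == [partial]

    def test_exclusion_list_applied(self):
        gol = self._ligand("GOL")
        assert filter_relevant_ligands([gol], default_exclusion_list()) == []

    def test_idempotent_and_order_preserving(self):
        ligs = [self._ligand("ATP"), self._ligand("HOH"), self._ligand("NAD"),
                self._ligand("GTP", occ=0.5), self._ligand("FAD")]
        once = filter_relevant_ligands(ligs, {"NAD"})
        twice = filter_relevant_ligands(once, {"NAD"})
        assert once == twice
        assert [l.comp_id for l in once] == ["ATP", "FAD"]


class TestValidateBatch:
    def _assembly(self, sid, n_chains):
        chains = [make_backbone_chain([geom.ALPHA_PHI_PSI] * 4,
                                      chain_id=chr(ord("A") + i))
                  for i in range(n_chains)]
        return Assembly("1", sid, protein_chains=chains)

    def test_uniform_monomers_pass(self):
        report = validate_batch([self._assembly(f"s{i}", 1) for i in range(3)])
        assert report.passed
        assert report.uses_structure_numbering

    def test_chain_count_mismatch_lists_ids(self):
        report = validate_batch([self._assembly("mono", 1),
                                 self._assembly("dimer", 2)])
        assert not report.passed
        assert set(report.offenders) == {"mono", "dimer"}

    def test_empty_batch_errors(self):
        with pytest.raises(ValueError):
            validate_batch([])

    def test_reference_accession_recorded(self):
        report = validate_batch([self._assembly("a", 1)], reference_id="P00517")
        assert report.reference_id == "P00517"
        assert not report.uses_structure_numbering


def test_exclusion_list_file_parsing(tmp_path):
    p = tmp_path / "excl.txt"
    p.write_text("# comment\nGOL  # glycerol\n\natp\n")
    assert load_exclusion_list(p) == {"GOL", "ATP"}
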