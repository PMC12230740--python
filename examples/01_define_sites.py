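"""Define binding sites by clustering ligand interfaces on a toy complex set.

Generates a synthetic batch of two structures with three planted ligand
pockets, detects protein-ligand contacts, and clusters the overlapping
interfaces into binding sites.
"""

from bindsite import (ToySpec, binding_residues_per_ligand, define_sites,
                      detect_contacts, make_toy_complex_set)

toy = make_toy_complex_set(ToySpec(n_structures=2, n_sites=3,
                                   ligands_per_site=2, seed=1))

ligand_residue_sets = {}
for assembly in toy.assemblies:
    contacts = detect_contacts(assembly)
    for key, residues in binding_residues_per_ligand(contacts).items():
        ligand_residue_sets[key] = {num for _, num in residues}

sites = define_sites(ligand_residue_sets, tau=0.5)

print(f"{len(ligand_residue_sets)} ligand interfaces -> {len(sites)} binding sites")
for site in sites:
    print(f"  Binding Site {site.site_id}: {site.n_ligands} ligands, "
          f"residues {sorted(site.residues)}")
print("planted truth:", {i: sorted(v) for i, v in toy.site_residues.items()})
# Each site groups the ligands bound at one planted pocket; the residue
# union matches the planted pocket exactly because the fixture has no
# coordinate jitter.
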