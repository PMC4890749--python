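"""Classify response regions as orthosteric or allosteric via the structure.

A response region containing at least one residue within 4 A of any ligand
atom in the bound structure is orthosteric (direct binding-site shielding);
a region with no such residue reports a long-range conformational change.
"""

from hdx_allomap import (
    classify_regions,
    contact_residues,
    difference_profile,
    load_structure,
    make_hsp90_fixture,
    merge_regions,
)

fx = make_hsp90_fixture()

model = load_structure(fx.structure_pdb, fx.ligand_selector)
contacts = contact_residues(model, cutoff_A=4.0)
print(f"{len(contacts.residues)} pocket contact residues (<= 4 A):")
print("  " + ", ".join(str(r) for r in sorted(contacts.residues)))

profile = difference_profile(fx.apo, fx.bound["radicicol"])
regions = merge_regions(profile.significant_peptides)
classified = classify_regions(regions, contacts)
print("\nclassified regions for the radicicol comparison:")
for c in classified:
    support = (f" via contacts {list(c.contact_residues)}"
               if c.contact_residues else "")
    print(f"  {c.region.name:<3} {c.start}-{c.end}: {c.label}{support}")
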