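"""Type residue contacts on a structure and ask what substitutions break.

Builds a toy chain with a planted Asp-Lys salt bridge at 3.0 Å and two
spatial residue clusters, detects and types the contacts, groups the
residues by single-linkage Cα clustering, then applies the class-consensus
substitutions D->N and K->L with the geometry frozen — the qualitative
inference that a charge-neutralising pair of substitutions abolishes a
stabilising salt bridge (the switch-I scenario in fast plant myosins).
"""

import tempfile
from pathlib import Path

from classtrace.structure import (
    SubstitutionEvent,
    find_contacts,
    interaction_diff_report,
    read_structure,
    spatial_clusters,
)
from classtrace.synthetic import ToyStructureSpec, gen_toy_structure

spec = ToyStructureSpec(
    n_residues=8,
    clusters=((1, 2, 3), (6, 7, 8)),
    contact_pairs=((1, 3, "salt_bridge", 3.0),),
    seed=0,
)
pdb_text, truth = gen_toy_structure(spec)
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "toy.pdb"
    path.write_text(pdb_text)
    structure = read_structure(path, chain="A")

print(f"chain {structure.chain_id}: {len(structure.residues)} residues")

contacts = find_contacts(structure)
print("typed contacts (excluding bare proximity):")
for c in contacts:
    if c.interaction_type != "proximity":
        print(
            f"  {c.res1_name}{c.res1[1]} - {c.res2_name}{c.res2[1]}: "
            f"{c.interaction_type} at {c.distance:.2f} Å "
            f"({c.atom_pair[0]}...{c.atom_pair[1]})"
        )

clusters = spatial_clusters([r.number for r in structure.residues], structure)
print("spatial clusters (Cα single linkage, 8 Å):",
      [[n for n, _ in cl] for cl in clusters])

report = interaction_diff_report(
    contacts,
    [SubstitutionEvent(1, "D", "N"), SubstitutionEvent(3, "K", "L")],
)
print("after substituting D1->N and K3->L (geometry frozen):")
for e in report.entries:
    if e.status != "retained":
        print(
            f"  {e.contact.res1_name}{e.contact.res1[1]}-"
            f"{e.contact.res2_name}{e.contact.res2[1]} {e.before_type}: "
            f"{e.status}"
            + (f" -> {', '.join(e.after_types)}" if e.after_types else "")
        )
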