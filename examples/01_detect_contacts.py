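"""Detect typed contacts in a structure and print them.

Builds a small synthetic protein (24 residues on a random walk), parses it
back through the PDB reader, and runs the Cα-pruned contact engine.  Each
output row is one typed atomic contact: the two atoms (chain, residue,
atom name), their separation in Å, and the contact type.
"""

import tempfile
from pathlib import Path

from caprune import detect_contacts, parse_structure, residue_count
from caprune.fixtures import make_random_fixture

workdir = Path(tempfile.mkdtemp())
path = make_random_fixture(n_residues=24, seed=11, out_dir=workdir)

protein = parse_structure(path)
contacts = detect_contacts(protein)

print(f"{protein.id}: {residue_count(protein)} residues, "
      f"{len(contacts)} contacts")
for c in contacts[:8]:
    print(f"  {c.chain_1}:{c.residue_name_1}{c.residue_number_1}:{c.atom_name_1}"
          f" -- {c.chain_2}:{c.residue_name_2}{c.residue_number_2}:{c.atom_name_2}"
          f"  {c.distance:.2f} A  {c.contact_type}")
print(f"  ... ({len(contacts) - 8} more)")

by_type = {}
for c in contacts:
    by_type[c.contact_type] = by_type.get(c.contact_type, 0) + 1
print("contacts by type:", dict(sorted(by_type.items())))
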