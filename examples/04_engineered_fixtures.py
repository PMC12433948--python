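"""Engineered two-residue fixtures, one per contact type.

Each fixture places two idealized residues so a designated atom pair (or
ring-centroid pair) sits at a chosen separation; the brute-force reference
scan then confirms exactly one contact of the requested type at exactly
that distance.  This is the machinery behind the equivalence test battery.
"""

import tempfile
from pathlib import Path

from caprune import all_atoms_contacts, parse_structure
from caprune.fixtures import make_contact_fixture

workdir = Path(tempfile.mkdtemp())
requests = [
    ("hydrogen_bond", 3.0), ("disulfide_bond", 2.05), ("hydrophobic", 4.2),
    ("repulsive", 5.9), ("attractive", 4.5), ("salt_bridge", 3.2),
    ("aromatic_stacking", 3.8),
]
for contact_type, distance in requests:
    path = make_contact_fixture(contact_type, distance, seed=7,
                                out_dir=workdir)
    contacts = all_atoms_contacts(parse_structure(path))
    hits = [c for c in contacts if c.contact_type == contact_type]
    (hit,) = hits
    print(f"{contact_type:18s} requested {distance:4.2f} A -> found "
          f"{hit.atom_name_1}-{hit.atom_name_2} at {hit.distance:.4f} A "
          f"({len(contacts)} contacts total)")
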