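"""Custom contact ranges and the ε matrix extension.

A pair of backbone atoms at 4.2 Å is no hydrogen bond under the default
0–3.9 Å window but becomes one when the range is widened to 4.5 Å; since
4.5 < 6 Å (the default overall maximum) the pruning matrix is unchanged
(ε = 0).  Widening hydrophobic contacts to 7.5 Å pushes the overall maximum
above 6 Å, so every Cα matrix entry grows by ε = 1.5 Å and pruned detection
remains exact, which is verified here against the brute-force scan.
"""

import tempfile
from pathlib import Path

from caprune import (
    CutoffExtension,
    all_atoms_contacts,
    build_conservative_matrix,
    default_rules,
    detect_contacts,
    extend_matrix,
    global_coarse_cutoff,
    max_rule_distance,
    parse_structure,
)
from caprune.fixtures import make_contact_fixture, make_random_fixture

workdir = Path(tempfile.mkdtemp())

# a 4.2 Å N···O pair: invisible by default, a hydrogen bond at max=4.5
protein = parse_structure(
    make_contact_fixture("hydrogen_bond", 4.2, seed=1, out_dir=workdir))
for label, rules in [("default ranges", default_rules()),
                     ("hydrogen_bond max 4.5", default_rules(
                         {"hydrogen_bond": {"max": 4.5}}))]:
    n = sum(c.contact_type == "hydrogen_bond"
            for c in detect_contacts(protein, rules))
    eps = CutoffExtension(user_max_contact=max_rule_distance(rules)).epsilon
    print(f"{label}: {n} hydrogen bond(s), epsilon = {eps:.1f} A")

# hydrophobic contacts out to 7.5 Å need the matrix extension
rules = default_rules({"hydrophobic": {"max": 7.5}})
ext = CutoffExtension(user_max_contact=max_rule_distance(rules))
matrix = extend_matrix(build_conservative_matrix(), ext)
print(f"hydrophobic max 7.5: epsilon = {ext.epsilon:.1f} A, "
      f"coarse cutoff {global_coarse_cutoff(build_conservative_matrix()):.2f}"
      f" -> {global_coarse_cutoff(matrix):.2f} A")

protein = parse_structure(make_random_fixture(30, seed=5, out_dir=workdir))
pruned = {c.key() for c in detect_contacts(protein, rules, matrix)}
brute = {c.key() for c in all_atoms_contacts(protein, rules)}
print(f"pruned vs brute force at custom ranges: "
      f"{len(pruned)} == {len(brute)} contacts, identical: {pruned == brute}")
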