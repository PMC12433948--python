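# caprune

Typed interatomic contact detection in protein structures, with the
residue-pair search pruned by a matrix of maximum Cα–Cα distances.

## What it does

Given a protein structure (PDB or mmCIF), `caprune` finds every pair of
heavy atoms in spatial proximity and classifies each pair into one or more
of seven contact types, driven by an auditable binary taxonomy of atoms
(hydrophobic, aromatic, positive, negative, donor, acceptor):

| contact type      | range (Å)   | condition besides the range              |
|-------------------|-------------|------------------------------------------|
| hydrogen bond     | 0.0 – 3.9   | donor + acceptor                          |
| disulfide bond    | 0.0 – 2.8   | two cysteine SG atoms                     |
| hydrophobic       | 2.0 – 4.5   | two hydrophobic atoms                     |
| repulsive         | 2.0 – 6.0   | equally charged atoms                     |
| attractive        | 3.9 – 6.0   | differently charged atoms                 |
| salt bridge       | 0.0 – 3.9   | opposite charges with donor/acceptor roles|
| aromatic stacking | 2.0 – 5.0   | ring centroids, parallel or perpendicular |

Distances are inclusive Euclidean separations `Da`; aromatic stacking is
evaluated on ring centroids and best-fit plane normals (parallel ≤ 30°,
perpendicular ≥ 60°).

Checking all atom pairs is quadratic in protein size and dominated by pairs
that can never touch. `caprune` prunes at residue level with a symmetric
20×20 matrix `D = [d_ij]` of the largest Cα–Cα separation at which residue
types *i* and *j* can still share an atomic contact (210 non-redundant
entries, `P = n(n−1)/2 + n` with `n = 20`):

1. **coarse tier** — residue pairs farther apart than the largest matrix
   entry are discarded;
2. **pair tier** — survivors farther apart than their own `d_ij` are
   discarded;
3. **atomic tier** — remaining pairs get full atom-by-atom rule evaluation.

Since alpha-carbons move far less than side chains, the bound holds across
folds and conformations, and pruned detection provably returns exactly the
same contacts as a brute-force scan. The default matrix is a conservative
geometric bound (`d_ij = ext_i + ext_j + 6 Å`, with `ext` the fully extended
side-chain reach from Cα); an empirical matrix surveyed from a structure
archive can be supplied as CSV, or rebuilt from any corpus with
`accumulate_max_ca_distances`. Custom contact ranges above the 6 Å default
maximum extend every entry by `ε = user_max − 6 Å`, keeping the pruning
sound.

The parser (built on [gemmi](https://gemmi.readthedocs.io)) keeps only what
contact detection needs: the first model, heavy atoms with occupancy ≥ 0.50,
and standard amino-acid residues — waters, hydrogens, nucleic acids,
ligands, metals and non-standard residues are excluded.

## Worked example

```python
from caprune import detect_contacts, parse_structure, residue_count
from caprune.fixtures import make_random_fixture

path = make_random_fixture(n_residues=24, seed=11, out_dir=".")
protein = parse_structure(path)
contacts = detect_contacts(protein)
print(f"{protein.id}: {residue_count(protein)} residues, {len(contacts)} contacts")
for c in contacts[:3]:
    print(f"  {c.chain_1}:{c.residue_name_1}{c.residue_number_1}:{c.atom_name_1}"
          f" -- {c.chain_2}:{c.residue_name_2}{c.residue_number_2}:{c.atom_name_2}"
          f"  {c.distance:.2f} A  {c.contact_type}")
```

prints

```
random_24_11: 24 residues, 133 contacts
  A:ASN1:O -- A:ARG2:N  3.74 A  hydrogen_bond
  A:ARG2:NE -- A:GLY3:O  3.58 A  hydrogen_bond
  A:ARG2:NH1 -- A:LEU4:O  3.30 A  hydrogen_bond
```

Each row is one typed contact: the two atoms (chain:residue:atom), their
separation, and the contact type. The `examples/` directory holds one short
script per capability (detection, custom ranges and the ε extension, matrix
sources, engineered fixtures, the runtime-model crossover).

## Command line

```sh
caprune structures/*.cif            # summary lines: name,residues,contacts,seconds
caprune entry.pdb -o                # also write entry_contacts.csv
caprune data/ -m 4 -o               # a directory, four worker processes
caprune entry.cif -d ranges.json    # custom per-type min/max distances (Å)
```

The CSV has ten columns in fixed order — Chain 1, Residue Number 1, Residue
Name 1, Atom Name 1, Chain 2, Residue Number 2, Residue Name 2, Atom Name 2,
Distance, Contact Type — with distances at two decimals and rows in a
canonical order that is byte-stable across runs and worker counts.

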