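# Methods

## Contact model

A *contact* is a pair of heavy atoms from two distinct residues whose
Euclidean separation `Da` falls inside an inclusive, type-specific window
and whose physicochemical profiles satisfy the type's condition. Every
heavy atom of the 20 standard amino acids carries six binary flags —
hydrophobic, aromatic, positive, negative, donor, acceptor — shipped as
`src/caprune/data/atom_classification.csv` (187 entries including the
C-terminal OXT) so the taxonomy can be audited or replaced. Flag
conventions: backbone N is a donor and backbone O an acceptor on every
residue; Cα and the carbonyl carbon carry no flags; side-chain carbons of
the apolar residues (Ala, Val, Leu, Ile, Pro, Phe, Trp, Met, Tyr) are
hydrophobic, ring carbons of Phe/Tyr/Trp doubly so (hydrophobic +
aromatic); His ring carbons are aromatic only; Cβ of the polar residues is
counted hydrophobic except where it bonds a heteroatom (Ser, Thr, Cys);
charges sit on Arg NE/NH1/NH2, Lys NZ, His ND1/NE2 (positive) and Asp
OD1/OD2, Glu OE1/OE2 (negative); donors/acceptors follow standard
hydrogen-bonding chemistry, with Ser OG, Thr OG1, Tyr OH and Cys SG both.
Two deliberate conventions: proline's backbone N is listed as a donor like
every other backbone N (the table treats the backbone uniformly, although
proline's amide lacks a hydrogen), and `GLU OD1/OD2` are accepted as
aliases for OE1/OE2 because some published classification tables print the
aspartate-style names for glutamate.

The seven contact types and their default windows are listed in the README.
Two wordings of the salt bridge circulate; we implement the chemically
consistent one — **opposite** charges whose atoms can also pair as
donor/acceptor, at 0–3.9 Å, the close-range complement of the attractive
band (3.9–6.0 Å) — and expose `strict_literal_salt_bridge` for the
alternative reading (equal charges + hydrogen-bonding roles). An atom pair
satisfying several types yields one contact per type; differently charged
pairs closer than 3.9 Å without donor/acceptor capability get no
"attractive" label (that window starts at 3.9 Å by definition).

Aromatic stacking is defined on ring systems, not atoms: the centroid is
the arithmetic mean of the ring atoms and the normal the smallest principal
direction of the ring's coordinates (SVD). Tryptophan uses one descriptor
over the fused 9-atom system by default (`split_trp` gives separate 5- and
6-rings). Rings whose interplanar angle θ = arccos|n₁·n₂| is ≤ 30° count
as parallel and ≥ 60° as perpendicular; the windows are configurable since
no canonical values exist, and boundary comparisons tolerate 1e-9° of
arccos rounding. Stacking rows carry the pseudo atom name `RNG` and the
centroid–centroid distance.

## Search pruning

Contact detection is quadratic in residue count; the engine prunes residue
pairs before atomic evaluation using a symmetric 20×20 matrix of maximum
feasible Cα–Cα separations (210 non-redundant entries). Tiers: (1) discard
pairs beyond the largest entry (the *coarse* cutoff); (2) discard pairs
beyond their type-specific entry; (3) evaluate all atom pairs of survivors,
plus one stacking evaluation per surviving residue pair. Each unordered
residue pair and atom pair is visited once; output is sorted by a canonical
key (chain, residue number, insertion code, atom name, entity 1 smaller),
so reruns are byte-identical.

Matrix sources, all behind one interface:

* **conservative bound** (default): `d_ij = ext_i + ext_j + 6.0`, where
  `ext_r` is the residue's maximum Cα→heavy-atom distance in idealized,
  fully extended geometry. By the triangle inequality, two residues with an
  atom pair within 6 Å can never exceed this Cα separation, so pruning is
  lossless for any structure under the default ranges. The bound brackets
  the published archive-wide extremes: Ala–Gly 10.79 Å ≥ 7.65 Å and
  Arg–Arg 20.63 Å ∈ (20.46, 21.0].
* **empirical CSV**: a user-supplied 210-value survey (tighter and faster;
  sound for structures resembling the surveyed corpus).
* **corpus accumulation**: rebuilt from any corpus with the static-cutoff
  reference engine; each residue-type pair observed in contact stores its
  maximum observed Cα–Cα distance, unobserved pairs keep the conservative
  value (tracked in an `observed` mask). Accumulation is order-independent
  because only maxima are kept.

When a custom range raises the overall maximum contact distance above the
6 Å default, `ε = user_max − 6` is added to **every** entry (a single
extension, derived from the maximum over all configured upper bounds), and
the bound argument goes through unchanged with 6 replaced by `user_max`.

Residues lacking a Cα after filtering (truncated models) are anchored at
their geometric centroid and subject only to the coarse tier, so they are
never pruned incorrectly. Sequence-adjacent residues are evaluated like any
other pair by default — the peptide-bond O(i)···N(i+1) pair registers as a
hydrogen bond — because counting conventions should not silently drop
contacts; `exclude_backbone_neighbors` removes main-chain/main-chain pairs
of residues i, i±1 for users who want that.

## Parsing

Files are read with gemmi (PDB and mmCIF, auto-detected) and reduced to the
first model (configurable), heavy atoms with occupancy ≥ 0.50, and standard
amino acids only; waters, hydrogens, nucleic acids, non-standard residues,
ligands and metal sites are dropped. When several altlocs of one atom pass
the threshold (possible only at exactly 0.50/0.50), the first in file order
is kept — deterministic, and ties above 0.50 are impossible since
occupancies sum to 1. Atoms with zero or negative occupancy (corrupt
records) are rejected with a warning rather than clamped. Author chain
identifiers and author residue numbering (with insertion codes) are used in
all output, falling back to label identifiers when absent; coordinates are
Å throughout. A file yielding no atom records at all is a parse error; a
valid file whose atoms are all filtered (e.g. water-only) parses to an
empty protein.

## Reference oracles

Two independently coded engines back the correctness claims: a brute-force
scan (`all_atoms_contacts`, every atom of every residue against every atom
of every other residue — the ground truth) and a static-cutoff engine
(single fixed Cα cutoff, 21 Å by default, before atomic evaluation). Both
are plain nested loops over the rule predicates and deliberately share no
code with the tiered engine — the pruning path is exactly what the
equivalence tests must not assume. The oracles' ring plane fit uses an
eigendecomposition rather than the engine's SVD.

`solve_crossover` computes, in closed form, the smallest positive n where
one fitted runtime curve `t(n) = a·n² + b·n + c` crosses above another.
With the reference fitted coefficients shipped in `reference_oracles`
(quadratic fits for the pruned and static-cutoff engines, linear for a
k-d-tree neighbor search, from an archive-scale benchmark), the pruned
engine is overtaken by the k-d tree only near 14,000 residues — beyond all
but a fraction of a percent of known protein structures. A bisection oracle
cross-checks the closed form in the tests.

## Synthetic structures

The fixture generator assembles structures from rigid idealized residue
templates built by natural-extension (NeRF) placement with standard bond
lengths/angles and all-trans side-chain torsions, so each template attains
the residue's maximum reach; aromatic rings are exact planar polygons
(indole as a fused pentagon/hexagon sharing the CD2–CE2 edge). The same
templates define the conservative matrix's `ext_r`. Proline's ring is
closed approximately (CD–N 1.47 Å).

Generators: `make_contact_fixture` solves a rigid placement so a designated
atom pair sits at exactly the requested separation (designated atoms land
on 3-decimal coordinates, so the distance survives file rounding to 1e-6;
sub-covalent separations are rejected); `make_decoy_fixture` surrounds a
minimal protein with parser decoys (waters, hydrogens, a 0.49/0.50
occupancy pair, altloc duplicates, a shifted second model, MSE/DA/ZN
hetero-entities, a zero-occupancy record); `make_random_fixture` places
2–50 residues on a random walk with 3.8–8 Å steps, random orientations and
0.05 Å coordinate jitter, giving a realistic mix of touching and distant
pairs. Identical spec + seed gives byte-identical files, and the PDB and
mmCIF renderings of one spec parse identically (both write 3-decimal
coordinates, 2-decimal occupancies).

What the generator does **not** emulate: real backbone connectivity between
consecutive residues (residues are rigid bodies, not a bonded chain),
rotamer statistics, steric relaxation, crystallographic artifacts beyond
the decoys listed, or B-factor structure. Passing the equivalence battery
therefore demonstrates the pruning logic and the parser filters on
physically plausible geometry; it does not validate biological contact
statistics on real structures.

## Problem sizes and numerical choices

The equivalence battery uses 100 random fixtures of 2–50 residues plus one
engineered fixture per contact type — small enough that the brute-force
oracle stays exact and the whole suite runs in well under a minute, while
covering all 20 residue types, all 7 contact types, both file dialects and
every parser filter. Contact-set equality is compared on identity keys with
distances rounded to 1e-9 Å. CSV output prints distances at 2 decimals
(nothing at contact scale is lost); the matrix CSV uses 4 decimals.
Batch processing assigns each input file to one worker process with no
shared mutable state, so output bytes are independent of worker count.

## Known limitations

* Hydrogen bonds are distance + donor/acceptor only — no hydrogen
  placement, no angular criteria.
* Protein–ligand, protein–nucleic-acid and solvent-mediated contacts are
  out of scope, as are assemblies/symmetry expansion and gzipped inputs.
* The conservative matrix is ~30–40% looser than an archive-surveyed
  empirical matrix for most pairs, costing pruning efficiency (never
  correctness); supply an empirical CSV for archive-scale throughput.
* His ring nitrogens are flagged positive (protonated reading) by default;
  users modelling neutral histidine should edit the classification table.
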