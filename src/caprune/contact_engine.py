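"""Typed contact detection with two-tier Cα-distance pruning.

For every unordered residue pair the engine applies:

1. a coarse filter — pairs whose Cα–Cα distance exceeds the largest matrix
   entry are discarded outright;
2. a pair-specific filter — pairs beyond the matrix entry for their residue
   types are discarded;
3. atomic evaluation — every heavy-atom pair of the survivors is tested
   against every distance rule, and aromatic stacking is evaluated once per
   residue pair on ring centroids and plane normals.

Residues lacking an alpha-carbon are anchored at their geometric centroid
and only the coarse tier applies to them, so they are never pruned
incorrectly.  The result is identical to a brute-force scan whenever the
matrix dominates the Cα separations of contacting pairs (always true for
the conservative matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .ca_matrix import CaDistanceMatrix, build_conservative_matrix, \
    global_coarse_cutoff, pair_cutoff
from .chem_rules import AtomClass, ContactRule, UnclassifiedAtomError, \
    classify_atom, default_rules, rule_satisfied
from .geometry import RING_ATOMS
from .structure_io import Protein, Residue

__all__ = [
    "Contact",
    "RingDescriptor",
    "RING_PSEUDO_ATOM",
    "detect_contacts",
    "evaluate_atom_pairs",
    "ring_descriptor",
    "stacking_class",
    "sort_contacts",
]

logger = logging.getLogger("caprune")

#: Pseudo atom-name used in aromatic-stacking output rows.
RING_PSEUDO_ATOM = "RNG"

# TRP split into separate 5- and 6-membered descriptors (optional mode)
_TRP_SPLIT = {
    "TRP5": ("CG", "CD1", "NE1", "CE2", "CD2"),
    "TRP6": ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
}


@dataclass(frozen=True)
class Contact:
    """One detected typed contact between two residues.

    ``atom_name`` is a real heavy-atom name, or ``"RNG"`` with the
    centroid–centroid distance for aromatic stacking.  Entity 1 always sorts
    before entity 2 under (chain, residue number, insertion code, atom name).
    """

    chain_1: str
    residue_number_1: int
    insertion_code_1: str
    residue_name_1: str
    atom_name_1: str
    chain_2: str
    residue_number_2: int
    insertion_code_2: str
    residue_name_2: str
    atom_name_2: str
    distance: float
    contact_type: str

    def key(self) -> tuple:
        """Identity for set comparison; distance rounded to 1e-9 Å."""
        return (
            self.chain_1, self.residue_number_1, self.insertion_code_1,
            self.residue_name_1, self.atom_name_1,
            self.chain_2, self.residue_number_2, self.insertion_code_2,
            self.residue_name_2, self.atom_name_2,
            self.contact_type, round(self.distance, 9),
        )


@dataclass(frozen=True)
class RingDescriptor:
    """Centroid and unit plane-normal of one aromatic ring system."""

    residue_label: str
    atom_names: tuple[str, ...]
    centroid: np.ndarray
    normal: np.ndarray


def _entity_key(res: Residue, atom_name: str) -> tuple:
    return (res.chain_id, res.number, res.insertion_code, atom_name)


def make_contact(res_a: Residue, atom_a: str, res_b: Residue, atom_b: str,
                 distance: float, contact_type: str) -> Contact:
    """Build a contact with canonical entity ordering."""
    if _entity_key(res_b, atom_b) < _entity_key(res_a, atom_a):
        res_a, atom_a, res_b, atom_b = res_b, atom_b, res_a, atom_a
    return Contact(
        chain_1=res_a.chain_id, residue_number_1=res_a.number,
        insertion_code_1=res_a.insertion_code, residue_name_1=res_a.name,
        atom_name_1=atom_a,
        chain_2=res_b.chain_id, residue_number_2=res_b.number,
        insertion_code_2=res_b.insertion_code, residue_name_2=res_b.name,
        atom_name_2=atom_b,
        distance=float(distance), contact_type=contact_type,
    )


def sort_contacts(contacts: list[Contact]) -> list[Contact]:
    return sorted(contacts, key=Contact.key)


def ring_descriptor(res: Residue, *, split_trp: bool = False
                    ) -> list[RingDescriptor]:
    """Ring descriptor(s) for an aromatic residue (PHE, TYR, TRP, HIS).

    The centroid is the arithmetic mean of the ring atoms and the normal the
    unit vector of the best-fit plane (smallest principal direction).  TRP
    yields one descriptor over the fused 9-atom system by default, or the
    separate 5- and 6-rings with ``split_trp``.  Returns ``[]`` when the
    residue is not aromatic or ring atoms are missing.
    """
    if res.name not in RING_ATOMS:
        return []
    if res.name == "TRP" and split_trp:
        wanted = _TRP_SPLIT.values()
    else:
        wanted = [RING_ATOMS[res.name]]
    positions = {a.name: a.position for a in res.atoms}
    out = []
    for names in wanted:
        if any(n not in positions for n in names):
            logger.warning("missing ring atoms in %s; excluded from stacking",
                           res.label)
            continue
        pts = np.array([positions[n] for n in names])
        centroid = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centroid)
        normal = vt[-1] / np.linalg.norm(vt[-1])
        out.append(RingDescriptor(
            residue_label=res.label, atom_names=tuple(names),
            centroid=centroid, normal=normal,
        ))
    return out


def stacking_class(r1: RingDescriptor, r2: RingDescriptor,
                   parallel_max_deg: float = 30.0,
                   perpendicular_min_deg: float = 60.0) -> str:
    """Classify the relative ring orientation.

    The interplanar angle is ``θ = arccos(|n1·n2|) ∈ [0°, 90°]``; rings are
    ``"parallel"`` for θ ≤ 30°, ``"perpendicular"`` for θ ≥ 60°, ``"none"``
    otherwise (thresholds configurable).
    """
    cosang = abs(float(np.dot(r1.normal, r2.normal)))
    theta = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    # inclusive windows, robust to arccos rounding at the boundaries
    if theta <= parallel_max_deg + 1e-9:
        return "parallel"
    if theta >= perpendicular_min_deg - 1e-9:
        return "perpendicular"
    return "none"


class _ResidueView:
    """Cached positions and atom classes for one residue."""

    __slots__ = ("residue", "atom_names", "positions", "classes", "rings")

    def __init__(self, res: Residue, *, split_trp: bool = False):
        self.residue = res
        names, positions, classes = [], [], []
        for atom in res.atoms:
            try:
                cls = classify_atom(res.name, atom.name)
            except UnclassifiedAtomError:
                logger.warning("skipping unclassifiable atom %s:%s",
                               res.label, atom.name)
                continue
            names.append(atom.name)
            positions.append(atom.position)
            classes.append(cls)
        self.atom_names: list[str] = names
        self.positions = (np.array(positions) if positions
                          else np.empty((0, 3)))
        self.classes: list[AtomClass] = classes
        self.rings = ring_descriptor(res, split_trp=split_trp)


def _atomic_contacts(va: _ResidueView, vb: _ResidueView,
                     rules: dict[str, ContactRule],
                     strict_literal_salt_bridge: bool) -> list[Contact]:
    out: list[Contact] = []
    if len(va.atom_names) == 0 or len(vb.atom_names) == 0:
        return out
    atomic_rules = [r for r in rules.values()
                    if r.contact_type != "aromatic_stacking"]
    max_d = max(r.d_max for r in atomic_rules)
    dmat = cdist(va.positions, vb.positions)
    for i, j in zip(*np.nonzero(dmat <= max_d)):
        d = float(dmat[i, j])
        ca, cb = va.classes[i], vb.classes[j]
        for rule in atomic_rules:
            if rule_satisfied(rule, ca, cb, d,
                              strict_literal_salt_bridge=strict_literal_salt_bridge):
                out.append(make_contact(va.residue, va.atom_names[i],
                                        vb.residue, vb.atom_names[j],
                                        d, rule.contact_type))
    return out


def _stacking_contacts(va: _ResidueView, vb: _ResidueView,
                       rules: dict[str, ContactRule]) -> list[Contact]:
    rule = rules.get("aromatic_stacking")
    if rule is None or not va.rings or not vb.rings:
        return []
    out = []
    for ra in va.rings:
        for rb in vb.rings:
            d = float(np.linalg.norm(ra.centroid - rb.centroid))
            if rule.in_range(d) and stacking_class(ra, rb) != "none":
                out.append(make_contact(va.residue, RING_PSEUDO_ATOM,
                                        vb.residue, RING_PSEUDO_ATOM,
                                        d, "aromatic_stacking"))
    return out


def evaluate_atom_pairs(res_a: Residue, res_b: Residue,
                        rules: dict[str, ContactRule] | None = None,
                        *, strict_literal_salt_bridge: bool = False,
                        split_trp: bool = False) -> list[Contact]:
    """All typed contacts between two residues (no pruning): every unordered
    heavy-atom pair against every distance rule, plus ring stacking."""
    if res_a is res_b:
        raise ValueError("contacts are inter-residue; got the same residue")
    if rules is None:
        rules = default_rules()
    va = _ResidueView(res_a, split_trp=split_trp)
    vb = _ResidueView(res_b, split_trp=split_trp)
    contacts = _atomic_contacts(va, vb, rules, strict_literal_salt_bridge)
    contacts += _stacking_contacts(va, vb, rules)
    return sort_contacts(contacts)


def _backbone_adjacent(ra: Residue, rb: Residue) -> bool:
    return (ra.chain_id == rb.chain_id
            and abs(ra.number - rb.number) == 1
            and ra.insertion_code == "" and rb.insertion_code == "")


_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


def detect_contacts(protein: Protein,
                    rules: dict[str, ContactRule] | None = None,
                    matrix: CaDistanceMatrix | None = None,
                    *, strict_literal_salt_bridge: bool = False,
                    split_trp: bool = False,
                    exclude_backbone_neighbors: bool = False) -> list[Contact]:
    """All typed contacts in a protein via two-tier Cα pruning.

    Parameters
    ----------
    protein:
        Parsed and filtered structure.
    rules:
        Contact rules; the matrix must already carry the ε extension when
        any custom range exceeds 6 Å.
    matrix:
        Cα pruning matrix (conservative bound by default).
    exclude_backbone_neighbors:
        Drop main-chain/main-chain contacts of sequence neighbours
        (i, i±1) — e.g. the peptide-bond O(i)···N(i+1) hydrogen bond.
        Default off: neighbours are evaluated like any other pair.

    Returns contacts in canonical order; rerunning is reproducible.
    """
    if rules is None:
        rules = default_rules()
    if matrix is None:
        matrix = build_conservative_matrix()
    residues = list(protein.iter_residues())
    if len(residues) < 2:
        return []
    views = [_ResidueView(r, split_trp=split_trp) for r in residues]
    anchors = np.array([r.anchor for r in residues])
    has_ca = np.array([r.ca is not None for r in residues])
    coarse = global_coarse_cutoff(matrix)
    anchor_d = cdist(anchors, anchors)

    contacts: list[Contact] = []
    n = len(residues)
    for i in range(n):
        for j in range(i + 1, n):
            d = anchor_d[i, j]
            if d > coarse:
                continue  # tier 1: global coarse filter
            if has_ca[i] and has_ca[j]:
                if d > pair_cutoff(matrix, residues[i].name, residues[j].name):
                    continue  # tier 2: pair-specific filter
            # tier 3: atomic evaluation
            found = _atomic_contacts(views[i], views[j], rules,
                                     strict_literal_salt_bridge)
            found += _stacking_contacts(views[i], views[j], rules)
            if exclude_backbone_neighbors and _backbone_adjacent(residues[i],
                                                                 residues[j]):
                found = [
                    c for c in found
                    if not (c.atom_name_1 in _BACKBONE_ATOMS
                            and c.atom_name_2 in _BACKBONE_ATOMS)
                ]
            contacts += found
    return sort_contacts(contacts)
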