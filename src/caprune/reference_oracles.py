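"""Independently coded correctness oracles for the pruned contact engine.

``all_atoms_contacts`` evaluates every unordered heavy-atom pair across
distinct residues against every rule with no pruning whatsoever — the
ground truth.  ``static_cutoff_contacts`` applies a single fixed Cα–Cα
cutoff (21 Å by default) before atomic evaluation.  Both are written as
plain nested loops over the rule predicates, deliberately sharing no code
with the tiered engine, so equivalence tests are meaningful.

``solve_crossover`` finds where one fitted runtime curve first overtakes
another — e.g. the protein size at which a quadratic-cost pruned scan
stops beating a linear-cost k-d-tree neighbor search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chem_rules import ContactRule, UnclassifiedAtomError, classify_atom, \
    default_rules, rule_satisfied
from .contact_engine import Contact, RING_PSEUDO_ATOM, make_contact, \
    sort_contacts
from .geometry import RING_ATOMS
from .structure_io import Protein, Residue

__all__ = [
    "ComplexityModel",
    "PRUNED_RUNTIME_FIT",
    "STATIC_RUNTIME_FIT",
    "KDTREE_RUNTIME_FIT",
    "all_atoms_contacts",
    "static_cutoff_contacts",
    "solve_crossover",
]


@dataclass(frozen=True)
class ComplexityModel:
    """Fitted runtime curve ``t(n) = a·n² + b·n + c`` (seconds, n residues)."""

    a: float
    b: float
    c: float
    label: str = ""

    def __call__(self, n: float) -> float:
        return self.a * n * n + self.b * n + self.c


# Reference fitted runtime curves from an archive-scale benchmark of the
# three engines (quadratic fits for the pruned and static-cutoff scans,
# linear for the k-d-tree neighbor search).
PRUNED_RUNTIME_FIT = ComplexityModel(1.35e-7, 5.04e-4, -6.36e-3, "pruned")
STATIC_RUNTIME_FIT = ComplexityModel(1.20e-7, 1.60e-3, -9.18e-2, "static")
KDTREE_RUNTIME_FIT = ComplexityModel(0.0, 2.37e-3, 7.94e-2, "kdtree")


def _atom_classes(res: Residue) -> list[tuple[str, np.ndarray, object]]:
    out = []
    for atom in res.atoms:
        try:
            cls = classify_atom(res.name, atom.name)
        except UnclassifiedAtomError:
            continue
        out.append((atom.name, atom.position, cls))
    return out


def _ring_geometry(res: Residue) -> tuple[np.ndarray, np.ndarray] | None:
    """Centroid and unit normal of the residue's aromatic ring, via an
    eigendecomposition plane fit (independent of the engine's SVD)."""
    names = RING_ATOMS.get(res.name)
    if names is None:
        return None
    positions = {a.name: a.position for a in res.atoms}
    if any(n not in positions for n in names):
        return None
    pts = np.array([positions[n] for n in names])
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    normal = eigvecs[:, int(np.argmin(eigvals))]
    return centroid, normal / np.linalg.norm(normal)


def _pair_contacts(res_a: Residue, res_b: Residue,
                   rules: dict[str, ContactRule],
                   strict_literal_salt_bridge: bool) -> list[Contact]:
    atomic = [r for r in rules.values() if r.contact_type != "aromatic_stacking"]
    max_d = max(r.d_max for r in atomic)
    out: list[Contact] = []
    for name_a, pos_a, cls_a in _atom_classes(res_a):
        for name_b, pos_b, cls_b in _atom_classes(res_b):
            d = math.dist(pos_a, pos_b)
            if d > max_d:
                continue
            for rule in atomic:
                if rule_satisfied(
                    rule, cls_a, cls_b, d,
                    strict_literal_salt_bridge=strict_literal_salt_bridge,
                ):
                    out.append(make_contact(res_a, name_a, res_b, name_b,
                                            d, rule.contact_type))
    stack_rule = rules.get("aromatic_stacking")
    if stack_rule is not None:
        ga, gb = _ring_geometry(res_a), _ring_geometry(res_b)
        if ga is not None and gb is not None:
            d = math.dist(ga[0], gb[0])
            if stack_rule.in_range(d):
                cosang = abs(float(np.dot(ga[1], gb[1])))
                theta = math.degrees(math.acos(min(1.0, cosang)))
                if theta <= 30.0 or theta >= 60.0:
                    out.append(make_contact(res_a, RING_PSEUDO_ATOM,
                                            res_b, RING_PSEUDO_ATOM,
                                            d, "aromatic_stacking"))
    return out


def all_atoms_contacts(protein: Protein,
                       rules: dict[str, ContactRule] | None = None,
                       *, strict_literal_salt_bridge: bool = False
                       ) -> list[Contact]:
    """Brute-force ground truth: every atom of every residue against every
    atom of every other residue, no pruning."""
    if rules is None:
        rules = default_rules()
    residues = list(protein.iter_residues())
    out: list[Contact] = []
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            out += _pair_contacts(residues[i], residues[j], rules,
                                  strict_literal_salt_bridge)
    return sort_contacts(out)


def static_cutoff_contacts(protein: Protein,
                           rules: dict[str, ContactRule] | None = None,
                           cutoff: float = 21.0,
                           *, strict_literal_salt_bridge: bool = False
                           ) -> list[Contact]:
    """Single fixed Cα–Cα cutoff (centroid for CA-less residues) before
    atomic evaluation.  At 21 Å this misses nothing under default ranges."""
    if rules is None:
        rules = default_rules()
    residues = list(protein.iter_residues())
    anchors = [r.anchor for r in residues]
    out: list[Contact] = []
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            if math.dist(anchors[i], anchors[j]) > cutoff:
                continue
            out += _pair_contacts(residues[i], residues[j], rules,
                                  strict_literal_salt_bridge)
    return sort_contacts(out)


def solve_crossover(f: ComplexityModel, h: ComplexityModel
                    ) -> float | None:
    """Smallest positive n where ``f(n) = h(n)`` with f exceeding h beyond
    it; ``None`` when f never overtakes h (or the models are identical)."""
    da, db, dc = f.a - h.a, f.b - h.b, f.c - h.c
    if da == 0.0 and db == 0.0:
        return None  # parallel or identical: never a crossing-up
    if da == 0.0:
        root = -dc / db
        return root if root > 0 and db > 0 else None
    disc = db * db - 4.0 * da * dc
    if disc < 0:
        return None
    sq = math.sqrt(disc)
    roots = sorted(((-db - sq) / (2 * da), (-db + sq) / (2 * da)))
    for root in roots:
        if root > 0 and 2 * da * root + db > 0:  # diff increasing: crossing up
            return root
    return None
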