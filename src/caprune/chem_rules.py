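"""Physicochemical atom taxonomy and contact-type rules.

Every heavy atom of the 20 standard amino acids carries six binary flags
(hydrophobic, aromatic, positive, negative, donor, acceptor).  Seven contact
types are defined over pairs of classified atoms, each with an inclusive
Euclidean-distance range in Å and a predicate on the two atoms' flags:

=================  =============  =============================================
contact type       range (Å)      condition besides the range
=================  =============  =============================================
hydrogen_bond      0.0 -- 3.9     donor + acceptor (either direction)
disulfide_bond     0.0 -- 2.8     both atoms are cysteine SG
hydrophobic        2.0 -- 4.5     both hydrophobic
repulsive          2.0 -- 6.0     equally charged
attractive         3.9 -- 6.0     differently charged
salt_bridge        0.0 -- 3.9     differently charged + donor/acceptor pairing
aromatic_stacking  2.0 -- 5.0     ring centroids, parallel or perpendicular
=================  =============  =============================================

The full classification table ships as ``data/atom_classification.csv`` so it
can be audited or overridden.  The salt-bridge condition is implemented as a
close-range ionic contact (opposite charges with hydrogen-bonding roles); a
``strict_literal`` mode is available that instead requires equal charges, for
users who want the alternative published wording verbatim.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .geometry import STANDARD_RESIDUES

__all__ = [
    "AtomClass",
    "ContactRule",
    "UnclassifiedAtomError",
    "CONTACT_TYPES",
    "default_rules",
    "classify_atom",
    "atom_table",
    "rule_satisfied",
    "max_rule_distance",
]

CONTACT_TYPES = (
    "hydrogen_bond",
    "disulfide_bond",
    "hydrophobic",
    "repulsive",
    "attractive",
    "salt_bridge",
    "aromatic_stacking",
)


class UnclassifiedAtomError(KeyError):
    """Raised for a (residue, atom) pair absent from the classification table."""


@dataclass(frozen=True)
class AtomClass:
    """Binary physicochemical profile of one heavy atom."""

    residue_name: str
    atom_name: str
    hydrophobic: bool = False
    aromatic: bool = False
    positive: bool = False
    negative: bool = False
    donor: bool = False
    acceptor: bool = False

    @property
    def charged(self) -> bool:
        return self.positive or self.negative

    @property
    def is_cys_sg(self) -> bool:
        return self.residue_name == "CYS" and self.atom_name == "SG"


@dataclass(frozen=True)
class ContactRule:
    """One contact type: an inclusive distance window plus a predicate id."""

    contact_type: str
    d_min: float
    d_max: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.d_min <= self.d_max:
            raise ValueError(
                f"invalid range for {self.contact_type}: "
                f"[{self.d_min}, {self.d_max}]"
            )
        if self.contact_type not in CONTACT_TYPES:
            raise ValueError(f"unknown contact type: {self.contact_type!r}")

    def in_range(self, distance: float) -> bool:
        return self.d_min <= distance <= self.d_max


_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "hydrogen_bond": (0.0, 3.9),
    "disulfide_bond": (0.0, 2.8),
    "hydrophobic": (2.0, 4.5),
    "repulsive": (2.0, 6.0),
    "attractive": (3.9, 6.0),
    "salt_bridge": (0.0, 3.9),
    "aromatic_stacking": (2.0, 5.0),
}


def default_rules(
    overrides: dict[str, dict[str, float]] | None = None,
) -> dict[str, ContactRule]:
    """The seven default rules, optionally with per-type ``min``/``max``
    overrides (the custom-distance configuration)."""
    rules = {}
    for ctype, (lo, hi) in _DEFAULT_RANGES.items():
        if overrides and ctype in overrides:
            ov = overrides[ctype]
            extra = set(ov) - {"min", "max"}
            if extra:
                raise ValueError(
                    f"unknown keys {sorted(extra)} for contact type {ctype!r}"
                )
            lo = float(ov.get("min", lo))
            hi = float(ov.get("max", hi))
        rules[ctype] = ContactRule(ctype, lo, hi)
    if overrides:
        unknown = set(overrides) - set(_DEFAULT_RANGES)
        if unknown:
            raise ValueError(f"unknown contact types in overrides: {sorted(unknown)}")
    return rules


def max_rule_distance(rules: dict[str, ContactRule]) -> float:
    """Largest upper bound over all rules; drives the ε matrix extension."""
    return max(r.d_max for r in rules.values())


# GLU side-chain oxygens are OE1/OE2 in PDB nomenclature; OD1/OD2 aliases are
# accepted because some classification tables print them for glutamate.
_ALIASES = {("GLU", "OD1"): "OE1", ("GLU", "OD2"): "OE2"}

_FLAG_NAMES = ("hydrophobic", "aromatic", "positive", "negative", "donor", "acceptor")


def _load_table() -> dict[tuple[str, str], AtomClass]:
    table: dict[tuple[str, str], AtomClass] = {}
    source = resources.files("caprune.data").joinpath("atom_classification.csv")
    with source.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            key = (row["residue"], row["atom"])
            table[key] = AtomClass(
                residue_name=row["residue"],
                atom_name=row["atom"],
                **{f: bool(int(row[f])) for f in _FLAG_NAMES},
            )
    return table


_TABLE: dict[tuple[str, str], AtomClass] | None = None


def atom_table() -> dict[tuple[str, str], AtomClass]:
    """The full (residue, atom) -> AtomClass classification table."""
    global _TABLE
    if _TABLE is None:
        _TABLE = _load_table()
    return _TABLE


def classify_atom(residue_name: str, atom_name: str) -> AtomClass:
    """Look up the six flags for one heavy atom.

    Raises :class:`UnclassifiedAtomError` for residues outside the 20
    standard amino acids or atom names not in the table; callers decide
    whether to skip the atom or abort.
    """
    residue_name = residue_name.upper()
    atom_name = atom_name.upper()
    if residue_name not in STANDARD_RESIDUES:
        raise UnclassifiedAtomError(
            f"unclassified atom: {residue_name} is not a standard amino acid"
        )
    atom_name = _ALIASES.get((residue_name, atom_name), atom_name)
    try:
        return atom_table()[(residue_name, atom_name)]
    except KeyError:
        raise UnclassifiedAtomError(
            f"unclassified atom: {residue_name}:{atom_name}"
        ) from None


def rule_satisfied(
    rule: ContactRule,
    a: AtomClass,
    b: AtomClass,
    distance: float,
    *,
    strict_literal_salt_bridge: bool = False,
) -> bool:
    """True iff ``distance`` lies in the rule's inclusive window and the two
    atoms satisfy the rule's physicochemical condition.

    ``aromatic_stacking`` always returns False here: it is defined on ring
    centroids and orientations, not on atom pairs (see the contact engine).
    """
    if not rule.in_range(distance):
        return False
    t = rule.contact_type
    if t == "hydrogen_bond":
        return (a.donor and b.acceptor) or (a.acceptor and b.donor)
    if t == "disulfide_bond":
        return a.is_cys_sg and b.is_cys_sg
    if t == "hydrophobic":
        return a.hydrophobic and b.hydrophobic
    if t == "repulsive":
        return (a.positive and b.positive) or (a.negative and b.negative)
    if t == "attractive":
        return (a.positive and b.negative) or (a.negative and b.positive)
    if t == "salt_bridge":
        hbond_roles = (a.donor and b.acceptor) or (a.acceptor and b.donor)
        if strict_literal_salt_bridge:
            equal = (a.positive and b.positive) or (a.negative and b.negative)
            return equal and hbond_roles
        opposite = (a.positive and b.negative) or (a.negative and b.positive)
        return opposite and hbond_roles
    return False
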