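"""Residue-pair-specific maximum Cα–Cα distances for search pruning.

The engine prunes residue pairs whose alpha-carbons are farther apart than
any pair of their atoms could bridge at contact range.  The bound is a
symmetric 20×20 matrix ``D = [d_ij]`` over the standard amino acids, with
``P = n(n-1)/2 + n = 210`` non-redundant entries for ``n = 20``.

Three interchangeable sources ship behind one interface:

``conservative_bound`` (default)
    ``d_ij = ext_i + ext_j + 6.0`` where ``ext_r`` is the residue's maximum
    Cα-to-heavy-atom reach in idealized fully extended geometry.  By the
    triangle inequality no atomic contact within 6 Å can be missed.
``empirical_supplementary``
    A user-supplied 210-value CSV of maxima surveyed over a structure
    archive (tighter, hence faster, but only sound for structures resembling
    the survey).
``corpus_accumulated``
    Rebuilt from any corpus of parsed proteins with the static-cutoff
    reference engine; unobserved pairs keep the conservative bound.

When user-defined contact ranges exceed the 6 Å default maximum, an epsilon
``ε = user_max − 6.0`` is added to every entry so pruning stays sound.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .geometry import STANDARD_RESIDUES, max_ca_extent
from .structure_io import Protein

__all__ = [
    "CaDistanceMatrix",
    "CutoffExtension",
    "DEFAULT_MAX_CONTACT",
    "pair_cutoff",
    "global_coarse_cutoff",
    "extend_matrix",
    "build_conservative_matrix",
    "accumulate_max_ca_distances",
    "nonredundant_pair_count",
]

#: Largest default contact-range upper bound (Å), over all seven rules.
DEFAULT_MAX_CONTACT = 6.0

_INDEX = {res: i for i, res in enumerate(STANDARD_RESIDUES)}


def nonredundant_pair_count(n: int = 20) -> int:
    """Number of unique residue-type pairs, ``P = n(n-1)/2 + n``."""
    return n * (n - 1) // 2 + n


@dataclass(frozen=True)
class CutoffExtension:
    """ε rule for user contact ranges above the 6 Å default maximum."""

    user_max_contact: float
    default_max_contact: float = DEFAULT_MAX_CONTACT

    def __post_init__(self) -> None:
        if self.user_max_contact < 0:
            raise ValueError("user-defined cutoff must be non-negative")

    @property
    def epsilon(self) -> float:
        return max(0.0, self.user_max_contact - self.default_max_contact)


@dataclass
class CaDistanceMatrix:
    """Symmetric 20×20 matrix of maximum Cα–Cα distances (Å)."""

    entries: np.ndarray
    provenance: str = "conservative_bound"
    #: per-entry flag: True where the value came from an observation rather
    #: than the conservative fallback (corpus accumulation only)
    observed: np.ndarray | None = None
    epsilon_applied: float = 0.0

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.shape != (self.n, self.n):
            raise ValueError(f"matrix must be {self.n}x{self.n}")
        if not np.allclose(self.entries, self.entries.T):
            raise ValueError("matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(STANDARD_RESIDUES)

    @property
    def pair_count(self) -> int:
        return nonredundant_pair_count(self.n)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return pair_cutoff(self, *pair)

    # -- serialization ----------------------------------------------------

    def to_csv(self, destination: str | Path | io.TextIOBase) -> None:
        """Write as plain CSV: header row/column of 3-letter codes in
        alphabetical order, symmetric entries."""
        lines = ["," + ",".join(STANDARD_RESIDUES)]
        for i, res in enumerate(STANDARD_RESIDUES):
            lines.append(res + "," + ",".join(f"{v:.4f}" for v in self.entries[i]))
        text = "\n".join(lines) + "\n"
        if isinstance(destination, (str, Path)):
            Path(destination).write_text(text)
        else:
            destination.write(text)

    @classmethod
    def from_csv(cls, source: str | Path | io.TextIOBase,
                 provenance: str = "empirical_supplementary") -> "CaDistanceMatrix":
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
        else:
            text = source.read()
        rows = [line.split(",") for line in text.strip().splitlines()]
        header = [h.strip().upper() for h in rows[0][1:]]
        if tuple(header) != STANDARD_RESIDUES:
            raise ValueError(
                "matrix CSV must have the 20 standard residues, alphabetical, "
                "as header"
            )
        entries = np.zeros((20, 20))
        for row in rows[1:]:
            res = row[0].strip().upper()
            entries[_INDEX[res]] = [float(v) for v in row[1:]]
        entries = np.maximum(entries, entries.T)  # symmetrize defensively
        return cls(entries=entries, provenance=provenance)


def pair_cutoff(m: CaDistanceMatrix, res_a: str, res_b: str) -> float:
    """Matrix entry d_ij for a residue-type pair (order-independent)."""
    try:
        i, j = _INDEX[res_a.upper()], _INDEX[res_b.upper()]
    except KeyError as exc:
        raise ValueError(f"not a standard amino acid: {exc.args[0]!r}") from None
    return float(m.entries[i, j])


def global_coarse_cutoff(m: CaDistanceMatrix) -> float:
    """Largest entry: the first-tier filter that discards residue pairs no
    residue-type combination could bridge."""
    return float(m.entries.max())


def extend_matrix(m: CaDistanceMatrix, ext: CutoffExtension) -> CaDistanceMatrix:
    """Add ε to every entry when ε > 0; otherwise return the matrix unchanged
    (a copy).  Symmetry and provenance are preserved."""
    eps = ext.epsilon
    return CaDistanceMatrix(
        entries=m.entries + eps,
        provenance=m.provenance,
        observed=None if m.observed is None else m.observed.copy(),
        epsilon_applied=m.epsilon_applied + eps,
    )


def build_conservative_matrix() -> CaDistanceMatrix:
    """``d_ij = ext_i + ext_j + 6.0`` from idealized extended side-chain
    reach; sound for any structure under the default contact ranges."""
    ext = np.array([max_ca_extent(res) for res in STANDARD_RESIDUES])
    entries = ext[:, None] + ext[None, :] + DEFAULT_MAX_CONTACT
    return CaDistanceMatrix(entries=entries, provenance="conservative_bound")


def accumulate_max_ca_distances(
    corpus: Iterable[Protein] | Sequence[Protein],
    static_cutoff: float = 21.0,
    rules=None,
) -> CaDistanceMatrix:
    """Rebuild the matrix from a corpus: for every residue-type pair that
    shares at least one contact (found with the static-cutoff reference
    engine), store the maximum observed Cα–Cα distance; unobserved pairs
    keep the conservative bound."""
    from .chem_rules import default_rules
    from .reference_oracles import static_cutoff_contacts

    if rules is None:
        rules = default_rules()
    observed_max = np.full((20, 20), np.nan)
    for protein in corpus:
        residues = {
            (r.chain_id, r.number, r.insertion_code): r
            for r in protein.iter_residues()
        }
        for contact in static_cutoff_contacts(protein, rules, cutoff=static_cutoff):
            ra = residues[(contact.chain_1, contact.residue_number_1,
                           contact.insertion_code_1)]
            rb = residues[(contact.chain_2, contact.residue_number_2,
                           contact.insertion_code_2)]
            if ra.ca is None or rb.ca is None:
                continue
            d = float(np.linalg.norm(ra.ca.position - rb.ca.position))
            i, j = _INDEX[ra.name], _INDEX[rb.name]
            current = observed_max[i, j]
            if np.isnan(current) or d > current:
                observed_max[i, j] = observed_max[j, i] = d
    conservative = build_conservative_matrix()
    mask = ~np.isnan(observed_max)
    entries = np.where(mask, observed_max, conservative.entries)
    return CaDistanceMatrix(
        entries=entries, provenance="corpus_accumulated", observed=mask,
    )
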