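"""PDB/mmCIF parsing into a uniform Protein/Chain/Residue/Atom model.

Files are read with :mod:`gemmi` (both dialects, auto-detected) and reduced
to exactly what contact detection needs:

* only the requested model (the first, by default — relevant for NMR entries),
* only heavy atoms with occupancy ≥ 0.50 (one altloc per atom name),
* only residues of the 20 standard amino acids — waters, hydrogens,
  nucleic acids, non-standard residues, ligands and metal/coordination
  entities are dropped.

Author chain identifiers and author residue numbering (with insertion codes)
are used throughout, falling back to label identifiers when authors' are
absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .geometry import STANDARD_RESIDUES

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Protein",
    "ParseError",
    "OCCUPANCY_THRESHOLD",
    "parse_structure",
    "residue_count",
]

logger = logging.getLogger("caprune")

#: Minimum occupancy for an atom to be retained.
OCCUPANCY_THRESHOLD = 0.50


class ParseError(ValueError):
    """Unreadable or structurally invalid input file."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""


@dataclass
class Residue:
    name: str
    number: int
    insertion_code: str
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def ca(self) -> Atom | None:
        """The alpha-carbon, or None when it did not survive filtering."""
        for atom in self.atoms:
            if atom.name == "CA" and atom.element != "CA":  # not calcium
                return atom
        return None

    @property
    def centroid(self) -> np.ndarray:
        """Geometric mean of the retained atoms (pruning fallback for
        residues without a CA)."""
        return np.mean([a.position for a in self.atoms], axis=0)

    @property
    def anchor(self) -> np.ndarray:
        """CA position when present, else the centroid."""
        ca = self.ca
        return ca.position if ca is not None else self.centroid

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.name}{self.number}{self.insertion_code}"


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Protein:
    id: str
    chains: list[Chain] = field(default_factory=list)
    model_used: int = 1

    def iter_residues(self):
        for chain in self.chains:
            yield from chain.residues


def residue_count(protein: Protein) -> int:
    """Total residues surviving the parser filters, over all chains."""
    return sum(len(chain.residues) for chain in protein.chains)


def _filter_altlocs(raw_atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: the first in file order whose
    occupancy passes the threshold."""
    kept: list[Atom] = []
    seen: set[str] = set()
    for atom in raw_atoms:
        if atom.name in seen:
            continue
        kept.append(atom)
        seen.add(atom.name)
    return kept


def parse_structure(path: str | Path, model_index: int = 1,
                    occupancy_threshold: float = OCCUPANCY_THRESHOLD
                    ) -> Protein:
    """Parse a ``.pdb`` or ``.cif`` file into a filtered :class:`Protein`.

    Parameters
    ----------
    path:
        Input file; the dialect is auto-detected.
    model_index:
        1-based model to keep (1 = first model).  Other models are ignored;
        an absent model is an error.
    occupancy_threshold:
        Minimum occupancy for an atom to be retained (0.50 by default).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path.name}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path.name}: no models found")
    if not 1 <= model_index <= len(st):
        raise ParseError(
            f"{path.name}: model {model_index} not present "
            f"(file has {len(st)} model(s))"
        )
    model = st[model_index - 1]
    if sum(len(res) for chain in model for res in chain) == 0:
        raise ParseError(f"{path.name}: no atom records found")

    protein = Protein(id=st.name.strip() or path.stem, model_used=model_index)
    for gchain in model:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            resname = gres.name.upper()
            if resname not in STANDARD_RESIDUES:
                continue  # waters, nucleic acids, ligands, metals, modified
            raw: list[Atom] = []
            for gatom in gres:
                if gatom.element.is_hydrogen:
                    continue
                occ = float(gatom.occ)
                if occ <= 0.0:
                    logger.warning(
                        "%s: rejecting %s %s/%s with non-positive occupancy %.2f",
                        path.name, chain.id, gres.name, gatom.name, occ,
                    )
                    continue
                if occ < occupancy_threshold:
                    continue
                raw.append(Atom(
                    name=gatom.name,
                    element=gatom.element.name.upper(),
                    position=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    occupancy=occ,
                    altloc=(gatom.altloc or "").strip(),
                ))
            if not raw:
                continue
            icode = gres.seqid.icode.strip() if gres.seqid.icode else ""
            residue = Residue(
                name=resname,
                number=gres.seqid.num,
                insertion_code=icode,
                chain_id=chain.id,
                atoms=_filter_altlocs(raw),
            )
            chain.residues.append(residue)
        if chain.residues:
            protein.chains.append(chain)
    return protein
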