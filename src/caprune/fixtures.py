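"""Deterministic synthetic protein structures for testing and examples.

Small structures are assembled from the idealized rigid residue templates in
:mod:`caprune.geometry` and written as minimal PDB or mmCIF files.  Given the
same specification and seed the emitted files are byte-identical, and the
two dialects of one specification parse to identical proteins (coordinates
are rounded to 3 decimals in both).

Three generators cover the test surface:

* :func:`make_contact_fixture` — a two-residue structure engineered so a
  designated atom (or ring-centroid) pair sits at a requested separation;
* :func:`make_decoy_fixture` — a minimal protein surrounded by parser
  decoys (waters, hydrogens, low-occupancy atoms, altlocs, extra models,
  non-standard residues, metals);
* :func:`make_random_fixture` — a random-walk arrangement of residues that
  exercises the pruning tiers on physically plausible geometry.

This is not a general protein builder: there are no rotamers and no clash
relaxation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import RING_ATOMS, STANDARD_RESIDUES, residue_template

__all__ = [
    "FixtureSpec",
    "SyntheticStructure",
    "DECOY_KINDS",
    "make_contact_fixture",
    "make_decoy_fixture",
    "make_random_fixture",
]

DECOY_KINDS = frozenset({
    "waters", "hydrogens", "low_occupancy", "altlocs", "extra_model",
    "nonstandard", "metal", "corrupt_occupancy",
})

_COVALENT_RADII = {"C": 0.77, "N": 0.75, "O": 0.73, "S": 1.02}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a decoy fixture: base residues plus requested decoys."""

    seed: int = 0
    recipe: tuple[tuple[str, str], ...] = (("A", "ALA"), ("A", "GLY"))
    perturbation_scale: float = 0.0
    dialect: str = "pdb"
    decoys: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = self.decoys - DECOY_KINDS
        if unknown:
            raise ValueError(f"unknown decoys: {sorted(unknown)}")
        if self.dialect not in ("pdb", "cif"):
            raise ValueError(f"dialect must be 'pdb' or 'cif': {self.dialect!r}")


@dataclass
class _AtomRecord:
    model: int
    chain: str
    resname: str
    resnum: int
    icode: str
    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    het: bool = False


def _element_of(atom_name: str) -> str:
    return atom_name.strip()[0]


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _align_rotation(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Rotation taking unit vector v onto unit vector w."""
    v = v / np.linalg.norm(v)
    w = w / np.linalg.norm(w)
    c = float(np.dot(v, w))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # 180 degrees about any axis perpendicular to v
        helper = np.array([1.0, 0.0, 0.0])
        if abs(v[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(v, helper)
        return _rotation_matrix(axis, math.pi)
    axis = np.cross(v, w)
    return _rotation_matrix(axis, math.acos(max(-1.0, min(1.0, c))))


class SyntheticStructure:
    """Accumulates atom records and renders them as PDB or mmCIF text."""

    def __init__(self, name: str = "synthetic"):
        self.name = name
        self.records: list[_AtomRecord] = []

    # -- construction -----------------------------------------------------

    def add_atom(self, chain: str, resname: str, resnum: int, name: str,
                 pos, *, model: int = 1, icode: str = "", element: str = "",
                 occupancy: float = 1.0, altloc: str = "",
                 het: bool = False) -> None:
        self.records.append(_AtomRecord(
            model=model, chain=chain, resname=resname, resnum=resnum,
            icode=icode, name=name, element=element or _element_of(name),
            pos=np.asarray(pos, dtype=float), occupancy=occupancy,
            altloc=altloc, het=het,
        ))

    def add_residue(self, chain: str, resname: str, resnum: int,
                    rotation: np.ndarray | None = None,
                    translation=(0.0, 0.0, 0.0), *, model: int = 1,
                    jitter: np.ndarray | None = None,
                    occupancy: float = 1.0) -> None:
        """Place a rigid idealized residue: ``x -> R x + t`` per atom."""
        rot = np.eye(3) if rotation is None else rotation
        t = np.asarray(translation, dtype=float)
        template = residue_template(resname)
        for k, (name, pos) in enumerate(template.items()):
            xyz = rot @ pos + t
            if jitter is not None:
                xyz = xyz + jitter[k % len(jitter)]
            self.add_atom(chain, resname, resnum, name, xyz,
                          model=model, occupancy=occupancy)

    def add_water(self, resnum: int, pos, *, chain: str = "W",
                  model: int = 1) -> None:
        self.add_atom(chain, "HOH", resnum, "O", pos, model=model, het=True)

    # -- rendering --------------------------------------------------------

    def _models(self) -> list[int]:
        return sorted({r.model for r in self.records})

    def _ordered(self, model: int) -> list[_AtomRecord]:
        """Records of one model grouped by residue (stable within a residue,
        so altloc file order is preserved)."""
        recs = [r for r in self.records if r.model == model]
        return sorted(recs, key=lambda r: (r.chain, r.resnum, r.icode))

    def to_pdb(self) -> str:
        lines: list[str] = []
        models = self._models()
        multi = len(models) > 1
        for model in models:
            if multi:
                lines.append(f"MODEL     {model:4d}")
            serial = 0
            for r in self._ordered(model):
                serial += 1
                record = "HETATM" if r.het else "ATOM  "
                name = r.name if len(r.name) >= 4 else f" {r.name:<3s}"
                lines.append(
                    f"{record}{serial:5d} {name:4s}{r.altloc or ' ':1s}"
                    f"{r.resname:>3s} {r.chain[:1]:1s}{r.resnum:4d}"
                    f"{r.icode or ' ':1s}   "
                    f"{r.pos[0]:8.3f}{r.pos[1]:8.3f}{r.pos[2]:8.3f}"
                    f"{r.occupancy:6.2f}{0.0:6.2f}          "
                    f"{r.element:>2s}"
                )
            if multi:
                lines.append("ENDMDL")
        lines.append("END")
        return "\n".join(lines) + "\n"

    def to_cif(self) -> str:
        lines = [
            f"data_{self.name}",
            "loop_",
            "_atom_site.group_PDB",
            "_atom_site.id",
            "_atom_site.type_symbol",
            "_atom_site.label_atom_id",
            "_atom_site.label_alt_id",
            "_atom_site.label_comp_id",
            "_atom_site.label_asym_id",
            "_atom_site.label_seq_id",
            "_atom_site.pdbx_PDB_ins_code",
            "_atom_site.Cartn_x",
            "_atom_site.Cartn_y",
            "_atom_site.Cartn_z",
            "_atom_site.occupancy",
            "_atom_site.B_iso_or_equiv",
            "_atom_site.auth_seq_id",
            "_atom_site.auth_comp_id",
            "_atom_site.auth_asym_id",
            "_atom_site.auth_atom_id",
            "_atom_site.pdbx_PDB_model_num",
        ]
        serial = 0
        for model in self._models():
            for r in self._ordered(model):
                serial += 1
                group = "HETATM" if r.het else "ATOM"
                lines.append(" ".join([
                    group, str(serial), r.element, r.name, r.altloc or ".",
                    r.resname, r.chain, str(r.resnum), r.icode or "?",
                    f"{r.pos[0]:.3f}", f"{r.pos[1]:.3f}", f"{r.pos[2]:.3f}",
                    f"{r.occupancy:.2f}", "0.00",
                    str(r.resnum), r.resname, r.chain, r.name, str(model),
                ]))
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        text = self.to_cif() if path.suffix == ".cif" else self.to_pdb()
        path.write_text(text)
        return path


# -- targeted contact fixtures -------------------------------------------

#: Residue/atom pairs engineered per contact type so the designated pair is
#: the closest approach between the two residues.
#: (res_a, atom_a, orient_ref_a, res_b, atom_b, orient_ref_b); the residue is
#: oriented along designated_atom - orient_ref (centroid when None), which
#: lets sibling atoms (e.g. the second carboxylate oxygen) be pushed directly
#: behind the designated one, out of contact range.
_CONTACT_RECIPES: dict[str, tuple[str, str, str | None, str, str, str | None]] = {
    "hydrogen_bond": ("ALA", "N", None, "ALA", "O", None),
    "disulfide_bond": ("CYS", "SG", None, "CYS", "SG", None),
    "hydrophobic": ("ALA", "CB", None, "ALA", "CB", None),
    "repulsive": ("LYS", "NZ", None, "LYS", "NZ", None),
    "attractive": ("LYS", "NZ", None, "GLU", "OE1", "OE2"),
    "salt_bridge": ("LYS", "NZ", None, "GLU", "OE1", "OE2"),
}


def _ring_frame(resname: str) -> tuple[np.ndarray, np.ndarray]:
    """Ring centroid and unit normal of a template aromatic residue."""
    template = residue_template(resname)
    pts = np.array([template[n] for n in RING_ATOMS[resname]])
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[-1] / np.linalg.norm(vt[-1])


def make_contact_fixture(contact_type: str, distance: float, seed: int = 0,
                         out_dir: str | Path = ".",
                         dialect: str = "pdb") -> Path:
    """Write a two-residue structure whose designated atom pair (or ring
    centroid pair, for stacking) sits at exactly ``distance`` Å.

    The second residue faces the first through the designated atoms, so the
    requested pair is the closest approach and the only contact of the
    requested type when the distance is in range.
    """
    rng = np.random.default_rng(seed)
    st = SyntheticStructure(name=f"{contact_type}_{seed}")
    path = Path(out_dir) / f"{contact_type}_{distance:.2f}_{seed}.{dialect}"

    if contact_type == "aromatic_stacking":
        if distance <= 0:
            raise ValueError("centroid separation must be positive")
        res = "PHE"
        centroid, normal = _ring_frame(res)
        st.add_residue("A", res, 1)
        # parallel-stacked copy: same orientation, offset along the normal
        spin = _rotation_matrix(normal, rng.uniform(0, 2 * math.pi))
        offset = centroid + distance * normal
        # rotate about the ring normal through the centroid, then translate
        translation = offset - spin @ centroid
        st.add_residue("B", res, 1, rotation=spin, translation=translation)
        return st.write(path)

    try:
        res_a, atom_a, ref_a, res_b, atom_b, ref_b = _CONTACT_RECIPES[contact_type]
    except KeyError:
        raise ValueError(f"unknown contact type: {contact_type!r}") from None
    r_min = _COVALENT_RADII[atom_a[0]] + _COVALENT_RADII[atom_b[0]]
    if distance < r_min:
        raise ValueError(
            f"unreachable geometry: {distance} Å is below the covalent "
            f"contact limit {r_min:.2f} Å for {atom_a}-{atom_b}"
        )

    tmpl_a = residue_template(res_a)
    tmpl_b = residue_template(res_b)
    centroid_a = np.mean(list(tmpl_a.values()), axis=0)
    centroid_b = np.mean(list(tmpl_b.values()), axis=0)
    x_hat = np.array([1.0, 0.0, 0.0])
    # rotate A so its designated atom's outward direction lies along +x and
    # translate the designated atom onto the origin; with the partner atom
    # placed at (distance, 0, 0) both designated atoms have coordinates that
    # survive the file's 3-decimal rounding exactly
    u = tmpl_a[atom_a] - (tmpl_a[ref_a] if ref_a else centroid_a)
    if np.linalg.norm(u) < 1e-9:
        u = x_hat.copy()
    rot_a = _align_rotation(u, x_hat)
    st.add_residue("A", res_a, 1, rotation=rot_a,
                   translation=-rot_a @ tmpl_a[atom_a])
    # orient B so its designated atom faces back along -x
    v = tmpl_b[atom_b] - (tmpl_b[ref_b] if ref_b else centroid_b)
    if np.linalg.norm(v) < 1e-9:
        v = x_hat.copy()
    rot_b = _rotation_matrix(x_hat, rng.uniform(0, 2 * math.pi)) \
        @ _align_rotation(v, -x_hat)
    target = np.array([distance, 0.0, 0.0])
    st.add_residue("B", res_b, 1, rotation=rot_b,
                   translation=target - rot_b @ tmpl_b[atom_b])
    return st.write(path)


# -- decoy fixtures -------------------------------------------------------

def build_decoy_structure(spec: FixtureSpec) -> SyntheticStructure:
    """The in-memory structure behind :func:`make_decoy_fixture`."""
    rng = np.random.default_rng(spec.seed)
    st = SyntheticStructure(name=f"decoy_{spec.seed}")
    resnum_by_chain: dict[str, int] = {}
    placements: list[tuple[str, str, int, np.ndarray]] = []
    offset = np.zeros(3)
    for chain, resname in spec.recipe:
        resnum = resnum_by_chain.get(chain, 0) + 1
        resnum_by_chain[chain] = resnum
        jitter = None
        if spec.perturbation_scale > 0:
            jitter = rng.normal(0.0, spec.perturbation_scale, size=(32, 3))
        st.add_residue(chain, resname, resnum, translation=offset,
                       jitter=jitter)
        placements.append((chain, resname, resnum, offset.copy()))
        offset = offset + np.array([3.8, 0.5, 0.0])

    last_chain, _, last_num, last_offset = placements[-1]
    decoys = spec.decoys
    if "waters" in decoys:
        for k in range(3):
            st.add_water(900 + k, last_offset + np.array([0.0, 6.0 + k, 0.0]))
    if "hydrogens" in decoys:
        for chain, resname, resnum, off in placements:
            st.add_atom(chain, resname, resnum, "H",
                        off + np.array([-0.8, -0.6, 0.0]), element="H")
            st.add_atom(chain, resname, resnum, "HA",
                        off + np.array([0.3, -0.9, 0.5]), element="H")
    if "low_occupancy" in decoys:
        chain, resname, resnum, off = placements[0]
        # threshold pair: 0.50 is retained, 0.49 is not
        st.add_atom(chain, resname, resnum, "OXT",
                    off + np.array([2.2, -1.1, 0.0]), occupancy=0.50)
        st.add_atom(last_chain, placements[-1][1], last_num, "OXT",
                    last_offset + np.array([2.2, -1.1, 0.0]), occupancy=0.49)
    if "altlocs" in decoys:
        chain, resname, resnum, off = placements[0]
        st.add_atom(chain, resname, resnum, "OXT",
                    off + np.array([2.0, 1.0, 0.0]), occupancy=0.5,
                    altloc="A", element="O")
        st.add_atom(chain, resname, resnum, "OXT",
                    off + np.array([2.0, 1.2, 0.0]), occupancy=0.5,
                    altloc="B", element="O")
    if "corrupt_occupancy" in decoys:
        chain, resname, resnum, off = placements[0]
        st.add_atom(chain, resname, resnum, "OXT",
                    off + np.array([-2.0, 1.0, 0.0]), occupancy=0.0,
                    element="O")
    if "nonstandard" in decoys:
        st.add_atom("N", "MSE", 1, "SE", last_offset + np.array([0, -7, 0]),
                    element="SE", het=True)
        for name, dx in (("P", 0.0), ("O5'", 1.2), ("C5'", 2.2), ("N9", 3.1)):
            st.add_atom("N", "DA", 2, name,
                        last_offset + np.array([dx, -9.0, 0.0]),
                        element=name[0], het=True)
    if "metal" in decoys:
        st.add_atom("M", "ZN", 1, "ZN", last_offset + np.array([0, 8, 0]),
                    element="ZN", het=True)
    if "extra_model" in decoys:
        shift = np.array([10.0, 0.0, 0.0])
        for chain, resname, resnum, off in placements:
            st.add_residue(chain, resname, resnum, translation=off + shift,
                           model=2)
    return st


def make_decoy_fixture(spec: FixtureSpec, out_dir: str | Path = ".") -> Path:
    """Write a minimal protein plus the requested parser decoys."""
    st = build_decoy_structure(spec)
    path = Path(out_dir) / f"decoy_{spec.seed}_{'-'.join(sorted(spec.decoys)) or 'clean'}.{spec.dialect}"
    return st.write(path)


# -- randomized fixtures ---------------------------------------------------

def make_random_fixture(n_residues: int, seed: int,
                        out_dir: str | Path = ".", dialect: str = "pdb",
                        perturbation_scale: float = 0.05,
                        step_range: tuple[float, float] = (3.8, 8.0)) -> Path:
    """Write a random-walk fixture of ``n_residues`` rigidly placed
    idealized residues (over one or two chains) with random orientations.

    Step lengths between consecutive anchor points span contact range, so
    fixtures contain a realistic mix of touching and distant residue pairs.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    rng = np.random.default_rng(seed)
    st = SyntheticStructure(name=f"random_{seed}")
    n_chains = 1 if n_residues < 4 else int(rng.integers(1, 3))
    split = n_residues if n_chains == 1 else int(rng.integers(1, n_residues))
    pos = np.zeros(3)
    resnum = 0
    for k in range(n_residues):
        chain = "A" if k < split else "B"
        resnum = resnum + 1 if k != split else 1
        resname = str(rng.choice(STANDARD_RESIDUES))
        axis = rng.normal(size=3)
        rot = _rotation_matrix(axis, rng.uniform(0, 2 * math.pi))
        jitter = None
        if perturbation_scale > 0:
            jitter = rng.normal(0.0, perturbation_scale, size=(32, 3))
        st.add_residue(chain, resname, resnum, rotation=rot, translation=pos,
                       jitter=jitter)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = pos + direction * rng.uniform(*step_range)
    path = Path(out_dir) / f"random_{n_residues}_{seed}.{dialect}"
    return st.write(path)
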