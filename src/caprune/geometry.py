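"""Idealized heavy-atom geometry for the 20 standard amino acids.

Each residue template is a rigid set of heavy-atom coordinates (Å) built from
standard bond lengths and angles with fully extended (all-trans) side-chain
dihedrals, so the Cα-to-atom reach of every template is the maximum the
residue can attain.  Aromatic ring systems are constructed as exact planar
polygons and rigidly attached to the Cβ–Cγ bond.

Templates serve two purposes:

* the synthetic-structure generator places rigid copies of them, and
* the conservative Cα-distance matrix bounds each residue's side-chain reach
  by ``max_ca_extent``.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

__all__ = [
    "STANDARD_RESIDUES",
    "RING_ATOMS",
    "residue_template",
    "max_ca_extent",
]

#: The 20 standard amino acids, alphabetical by 3-letter code.  This ordering
#: is the canonical row/column order of the Cα distance matrix.
STANDARD_RESIDUES: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: Aromatic ring atoms per residue (TRP as one fused 9-atom system).
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}

# Bond lengths (Å): single/partial-double bonds between heavy atoms.
_CC = 1.52      # sp3 C-C
_CC_AR = 1.39   # aromatic C-C
_CN = 1.47      # C-N single
_CN_AM = 1.33   # amide / guanidinium C-N
_CO = 1.43      # C-O single
_CO_D = 1.23    # C=O
_CO_X = 1.25    # carboxylate C-O
_CS = 1.81      # C-S


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom D bonded to C.

    ``angle`` is the B-C-D valence angle and ``dihedral`` the A-B-C-D torsion,
    both in degrees.
    """
    ang = math.radians(angle)
    tor = math.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _regular_polygon(n: int, side: float) -> list[np.ndarray]:
    """2D vertices of a regular n-gon with the first vertex at the origin and
    the centroid on the +x axis."""
    radius = side / (2.0 * math.sin(math.pi / n))
    center = np.array([radius, 0.0])
    out = []
    for k in range(n):
        theta = math.pi - k * 2.0 * math.pi / n
        out.append(center + radius * np.array([math.cos(theta), math.sin(theta)]))
    return out


def _indole_2d() -> dict[str, np.ndarray]:
    """Planar 2D coordinates for the fused tryptophan ring system, CG at the
    origin.  Pentagon CG-CD1-NE1-CE2-CD2 fused with the benzo ring on the
    CD2-CE2 edge."""
    pent = _regular_polygon(5, 1.37)
    coords = {
        "CG": pent[0], "CD1": pent[1], "NE1": pent[2],
        "CE2": pent[3], "CD2": pent[4],
    }
    cd2, ce2 = coords["CD2"], coords["CE2"]
    mid = 0.5 * (cd2 + ce2)
    edge = ce2 - cd2
    side = float(np.linalg.norm(edge))
    # outward normal of the fusion edge (away from the pentagon centroid)
    perp = np.array([edge[1], -edge[0]]) / side
    pent_center = np.mean(pent, axis=0)
    if np.dot(perp, mid - pent_center) < 0:
        perp = -perp
    center = mid + perp * (side * math.sqrt(3.0) / 2.0)
    ang_cd2 = math.atan2(*(cd2 - center)[::-1])
    ang_ce2 = math.atan2(*(ce2 - center)[::-1])
    # walk CD2 -> CE3 -> CZ3 -> CH2 -> CZ2 -> CE2 the long way around
    step = math.pi / 3.0
    if math.isclose((ang_cd2 + step) % (2 * math.pi), ang_ce2 % (2 * math.pi),
                    abs_tol=1e-9):
        step = -step
    for i, name in enumerate(("CE3", "CZ3", "CH2", "CZ2"), start=1):
        theta = ang_cd2 + step * i
        coords[name] = center + side * np.array([math.cos(theta), math.sin(theta)])
    return coords


def _hexagon_2d(with_oh: bool = False) -> dict[str, np.ndarray]:
    hexa = _regular_polygon(6, _CC_AR)
    coords = {
        "CG": hexa[0], "CD1": hexa[1], "CE1": hexa[2],
        "CZ": hexa[3], "CE2": hexa[4], "CD2": hexa[5],
    }
    if with_oh:
        coords["OH"] = coords["CZ"] + np.array([1.37, 0.0])
    return coords


def _pentagon_his_2d() -> dict[str, np.ndarray]:
    pent = _regular_polygon(5, 1.37)
    # ring order CG-ND1-CE1-NE2-CD2
    return {"CG": pent[0], "ND1": pent[1], "CE1": pent[2],
            "NE2": pent[3], "CD2": pent[4]}


# Side-chain recipes: atom -> (ref_a, ref_b, parent, bond, angle, dihedral).
# All-trans (180 deg) torsions extend the chain to maximum reach.
_CHAINS: dict[str, list[tuple[str, str, str, str, float, float, float]]] = {
    "ALA": [],
    "ARG": [
        ("CG", "N", "CA", "CB", _CC, 114.0, 180.0),
        ("CD", "CA", "CB", "CG", _CC, 111.5, 180.0),
        ("NE", "CB", "CG", "CD", 1.46, 112.0, 180.0),
        ("CZ", "CG", "CD", "NE", _CN_AM, 124.0, 180.0),
        ("NH1", "CD", "NE", "CZ", _CN_AM, 120.0, 0.0),
        ("NH2", "CD", "NE", "CZ", _CN_AM, 120.0, 180.0),
    ],
    "ASN": [
        ("CG", "N", "CA", "CB", _CC, 112.5, 180.0),
        ("OD1", "CA", "CB", "CG", _CO_D, 120.5, 0.0),
        ("ND2", "CA", "CB", "CG", _CN_AM, 116.5, 180.0),
    ],
    "ASP": [
        ("CG", "N", "CA", "CB", _CC, 112.5, 180.0),
        ("OD1", "CA", "CB", "CG", _CO_X, 118.5, 0.0),
        ("OD2", "CA", "CB", "CG", _CO_X, 118.5, 180.0),
    ],
    "CYS": [("SG", "N", "CA", "CB", _CS, 114.0, 180.0)],
    "GLN": [
        ("CG", "N", "CA", "CB", _CC, 114.0, 180.0),
        ("CD", "CA", "CB", "CG", _CC, 112.5, 180.0),
        ("OE1", "CB", "CG", "CD", _CO_D, 120.5, 0.0),
        ("NE2", "CB", "CG", "CD", _CN_AM, 116.5, 180.0),
    ],
    "GLU": [
        ("CG", "N", "CA", "CB", _CC, 114.0, 180.0),
        ("CD", "CA", "CB", "CG", _CC, 112.5, 180.0),
        ("OE1", "CB", "CG", "CD", _CO_X, 118.5, 0.0),
        ("OE2", "CB", "CG", "CD", _CO_X, 118.5, 180.0),
    ],
    "GLY": [],
    "ILE": [
        ("CG1", "N", "CA", "CB", 1.53, 110.5, 180.0),
        ("CG2", "N", "CA", "CB", 1.53, 110.5, -60.0),
        ("CD1", "CA", "CB", "CG1", 1.53, 113.0, 180.0),
    ],
    "LEU": [
        ("CG", "N", "CA", "CB", 1.53, 116.5, 180.0),
        ("CD1", "CA", "CB", "CG", 1.53, 110.5, 180.0),
        ("CD2", "CA", "CB", "CG", 1.53, 110.5, -60.0),
    ],
    "LYS": [
        ("CG", "N", "CA", "CB", _CC, 114.0, 180.0),
        ("CD", "CA", "CB", "CG", _CC, 111.5, 180.0),
        ("CE", "CB", "CG", "CD", _CC, 111.5, 180.0),
        ("NZ", "CG", "CD", "CE", 1.49, 112.0, 180.0),
    ],
    "MET": [
        ("CG", "N", "CA", "CB", _CC, 114.0, 180.0),
        ("SD", "CA", "CB", "CG", _CS, 112.5, 180.0),
        ("CE", "CB", "CG", "SD", 1.79, 100.5, 180.0),
    ],
    "PRO": [
        ("CG", "N", "CA", "CB", 1.50, 104.5, -20.0),
        ("CD", "CA", "CB", "CG", 1.51, 105.5, 10.0),
    ],
    "SER": [("OG", "N", "CA", "CB", 1.42, 111.0, 180.0)],
    "THR": [
        ("OG1", "N", "CA", "CB", 1.43, 109.5, 180.0),
        ("CG2", "N", "CA", "CB", 1.53, 110.5, -60.0),
    ],
    "VAL": [
        ("CG1", "N", "CA", "CB", 1.53, 110.5, 180.0),
        ("CG2", "N", "CA", "CB", 1.53, 110.5, -60.0),
    ],
}

_RINGS_2D: dict[str, dict[str, np.ndarray]] = {
    "PHE": _hexagon_2d(),
    "TYR": _hexagon_2d(with_oh=True),
    "HIS": _pentagon_his_2d(),
    "TRP": _indole_2d(),
}


def _backbone() -> dict[str, np.ndarray]:
    """N, CA, C, O with CA at the origin."""
    ca = np.zeros(3)
    n = np.array([1.458, 0.0, 0.0])
    # C at 1.525 from CA, N-CA-C angle 111 deg, in the z=0 plane
    ang = math.radians(111.0)
    c = np.array([1.525 * math.cos(ang), 1.525 * math.sin(ang), 0.0])
    o = _place(n, ca, c, _CO_D, 120.5, 0.0)
    return {"N": n, "CA": ca, "C": c, "O": o}


def _attach_ring(coords: dict[str, np.ndarray], resname: str) -> None:
    """Place CG, then rigidly attach the planar ring in the frame defined by
    the CB->CG direction and the CA-CB-CG plane."""
    cg = _place(coords["N"], coords["CA"], coords["CB"], 1.51, 114.0, 180.0)
    x_hat = cg - coords["CB"]
    x_hat /= np.linalg.norm(x_hat)
    ref = coords["CA"] - coords["CB"]
    z_hat = np.cross(x_hat, ref)
    z_hat /= np.linalg.norm(z_hat)
    y_hat = np.cross(z_hat, x_hat)
    for name, uv in _RINGS_2D[resname].items():
        coords[name] = cg + uv[0] * x_hat + uv[1] * y_hat


@lru_cache(maxsize=None)
def _template(resname: str) -> tuple[tuple[str, tuple[float, float, float]], ...]:
    if resname not in STANDARD_RESIDUES:
        raise ValueError(f"not a standard amino acid: {resname!r}")
    coords = _backbone()
    if resname != "GLY":
        coords["CB"] = _place(coords["C"], coords["N"], coords["CA"],
                              1.53, 110.5, -122.0)
    if resname in _RINGS_2D:
        _attach_ring(coords, resname)
    else:
        for name, a, b, c, bond, angle, dihedral in _CHAINS[resname]:
            coords[name] = _place(coords[a], coords[b], coords[c],
                                  bond, angle, dihedral)
    return tuple((name, tuple(float(x) for x in xyz))
                 for name, xyz in coords.items())


def residue_template(resname: str) -> dict[str, np.ndarray]:
    """Heavy-atom coordinates (Å) of an idealized, fully extended residue,
    with CA at the origin.  Returns a fresh dict of name -> 3-vector."""
    return {name: np.array(xyz) for name, xyz in _template(resname)}


@lru_cache(maxsize=None)
def max_ca_extent(resname: str) -> float:
    """Maximum distance (Å) from CA to any heavy atom of the idealized,
    fully extended residue.  Used by the conservative Cα-matrix bound."""
    tmpl = residue_template(resname)
    ca = tmpl["CA"]
    return max(float(np.linalg.norm(p - ca)) for p in tmpl.values())
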