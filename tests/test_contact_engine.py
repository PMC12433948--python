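"""Tiered contact detection, ring geometry, and stacking classification."""

import math

import numpy as np
import pytest

from caprune.chem_rules import default_rules
from caprune.contact_engine import (
    RING_PSEUDO_ATOM,
    RingDescriptor,
    detect_contacts,
    evaluate_atom_pairs,
    ring_descriptor,
    stacking_class,
)
from caprune.fixtures import SyntheticStructure, make_contact_fixture, \
    make_random_fixture
from caprune.reference_oracles import all_atoms_contacts
from caprune.structure_io import Atom, Protein, Residue, parse_structure
from conftest import contact_keys


def _residue(name, atom_positions, chain="A", number=1):
    atoms = [Atom(name=n, element=n[0], position=np.asarray(p, dtype=float))
             for n, p in atom_positions]
    return Residue(name=name, number=number, insertion_code="",
                   chain_id=chain, atoms=atoms)


def _hexagon_ring(center=(0.0, 0.0, 0.0), radius=1.4, pucker=0.0):
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    pts = []
    for k, n in enumerate(names):
        ang = 2 * math.pi * k / 6
        z = pucker * (-1) ** k
        pts.append((n, (center[0] + radius * math.cos(ang),
                        center[1] + radius * math.sin(ang),
                        center[2] + z)))
    return pts


def test_ring_centroid_and_normal_of_a_flat_hexagon():
    res = _residue("PHE", _hexagon_ring())
    (ring,) = ring_descriptor(res)
    assert np.allclose(ring.centroid, [0, 0, 0], atol=1e-12)
    assert abs(ring.normal[2]) == pytest.approx(1.0)
    # translation equivariance
    res2 = _residue("PHE", _hexagon_ring(center=(10.0, 0.0, 0.0)))
    (ring2,) = ring_descriptor(res2)
    assert np.allclose(ring2.centroid, [10, 0, 0], atol=1e-12)
    assert np.allclose(np.abs(ring2.normal), np.abs(ring.normal), atol=1e-12)


def test_puckered_ring_normal_matches_plane_fit_oracle():
    res = _residue("PHE", _hexagon_ring(pucker=0.07))
    (ring,) = ring_descriptor(res)
    # independent oracle: smallest-variance direction by eigendecomposition
    pts = np.array([a.position for a in res.atoms])
    centered = pts - pts.mean(axis=0)
    w, v = np.linalg.eigh(centered.T @ centered)
    oracle = v[:, np.argmin(w)]
    cross = np.linalg.norm(np.cross(ring.normal, oracle))
    assert cross < 1e-6  # parallel up to sign


def test_incomplete_rings_are_excluded_from_stacking():
    res = _residue("PHE", _hexagon_ring()[:-1])  # CD2 missing
    assert ring_descriptor(res) == []
    assert ring_descriptor(_residue("ALA", [("CB", (0, 0, 0))])) == []


def test_trp_fused_ring_descriptor_modes(tmp_path):
    st = SyntheticStructure()
    st.add_residue("A", "TRP", 1)
    protein = parse_structure(st.write(tmp_path / "trp.pdb"))
    trp = next(protein.iter_residues())
    fused = ring_descriptor(trp)
    assert len(fused) == 1 and len(fused[0].atom_names) == 9
    split = ring_descriptor(trp, split_trp=True)
    assert sorted(len(r.atom_names) for r in split) == [5, 6]


def _descriptor(normal):
    n = np.asarray(normal, dtype=float)
    return RingDescriptor(residue_label="x", atom_names=(),
                          centroid=np.zeros(3), normal=n / np.linalg.norm(n))


@pytest.mark.parametrize("theta,expected", [
    (0.0, "parallel"), (20.0, "parallel"), (30.0, "parallel"),
    (45.0, "none"), (60.0, "perpendicular"), (90.0, "perpendicular"),
])
def test_stacking_orientation_windows(theta, expected):
    r1 = _descriptor([0, 0, 1])
    rad = math.radians(theta)
    r2 = _descriptor([math.sin(rad), 0, math.cos(rad)])
    assert stacking_class(r1, r2) == expected
    assert stacking_class(r2, r1) == expected  # symmetry
    # an anti-parallel normal is the same plane
    r3 = _descriptor([-math.sin(rad), 0, -math.cos(rad)])
    assert stacking_class(r1, r3) == expected


def test_atom_pair_evaluation_examples(tmp_path):
    disulfide = parse_structure(
        make_contact_fixture("disulfide_bond", 2.05, 7, tmp_path))
    a, b = disulfide.iter_residues()
    found = evaluate_atom_pairs(a, b)
    assert [(c.contact_type, round(c.distance, 6)) for c in found
            if c.contact_type == "disulfide_bond"] == [("disulfide_bond", 2.05)]

    # backbone-only Ala/Gly can only hydrogen bond
    st = SyntheticStructure()
    st.add_residue("A", "ALA", 1)
    st.add_residue("A", "GLY", 2, translation=(4.2, 0.0, 0.0))
    ala, gly = parse_structure(st.write(tmp_path / "ag.pdb")).iter_residues()
    types = {c.contact_type for c in evaluate_atom_pairs(ala, gly)}
    assert types == {"hydrogen_bond"}

    # far apart: nothing
    st = SyntheticStructure()
    st.add_residue("A", "ALA", 1)
    st.add_residue("A", "ALA", 2, translation=(12.0, 0.0, 0.0))
    a1, a2 = parse_structure(st.write(tmp_path / "far.pdb")).iter_residues()
    assert evaluate_atom_pairs(a1, a2) == []
    with pytest.raises(ValueError):
        evaluate_atom_pairs(a1, a1)


def test_empty_inputs_give_empty_output(tmp_path):
    assert detect_contacts(Protein(id="empty")) == []
    st = SyntheticStructure()
    st.add_residue("A", "LYS", 1)
    single = parse_structure(st.write(tmp_path / "one.pdb"))
    assert detect_contacts(single) == []


def test_detection_matches_oracle_and_is_deterministic(small_battery):
    for protein in small_battery:
        first = detect_contacts(protein)
        assert contact_keys(first) == contact_keys(all_atoms_contacts(protein))
        assert first == detect_contacts(protein)  # byte-identical rerun
        keys = [c.key() for c in first]
        assert keys == sorted(keys)
        assert len(keys) == len(set(keys))
        for c in first:
            assert (c.chain_1, c.residue_number_1, c.insertion_code_1,
                    c.atom_name_1) \
                <= (c.chain_2, c.residue_number_2, c.insertion_code_2,
                    c.atom_name_2)


def test_shrinking_a_range_never_adds_contacts(small_battery):
    narrow = default_rules({"hydrophobic": {"min": 2.5, "max": 4.0},
                            "hydrogen_bond": {"max": 3.0}})
    for protein in small_battery[:6]:
        wide_keys = contact_keys(detect_contacts(protein))
        assert contact_keys(detect_contacts(protein, narrow)) <= wide_keys


def test_backbone_neighbor_exclusion_flag(tmp_path):
    st = SyntheticStructure()
    st.add_residue("A", "ALA", 1)
    st.add_residue("A", "GLY", 2, translation=(4.2, 0.0, 0.0))
    protein = parse_structure(st.write(tmp_path / "adj.pdb"))
    default = detect_contacts(protein)
    assert default, "sequence neighbours are evaluated by default"
    filtered = detect_contacts(protein, exclude_backbone_neighbors=True)
    assert filtered == []  # Ala/Gly only have main-chain atoms


def test_residue_without_ca_still_matches_oracle(tmp_path):
    """CA-less residues anchor at their centroid and use only the coarse
    tier, so no contact is pruned away."""
    from caprune.geometry import residue_template
    st = SyntheticStructure()
    st.add_residue("A", "ARG", 1)
    for name, pos in residue_template("LYS").items():
        if name == "CA":
            continue
        st.add_atom("A", "LYS", 2, name, np.asarray(pos) + [6.0, 0.0, 0.0])
    protein = parse_structure(st.write(tmp_path / "noca.pdb"))
    residues = list(protein.iter_residues())
    assert residues[1].ca is None
    engine = detect_contacts(protein)
    assert engine, "fixture should produce at least one contact"
    assert contact_keys(engine) == contact_keys(all_atoms_contacts(protein))


def test_stacking_reported_once_per_residue_pair(tmp_path):
    protein = parse_structure(
        make_contact_fixture("aromatic_stacking", 3.8, 1, tmp_path))
    stackings = [c for c in detect_contacts(protein)
                 if c.contact_type == "aromatic_stacking"]
    assert len(stackings) == 1
    (c,) = stackings
    assert c.atom_name_1 == c.atom_name_2 == RING_PSEUDO_ATOM
    assert c.distance == pytest.approx(3.8, abs=2e-3)
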