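"""Cα distance matrix: layout, ε extension, conservative bound, accumulation."""

import io
import math

import numpy as np
import pytest

from caprune.ca_matrix import (
    CaDistanceMatrix,
    CutoffExtension,
    accumulate_max_ca_distances,
    build_conservative_matrix,
    extend_matrix,
    global_coarse_cutoff,
    nonredundant_pair_count,
    pair_cutoff,
)
from caprune.fixtures import SyntheticStructure
from caprune.geometry import STANDARD_RESIDUES, max_ca_extent
from caprune.structure_io import parse_structure


@pytest.fixture()
def reference_matrix():
    """A matrix carrying the two published empirical extremes, with
    conservative values elsewhere (round-tripped through CSV)."""
    m = build_conservative_matrix()
    entries = m.entries.copy()
    idx = {r: i for i, r in enumerate(STANDARD_RESIDUES)}
    entries[idx["ARG"], idx["ARG"]] = 20.46
    a, g = idx["ALA"], idx["GLY"]
    entries[a, g] = entries[g, a] = 7.65
    buffer = io.StringIO()
    CaDistanceMatrix(entries=entries).to_csv(buffer)
    buffer.seek(0)
    return CaDistanceMatrix.from_csv(buffer)


def test_nonredundant_pair_count_formula():
    assert nonredundant_pair_count(20) == 210
    assert build_conservative_matrix().pair_count == 210
    # n(n-1)/2 + n counts the upper triangle including the diagonal
    assert nonredundant_pair_count(3) == 6


def test_lookup_is_symmetric_and_rejects_unknown_codes(reference_matrix):
    assert pair_cutoff(reference_matrix, "ARG", "ARG") == pytest.approx(20.46)
    assert pair_cutoff(reference_matrix, "ALA", "GLY") == pytest.approx(7.65)
    for a in STANDARD_RESIDUES:
        for b in STANDARD_RESIDUES:
            assert pair_cutoff(reference_matrix, a, b) \
                == pair_cutoff(reference_matrix, b, a)
    with pytest.raises(ValueError):
        pair_cutoff(reference_matrix, "XXX", "ALA")


def test_global_coarse_cutoff_is_the_largest_entry(reference_matrix):
    assert global_coarse_cutoff(reference_matrix) == pytest.approx(20.46)
    flat = CaDistanceMatrix(entries=np.full((20, 20), 9.0))
    assert global_coarse_cutoff(flat) == 9.0
    extended = extend_matrix(reference_matrix,
                             CutoffExtension(user_max_contact=7.0))
    assert global_coarse_cutoff(extended) == pytest.approx(21.46)


def test_epsilon_extension_rules():
    assert CutoffExtension(user_max_contact=4.5).epsilon == 0.0
    assert CutoffExtension(user_max_contact=6.0).epsilon == 0.0
    assert CutoffExtension(user_max_contact=7.5).epsilon == pytest.approx(1.5)
    with pytest.raises(ValueError):
        CutoffExtension(user_max_contact=-1.0)

    m = build_conservative_matrix()
    unchanged = extend_matrix(m, CutoffExtension(user_max_contact=6.0))
    assert np.array_equal(unchanged.entries, m.entries)
    plus = extend_matrix(m, CutoffExtension(user_max_contact=7.5))
    assert np.allclose(plus.entries, m.entries + 1.5)
    # additivity: extending twice equals one extension from the base
    twice = extend_matrix(
        extend_matrix(m, CutoffExtension(user_max_contact=7.0)),
        CutoffExtension(user_max_contact=6.5))
    once = extend_matrix(m, CutoffExtension(user_max_contact=7.5))
    assert np.allclose(twice.entries, once.entries)


def test_conservative_bound_dominates_known_empirical_values():
    m = build_conservative_matrix()
    assert m.provenance == "conservative_bound"
    assert np.allclose(m.entries, m.entries.T)
    # published archive extremes bracket the bound
    assert pair_cutoff(m, "ALA", "GLY") >= 7.65
    assert 20.46 <= pair_cutoff(m, "ARG", "ARG") <= 21.0
    arg = STANDARD_RESIDUES.index("ARG")
    assert m.entries.max() == m.entries[arg, arg]
    assert m.entries.min() >= 7.0
    assert pair_cutoff(m, "GLY", "GLY") \
        == pytest.approx(2 * max_ca_extent("GLY") + 6.0)


def test_csv_round_trip(tmp_path, reference_matrix):
    path = tmp_path / "matrix.csv"
    reference_matrix.to_csv(path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 21  # header + 20 rows
    assert lines[0].split(",")[1:] == list(STANDARD_RESIDUES)
    back = CaDistanceMatrix.from_csv(path)
    assert np.allclose(back.entries, reference_matrix.entries, atol=1e-4)


def _two_residue_protein(tmp_path, res_a, res_b, separation):
    st = SyntheticStructure()
    st.add_residue("A", res_a, 1)
    st.add_residue("A", res_b, 2, translation=(separation, 0.0, 0.0))
    return parse_structure(st.write(tmp_path / f"{res_a}_{res_b}.pdb"))


def test_accumulation_records_observed_ca_distance(tmp_path):
    """One Ala–Gly hydrogen-bonded pair: the entry becomes the observed
    Cα–Cα distance; unobserved pairs keep the conservative value."""
    protein = _two_residue_protein(tmp_path, "ALA", "GLY", 4.2)
    residues = list(protein.iter_residues())
    ca_sep = float(np.linalg.norm(residues[0].ca.position
                                  - residues[1].ca.position))
    assert ca_sep == pytest.approx(4.2, abs=1e-3)

    m = accumulate_max_ca_distances([protein])
    assert m.provenance == "corpus_accumulated"
    assert pair_cutoff(m, "ALA", "GLY") == pytest.approx(ca_sep)
    conservative = build_conservative_matrix()
    assert pair_cutoff(m, "CYS", "CYS") \
        == pair_cutoff(conservative, "CYS", "CYS")
    idx = {r: i for i, r in enumerate(STANDARD_RESIDUES)}
    assert m.observed[idx["ALA"], idx["GLY"]]
    assert not m.observed[idx["CYS"], idx["CYS"]]


def test_accumulation_is_order_independent(tmp_path):
    a = _two_residue_protein(tmp_path, "SER", "THR", 4.0)
    b = _two_residue_protein(tmp_path, "SER", "THR", 5.5)
    ab = accumulate_max_ca_distances([a, b])
    ba = accumulate_max_ca_distances([b, a])
    assert np.allclose(ab.entries, ba.entries)
    # the larger observation wins
    assert pair_cutoff(ab, "SER", "THR") == pytest.approx(5.5, abs=1e-3)


def test_empty_corpus_returns_the_conservative_matrix():
    m = accumulate_max_ca_distances([])
    assert np.allclose(m.entries, build_conservative_matrix().entries)
    assert not m.observed.any()


def test_matrix_validation():
    with pytest.raises(ValueError):
        CaDistanceMatrix(entries=np.zeros((19, 19)))
    bad = np.zeros((20, 20))
    bad[0, 1] = 5.0
    with pytest.raises(ValueError):
        CaDistanceMatrix(entries=bad)
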