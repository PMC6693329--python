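"""Geometry representations, XYZ round-trips, and similarity-function axioms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import exhaustive_best_mapping, random_geometry, random_rigid_motion
from pesmap.geom import (
    CompositionError,
    DimensionError,
    Geometry,
    MassWeightedVector,
    XYZParseError,
    ZeroNormError,
    cosine_distance,
    distance_matrix,
    dm_similarity,
    element_constrained_mapping,
    mass_weighted_vector,
    read_xyz,
    write_xyz,
)


class TestXYZ:
    def test_water_block_parses(self, tmp_path, water):
        p = tmp_path / "w.xyz"
        write_xyz(water, p)
        (g,) = read_xyz(p)
        assert g.elements == ["O", "H", "H"]
        assert g.n_atoms == 3
        assert g.label.startswith("water")

    def test_round_trip_preserves_coordinates(self, tmp_path):
        g = random_geometry(6, seed=0, elements=["C", "C", "O", "H", "H", "N"])
        p = tmp_path / "g.xyz"
        write_xyz(g, p)
        (back,) = read_xyz(p)
        assert back.elements == g.elements
        np.testing.assert_allclose(back.coords, g.coords, atol=1e-6)

    def test_multi_frame_order_and_energy_token(self, tmp_path):
        g1 = random_geometry(3, seed=1).with_coords(random_geometry(3, seed=1).coords, energy=-1.25)
        g2 = random_geometry(3, seed=2)
        p = tmp_path / "two.xyz"
        write_xyz([g1, g2], p)
        frames = read_xyz(p)
        assert len(frames) == 2
        assert frames[0].energy == pytest.approx(-1.25)
        assert frames[1].energy is None
        np.testing.assert_allclose(frames[1].coords, g2.coords, atol=1e-6)

    @pytest.mark.parametrize(
        "content, lineno",
        [
            ("nope\ncomment\nO 0 0 0\n", 1),  # malformed count
            ("1\ncomment\nQq 0 0 0\n", 3),  # unknown element
            ("1\ncomment\nO 0 zero 0\n", 3),  # non-numeric coordinate
            ("3\ncomment\nO 0 0 0\nH 1 0 0\n", 1),  # truncated frame
        ],
    )
    def test_parse_errors_name_line(self, tmp_path, content, lineno):
        p = tmp_path / "bad.xyz"
        p.write_text(content)
        with pytest.raises(XYZParseError, match=f"line {lineno}"):
            read_xyz(p)


class TestDistanceMatrix:
    def test_collinear_ruler(self):
        g = Geometry(["X"] * 3, [[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        D = distance_matrix(g).D
        assert sorted([D[0, 1], D[1, 2], D[0, 2]]) == [1.0, 1.0, 2.0]
        assert np.all(np.diag(D) == 0.0)

    def test_unit_equilateral_triangle(self):
        h = np.sqrt(3) / 2
        g = Geometry(["X"] * 3, [[0, 0, 0], [1, 0, 0], [0.5, h, 0]])
        D = distance_matrix(g).D
        iu = np.triu_indices(3, 1)
        np.testing.assert_allclose(D[iu], 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_invariance(self, seed):
        g = random_geometry(7, seed=seed)
        moved = random_rigid_motion(g, seed=seed + 100)
        np.testing.assert_allclose(
            distance_matrix(g).D, distance_matrix(moved).D, atol=1e-10
        )

    def test_quadratic_vs_linear_container_growth(self):
        g4, g8 = random_geometry(4, seed=3), random_geometry(8, seed=3)
        assert distance_matrix(g8).D.size == 4 * distance_matrix(g4).D.size
        assert mass_weighted_vector(g8).values.size == 2 * mass_weighted_vector(g4).values.size


class TestDmSimilarity:
    def test_identity_is_zero(self):
        g = random_geometry(5, seed=4)
        assert dm_similarity(g, g) == 0.0

    def test_hand_enumerated_chains(self):
        a = Geometry(["X"] * 3, [[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        b = Geometry(["X"] * 3, [[0, 0, 0], [1, 0, 0], [3, 0, 0]])
        # pairs (0,1): |1-1|=0, (0,2): |2-3|=1, (1,2): |1-2|=1
        assert dm_similarity(a, b) == pytest.approx(2.0)

    def test_mismatched_sizes_rejected(self):
        a, b = random_geometry(4, seed=5), random_geometry(5, seed=6)
        with pytest.raises(DimensionError):
            dm_similarity(a, b)

    @pytest.mark.parametrize("seed", range(5))
    def test_element_mapping_never_worse_than_identity(self, seed):
        a = random_geometry(5, seed=seed)
        b = random_geometry(5, seed=seed + 50)
        assert dm_similarity(a, b, mapping="element") <= dm_similarity(a, b) + 1e-12


class TestMassWeightedVector:
    def test_single_atom_sits_at_its_com(self):
        g = Geometry(["C"], [[3.0, -2.0, 1.0]])
        np.testing.assert_allclose(mass_weighted_vector(g).values, [0.0])

    def test_homonuclear_diatomic(self):
        r, m = 1.4, 14.0031
        g = Geometry(["N", "N"], [[0, 0, 0], [r, 0, 0]])
        np.testing.assert_allclose(mass_weighted_vector(g).values, m * r / 2, rtol=1e-12)

    def test_translation_invariance(self):
        g = random_geometry(6, seed=7, elements=["C", "O", "H", "H", "N", "S"])
        shifted = g.translated([5.0, -3.0, 2.0])
        np.testing.assert_allclose(
            mass_weighted_vector(g).values, mass_weighted_vector(shifted).values, atol=1e-10
        )

    def test_sorted_flag_orders_entries(self):
        g = random_geometry(6, seed=8, elements=["C", "O", "H", "H", "N", "S"])
        v = mass_weighted_vector(g, sorted=True).values
        assert np.all(np.diff(v) >= 0)


class TestCosineDistance:
    def test_identity_is_zero(self):
        v = MassWeightedVector(np.array([1.0, 2.0, 3.0]))
        assert cosine_distance(v, v) == pytest.approx(0.0, abs=1e-12)

    def test_quarter_turn_pair(self):
        # arccos(1/sqrt(2))/pi = 0.25
        a = MassWeightedVector(np.array([1.0, 1.0]))
        b = MassWeightedVector(np.array([1.0, 0.0]))
        assert cosine_distance(a, b) == pytest.approx(0.25, abs=1e-12)

    def test_zero_norm_rejected(self):
        z = MassWeightedVector(np.array([0.0, 0.0]))
        v = MassWeightedVector(np.array([1.0, 1.0]))
        with pytest.raises(ZeroNormError):
            cosine_distance(z, v)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_range_for_nonnegative_vectors(self, seed):
        rng = np.random.default_rng(seed)
        a = MassWeightedVector(rng.uniform(0.0, 5.0, 6) + 1e-6)
        b = MassWeightedVector(rng.uniform(0.0, 5.0, 6) + 1e-6)
        d = cosine_distance(a, b)
        assert 0.0 <= d <= 0.5


class TestElementConstrainedMapping:
    def test_reversed_relabelling_recovered(self):
        g = random_geometry(6, seed=9, elements=["C", "O", "H", "H", "N", "S"])
        rev = Geometry(list(reversed(g.elements)), g.coords[::-1].copy())
        perm = element_constrained_mapping(g, rev)
        assert dm_similarity(g, rev, mapping="element") == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_array_equal(perm, np.arange(6)[::-1])

    def test_element_constraint_respected(self, water):
        other = random_rigid_motion(water, seed=11)
        perm = element_constrained_mapping(water, other)
        for i, j in enumerate(perm):
            assert water.elements[i] == other.elements[j]

    @pytest.mark.parametrize("seed", range(8))
    def test_heuristic_close_to_exhaustive_optimum(self, seed):
        elements = ["C", "C", "O", "H", "H", "H"]
        a = random_geometry(6, seed=seed, elements=elements)
        b = random_geometry(6, seed=seed + 500, elements=elements)
        best, _ = exhaustive_best_mapping(a, b)
        heur = dm_similarity(a, b, mapping="element")
        assert heur <= 1.05 * best + 1e-9


class TestSimilarityAxioms:
    """The three axioms plus rigid-motion invariance, on seeded random pairs."""

    @pytest.mark.parametrize("seed", range(25))
    def test_axioms_and_invariance(self, seed):
        elements = ["C", "O", "N", "H", "H", "S", "C", "H"]
        a = random_geometry(8, seed=seed, elements=elements)
        b = random_geometry(8, seed=seed + 1000, elements=elements)
        d_ab = dm_similarity(a, b)
        assert d_ab >= 0.0
        assert d_ab == pytest.approx(dm_similarity(b, a), abs=1e-12)
        assert dm_similarity(a, a) == 0.0
        moved = random_rigid_motion(a, seed=seed + 2000)
        assert dm_similarity(a, moved) == pytest.approx(0.0, abs=1e-8)
        assert dm_similarity(moved, b) == pytest.approx(d_ab, abs=1e-8)

        va, vb = mass_weighted_vector(a), mass_weighted_vector(b)
        c_ab = cosine_distance(va, vb)
        assert 0.0 <= c_ab <= 1.0
        assert c_ab == pytest.approx(cosine_distance(vb, va), abs=1e-14)
        assert cosine_distance(va, va) == pytest.approx(0.0, abs=1e-7)
        vm = mass_weighted_vector(moved)
        assert cosine_distance(va, vm) == pytest.approx(0.0, abs=1e-7)

    def test_sorted_cosine_invariant_under_relabelling(self):
        g = random_geometry(7, seed=42, elements=["C", "C", "O", "H", "H", "N", "S"])
        rng = np.random.default_rng(0)
        perm = rng.permutation(7)
        shuffled = Geometry([g.elements[i] for i in perm], g.coords[perm].copy())
        va = mass_weighted_vector(g, sorted=True)
        vb = mass_weighted_vector(shuffled, sorted=True)
        assert cosine_distance(va, vb) == pytest.approx(0.0, abs=1e-10)
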