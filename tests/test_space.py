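"""Gower dissimilarity, PCoA/Cailliez embedding, quality, and convex-hull FRic."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from fediv import (
    DegenerateHullError,
    TraitDefinition,
    TraitSchema,
    TraitSpace,
    ValidationError,
    fric,
    gower_matrix,
    pcoa_cailliez,
    space_quality,
)


def brute_force_gower(tuples, schema):
    """Literal per-trait, per-pair implementation of the Gower formula."""
    n = len(tuples)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            total = 0.0
            for t, trait in enumerate(schema.traits):
                a, b = tuples[i][t], tuples[j][t]
                if trait.ordered and trait.n_levels > 1:
                    total += abs(trait.rank(a) - trait.rank(b)) / (trait.n_levels - 1)
                else:
                    total += 0.0 if a == b else 1.0
            D[i, j] = total / len(schema.traits)
    return D


def random_schema_and_tuples(rng, max_traits=4, max_levels=5, max_entities=8):
    n_traits = int(rng.integers(2, max_traits + 1))
    traits = tuple(
        TraitDefinition(
            f"t{i}",
            tuple(f"l{j}" for j in range(int(rng.integers(2, max_levels + 1)))),
            ordered=bool(rng.integers(2)),
        )
        for i in range(n_traits)
    )
    schema = TraitSchema(traits)
    tuples = {
        tuple(t.levels[rng.integers(t.n_levels)] for t in traits)
        for _ in range(int(rng.integers(2, max_entities + 1)))
    }
    return schema, sorted(tuples)


class TestGower:
    def test_two_nominal_mismatches_of_six(self, fine_schema):
        t1 = ("S1", "HD", "sedentary", "solitary", "diurnal", "bottom")
        t2 = ("S1", "HM", "mobile", "solitary", "diurnal", "bottom")
        D = gower_matrix([t1, t2], fine_schema)
        assert D[0, 1] == pytest.approx(2 / 6)
        assert D[0, 0] == 0.0
        assert D[1, 0] == D[0, 1]

    def test_ordered_size_extreme_ranks(self, fine_schema):
        t1 = ("S1", "HD", "sedentary", "solitary", "diurnal", "bottom")
        t2 = ("S6", "HD", "sedentary", "solitary", "diurnal", "bottom")
        D = gower_matrix([t1, t2], fine_schema)
        assert D[0, 1] == pytest.approx(1 / 6)

    def test_single_entity_rejected(self, fine_schema):
        with pytest.raises(ValidationError, match="at least 2"):
            gower_matrix([("S1", "HD", "sedentary", "solitary", "diurnal", "bottom")],
                         fine_schema)

    def test_matches_bruteforce_on_random_schemas(self, rng):
        for _ in range(25):
            schema, tuples = random_schema_and_tuples(rng)
            if len(tuples) < 2:
                continue
            D = gower_matrix(tuples, schema)
            np.testing.assert_allclose(D, brute_force_gower(tuples, schema), atol=1e-12)
            assert (D >= 0).all() and (D <= 1 + 1e-12).all()


class TestPCoA:
    def test_euclidean_square_needs_no_correction(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        D = squareform(pdist(pts))
        space = pcoa_cailliez(D, m=2)
        assert space.cailliez_constant == 0.0
        np.testing.assert_allclose(pdist(space.coordinates), pdist(pts), atol=1e-8)

    def test_three_equidistant_points_spectrum(self):
        D = np.ones((3, 3)) - np.eye(3)
        space = pcoa_cailliez(D, m=2)
        # equilateral triangle: two equal positive eigenvalues, nothing else
        assert space.eigenvalues.size == 2
        assert space.eigenvalues[0] == pytest.approx(space.eigenvalues[1])

    def test_agrees_with_skbio_on_euclidean_input(self, rng):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        pts = rng.normal(size=(12, 5))
        D = squareform(pdist(pts))
        ours = pcoa_cailliez(D, m=4)
        theirs = skbio_pcoa(D, dimensions=4)
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues)[::-1][:4],
            np.asarray(theirs.eigvals)[:4],
            rtol=1e-6,
        )
        np.testing.assert_allclose(
            pdist(ours.coordinates),
            pdist(np.asarray(theirs.samples)),
            rtol=1e-6,
        )

    def test_cailliez_removes_negative_eigenvalues(self, fine_schema, rng):
        schema, tuples = random_schema_and_tuples(rng, max_entities=8)
        while len(tuples) < 5:
            schema, tuples = random_schema_and_tuples(rng, max_entities=8)
        D = gower_matrix(tuples, schema)
        space = pcoa_cailliez(D, m=2)
        # after correction every retained eigenvalue is positive
        assert (space.eigenvalues > 0).all()

    def test_too_many_axes_rejected_with_maximum(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        D = squareform(pdist(pts))
        with pytest.raises(ValidationError, match="2 positive axes"):
            pcoa_cailliez(D, m=4)


class TestQuality:
    def test_full_rank_euclidean_space_has_zero_msd(self, rng):
        pts = rng.normal(size=(10, 3))
        D = squareform(pdist(pts))
        space = pcoa_cailliez(D, m=3)
        q = space_quality(D, space, permutations=99, seed=0)
        assert q.msd == pytest.approx(0.0, abs=1e-10)
        assert q.mantel_r == pytest.approx(1.0)
        assert q.mantel_r2 == pytest.approx(q.mantel_r ** 2)

    def test_msd_decreases_with_more_axes(self, rng):
        pts = rng.normal(size=(15, 3))
        D = squareform(pdist(pts))
        m1 = space_quality(D, pcoa_cailliez(D, m=2), permutations=99, seed=0).msd
        m3 = space_quality(D, pcoa_cailliez(D, m=3), permutations=99, seed=0).msd
        assert m1 > m3

    def test_shuffled_dissimilarities_give_near_zero_mantel(self, rng):
        pts = rng.normal(size=(25, 4))
        D = squareform(pdist(pts))
        space = pcoa_cailliez(D, m=4)
        perm = rng.permutation(25)
        shuffled = D[np.ix_(perm, perm)]
        q = space_quality(shuffled, TraitSpace(space.coordinates, space.eigenvalues, 4),
                          permutations=199, seed=1)
        assert abs(q.mantel_r) < 0.35

    def test_low_permutation_count_flagged(self, rng):
        pts = rng.normal(size=(8, 3))
        D = squareform(pdist(pts))
        space = pcoa_cailliez(D, m=3)
        q = space_quality(D, space, permutations=49, seed=0)
        assert q.low_permutations


def cube_space():
    corners = np.array(
        [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
    )
    half = corners * 0.5
    coords = np.vstack([corners, half])
    return TraitSpace(coords, np.ones(3), m=3)


class TestFRic:
    def test_subset_equal_to_pool_is_100(self, rng):
        space = TraitSpace(rng.normal(size=(12, 3)), np.ones(3), m=3)
        res = fric(space, range(12))
        assert res.fric_percent == pytest.approx(100.0)

    def test_hull_vertices_alone_give_100(self, rng):
        from scipy.spatial import ConvexHull

        space = TraitSpace(rng.normal(size=(20, 3)), np.ones(3), m=3)
        vertices = ConvexHull(space.coordinates).vertices
        res = fric(space, vertices)
        assert res.fric_percent == pytest.approx(100.0)

    def test_half_cube_inside_unit_cube(self):
        space = cube_space()
        res = fric(space, range(8, 16), range(16))
        assert res.fric_percent == pytest.approx(12.5)

    def test_monotone_under_adding_entities(self, rng):
        space = TraitSpace(rng.normal(size=(20, 3)), np.ones(3), m=3)
        subset = list(range(5))
        prev = fric(space, subset).fric_percent
        for extra in range(5, 20):
            subset.append(extra)
            cur = fric(space, subset).fric_percent
            assert cur >= prev - 1e-9
            prev = cur

    def test_degenerate_subset_raises(self):
        space = cube_space()
        with pytest.raises(DegenerateHullError):
            fric(space, [0, 1, 2, 3])  # coplanar cube face

    def test_subset_outside_pool_rejected(self):
        space = cube_space()
        with pytest.raises(ValidationError, match="contained"):
            fric(space, [0, 1, 2, 14], pool=range(8))

    def test_permuting_entity_order_preserves_volume(self, rng):
        coords = rng.normal(size=(15, 3))
        perm = rng.permutation(15)
        a = fric(TraitSpace(coords, np.ones(3), 3), range(6))
        b = fric(TraitSpace(coords[perm], np.ones(3), 3),
                 np.nonzero(perm < 6)[0])
        assert a.hull_volume == pytest.approx(b.hull_volume)
        assert a.fric_percent == pytest.approx(b.fric_percent)
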