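"""Gower distances, PCoA embedding, and the functional indices."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import Delaunay
from shapely.geometry import MultiPoint

from parkshift.synthetic import generate_trait_table
from parkshift.traitspace import (
    build_functional_space,
    functional_dispersion,
    functional_richness,
    gower_distance,
    pcoa_embed,
    space_quality_msd,
    taxon_restrictedness,
)
from conftest import make_space


def _table(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, index=[f"sp{i}" for i in range(len(rows))])
    df.index.name = "species_id"
    return df


class TestGower:
    def test_identical_rows_distance_zero(self):
        row = dict(feeding_behavior="a", primary_food="b", habitat="c",
                   nesting="d", relative_size=1)
        other = dict(row, feeding_behavior="x")  # keep >=2 levels per column
        d = gower_distance(_table([row, row, other]))
        assert d.iloc[0, 1] == 0.0

    def test_maximal_difference_distance_one(self):
        a = dict(feeding_behavior="a", primary_food="a", habitat="a",
                 nesting="a", relative_size=0)
        b = dict(feeding_behavior="b", primary_food="b", habitat="b",
                 nesting="b", relative_size=4)
        d = gower_distance(_table([a, b]))
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_two_of_four_categorical_mismatches(self):
        a = dict(feeding_behavior="a", primary_food="a", habitat="a",
                 nesting="a", relative_size=0)
        b = dict(feeding_behavior="b", primary_food="b", habitat="a",
                 nesting="a", relative_size=0)
        c = dict(feeding_behavior="a", primary_food="a", habitat="b",
                 nesting="b", relative_size=1)  # keeps every column 2-level
        d = gower_distance(_table([a, b, c]))
        assert d.iloc[0, 1] == pytest.approx(0.4)

    def test_single_level_column_contributes_zero_with_warning(self):
        a = dict(feeding_behavior="a", primary_food="a", habitat="a",
                 nesting="a", relative_size=0)
        b = dict(feeding_behavior="b", primary_food="a", habitat="b",
                 nesting="b", relative_size=1)
        with pytest.warns(UserWarning, match="primary_food"):
            d = gower_distance(_table([a, b]))
        assert d.iloc[0, 1] == pytest.approx(4 / 5)

    def test_symmetry_zero_diagonal_unit_range(self):
        traits = generate_trait_table(40, seed=3)
        d = gower_distance(traits).to_numpy()
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0.0)
        assert d.min() >= 0.0 and d.max() <= 1.0

    def test_sqrt_corrected_matrix_has_no_negative_eigenvalues(self):
        traits = generate_trait_table(25, seed=7)
        d = np.sqrt(gower_distance(traits).to_numpy())
        n = d.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        eig = np.linalg.eigvalsh(-0.5 * j @ (d**2) @ j)
        assert eig.min() > -1e-8


class TestPCoA:
    def test_three_collinear_points(self):
        d = pd.DataFrame([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        space = pcoa_embed(d, n_axes=1, correction=None)
        assert space.eigenvalues[0] == pytest.approx(2.0)
        axis = np.sort(space.coords.to_numpy().ravel())
        np.testing.assert_allclose(axis, [-1.0, 0.0, 1.0], atol=1e-9)

    def test_euclidean_input_is_reproduced(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(20, 4))
        d = pd.DataFrame(np.linalg.norm(pts[:, None] - pts[None, :], axis=-1))
        space = pcoa_embed(d, n_axes=4, correction=None)
        emb = space.coords.to_numpy()
        d2 = np.linalg.norm(emb[:, None] - emb[None, :], axis=-1)
        assert np.max(np.abs(d2 - d.to_numpy())) < 1e-9

    def test_two_points_have_one_positive_axis(self):
        d = pd.DataFrame([[0.0, 0.5], [0.5, 0.0]])
        space = pcoa_embed(d, n_axes=1, correction=None)
        assert space.n_axes == 1
        with pytest.raises(ValueError, match="n_axes"):
            pcoa_embed(d, n_axes=2, correction=None)

    def test_agrees_with_reference_implementation(self):
        """Cross-check against scikit-bio's PCoA (eigenvalues and the
        geometry of the retained subspace, which is sign/rotation free)."""
        from scipy.spatial.distance import pdist
        from skbio import DistanceMatrix
        from skbio.stats.ordination import pcoa as skbio_pcoa

        traits = generate_trait_table(15, seed=1)
        d = np.sqrt(gower_distance(traits).to_numpy())
        ours = pcoa_embed(pd.DataFrame(d), n_axes=6, correction=None)
        ref = skbio_pcoa(DistanceMatrix(d))
        np.testing.assert_allclose(
            ours.eigenvalues, ref.eigvals.to_numpy()[:6], atol=1e-8
        )
        np.testing.assert_allclose(
            pdist(ours.coords.to_numpy()),
            pdist(ref.samples.to_numpy()[:, :6]),
            atol=1e-6,
        )


class TestSpaceQuality:
    def test_exact_embedding_zero_msd(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        d = pd.DataFrame(np.linalg.norm(pts[:, None] - pts[None, :], axis=-1))
        space = pcoa_embed(d, n_axes=3, correction=None)
        assert space_quality_msd(d, space) == pytest.approx(0.0, abs=1e-12)

    def test_msd_non_increasing_in_axes(self):
        traits = generate_trait_table(30, seed=5)
        d = gower_distance(traits)
        msds = [
            space_quality_msd(d, pcoa_embed(d, n_axes=k, correction="sqrt"))
            for k in range(2, 7)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(msds, msds[1:]))

    def test_identical_species_zero_msd(self):
        from parkshift.traitspace import FunctionalSpace

        d = pd.DataFrame(np.zeros((4, 4)))
        coords = pd.DataFrame(np.zeros((4, 2)), columns=["axis_1", "axis_2"])
        space = FunctionalSpace(coords=coords, eigenvalues=np.zeros(2))
        assert space_quality_msd(d, space) == 0.0


class TestFunctionalRichness:
    def test_whole_pool_is_one(self, unit_square_space):
        pts = unit_square_space.coords.to_numpy()
        fric, reason = functional_richness(pts, unit_square_space)
        assert reason is None
        assert fric == pytest.approx(1.0)

    def test_three_corners_are_half_the_square(self, unit_square_space):
        pts = np.array([[0, 0], [1, 0], [1, 1]], dtype=float)
        fric, reason = functional_richness(pts, unit_square_space)
        assert reason is None
        # shoelace oracle for the triangle
        assert fric == pytest.approx(0.5)

    def test_too_few_members_flagged(self, unit_square_space):
        pts = np.array([[0, 0], [1, 1]], dtype=float)
        fric, reason = functional_richness(pts, unit_square_space)
        assert fric is None and reason == "insufficient_species"

    def test_collinear_members_flagged(self, unit_square_space):
        pts = np.array([[0, 0], [0.5, 0.5], [1, 1]], dtype=float)
        fric, reason = functional_richness(pts, unit_square_space)
        assert fric is None and reason == "degenerate_hull"

    @pytest.mark.parametrize("dim", [2, 3])
    def test_monotone_under_addition_vs_hull_oracle(self, dim):
        """Adding a species never shrinks the hull; 2-D agrees with shapely."""
        rng = np.random.default_rng(42)
        pool = rng.uniform(0, 1, size=(30, dim))
        space = make_space(pool)
        for _ in range(50):
            k = rng.integers(dim + 1, 10)
            idx = rng.choice(30, size=k, replace=False)
            before, r1 = functional_richness(pool[idx], space)
            extra = rng.choice(np.setdiff1d(np.arange(30), idx))
            after, r2 = functional_richness(
                np.vstack([pool[idx], pool[extra]]), space
            )
            if r1 or r2:
                continue  # degenerate draw
            assert after >= before - 1e-12
            if dim == 2:
                oracle = (
                    MultiPoint(pool[idx]).convex_hull.area
                    / MultiPoint(pool).convex_hull.area
                )
                assert before == pytest.approx(oracle, abs=1e-10)
            else:
                tri = Delaunay(pool[idx])
                vol = 0.0
                for simplex in tri.simplices:
                    mat = pool[idx][simplex[1:]] - pool[idx][simplex[0]]
                    vol += abs(np.linalg.det(mat)) / 6.0
                pool_tri = Delaunay(pool)
                pvol = 0.0
                for simplex in pool_tri.simplices:
                    mat = pool[simplex[1:]] - pool[simplex[0]]
                    pvol += abs(np.linalg.det(mat)) / 6.0
                assert before == pytest.approx(vol / pvol, abs=1e-8)


class TestFunctionalDispersion:
    def test_singleton_zero(self, unit_square_space):
        raw, scaled = functional_dispersion(
            np.array([[0.3, 0.7]]), unit_square_space
        )
        assert raw == 0.0 and scaled == 0.0

    def test_two_most_distant_species_scaled_one(self, unit_square_space):
        # opposite corners are the pool's most distant pair (distance sqrt(2))
        pts = np.array([[0, 0], [1, 1]], dtype=float)
        raw, scaled = functional_dispersion(pts, unit_square_space)
        assert raw == pytest.approx(np.sqrt(2) / 2)
        assert scaled == pytest.approx(1.0, abs=1e-12)

    def test_equilateral_triangle_exceeds_one(self):
        d = 1.0
        tri = np.array(
            [[0, 0], [d, 0], [d / 2, d * np.sqrt(3) / 2]], dtype=float
        )
        space = make_space(tri)  # pool max distance = side length d
        raw, scaled = functional_dispersion(tri, space)
        assert raw == pytest.approx(d / np.sqrt(3))
        assert scaled == pytest.approx(2 / np.sqrt(3))

    def test_zero_iff_coincident(self, unit_square_space):
        pts = np.repeat([[0.2, 0.2]], 5, axis=0)
        raw, _ = functional_dispersion(pts, unit_square_space)
        assert raw == 0.0
        raw2, _ = functional_dispersion(
            np.array([[0.2, 0.2], [0.8, 0.2]]), unit_square_space
        )
        assert raw2 > 0.0


class TestRestrictedness:
    def _occurrence(self, presence: np.ndarray, parks, species):
        occ = {}
        for j, park in enumerate(parks):
            for period_idx, period in enumerate(("baseline", "scenario")):
                occ[(park, period)] = frozenset(
                    species[i] for i in range(len(species))
                    if presence[period_idx, i, j]
                )
        return occ

    def test_matches_direct_counting_on_random_matrices(self):
        rng = np.random.default_rng(9)
        parks = [f"p{j}" for j in range(10)]
        species = [f"s{i}" for i in range(15)]
        presence = rng.random((2, 15, 10)) < 0.5
        occ = self._occurrence(presence, parks, species)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            tres = taxon_restrictedness(occ, parks, "summer")
        for row in tres.itertuples():
            i = species.index(row.species_id)
            k = 0 if row.period == "baseline" else 1
            assert row.tres == pytest.approx(presence[k, i].mean())

    def test_boundary_values(self):
        parks = ["p0", "p1"]
        occ = {
            ("p0", "baseline"): frozenset({"everywhere"}),
            ("p1", "baseline"): frozenset({"everywhere"}),
            ("p0", "scenario"): frozenset({"everywhere"}),
            ("p1", "scenario"): frozenset({"everywhere", "gone"}),
        }
        with pytest.warns(UserWarning, match="dropped"):
            tres = taxon_restrictedness(occ, parks, "summer")
        assert set(tres["species_id"]) == {"everywhere"}
        assert (tres["tres"] == 1.0).all()


def test_build_functional_space_end_to_end():
    traits = generate_trait_table(40, seed=12)
    space = build_functional_space(traits, n_axes=6)
    assert space.n_axes == 6
    assert np.all(np.diff(space.eigenvalues) <= 1e-12)
    assert np.all(space.eigenvalues > 0)
    assert space.msd >= 0.0
    assert space.pool_hull_volume > 0.0
    assert space.pool_max_distance > 0.0
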