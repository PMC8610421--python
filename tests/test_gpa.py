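"""Generalized Procrustes analysis building blocks and invariants."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import lumbarmorph as lm
from lumbarmorph.gpa import centroid_size, optimal_rotation, procrustes_distance


def rot_z(deg):
    return Rotation.from_euler("z", deg, degrees=True).as_matrix()


class TestCentroidSize:
    def test_planar_unit_square(self):
        square = np.array(
            [[0.5, 0.5, 0], [0.5, -0.5, 0], [-0.5, 0.5, 0], [-0.5, -0.5, 0]]
        )
        assert centroid_size(square) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_homogeneity(self, template):
        cs = centroid_size(template.coordinates)
        for c in (0.1, 2.0, 17.5):
            assert centroid_size(c * template.coordinates) == pytest.approx(
                c * cs, rel=1e-12
            )

    def test_coincident_points_degenerate(self):
        assert centroid_size(np.ones((5, 3))) == 0.0


class TestOptimalRotation:
    def test_self_alignment_is_identity(self, template):
        a = template.coordinates - template.coordinates.mean(0)
        r = optimal_rotation(a, a)
        assert np.allclose(r, np.eye(3), atol=1e-10)
        assert np.linalg.norm(a @ r - a) < 1e-9

    def test_recovers_known_rotation(self, template):
        a = template.coordinates - template.coordinates.mean(0)
        true = rot_z(90.0)
        b = a @ true.T
        r = optimal_rotation(a, b)
        assert np.allclose(r, true.T, atol=1e-10)

    def test_mirror_image_never_reflected(self, template):
        """The best proper rotation onto a mirror image leaves residual."""
        a = template.coordinates - template.coordinates.mean(0)
        b = a.copy()
        b[:, 0] = -b[:, 0]  # reflect across the yz plane
        r = optimal_rotation(a, b)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(a @ r - b) > 1.0

    def test_matches_scipy_wahba_solution(self, template):
        """Independent oracle: scipy's align_vectors solves the same problem."""
        rng = np.random.default_rng(7)
        a = template.coordinates - template.coordinates.mean(0)
        b = a @ rng.standard_normal((3, 3)) * 0.1 + rng.normal(
            0, 0.5, a.shape
        )
        b = b - b.mean(0)
        r = optimal_rotation(a, b)
        # align_vectors finds R_s minimizing ||R_s a_i - b_i||
        r_scipy, _ = Rotation.align_vectors(b, a)
        assert np.allclose(r, r_scipy.as_matrix().T, atol=1e-8)


class TestGPA:
    def test_single_shape_orbit_collapses(self):
        """Copies of one shape under rigid motion + scale align exactly."""
        sim = lm.gen_landmarks(
            lm.LandmarkSimSpec(group_offset_magnitudes={"A": 0.0},
                               n_per_group=6, noise_sd=0.0),
            seed=11,
        )
        fit = lm.GeneralizedProcrustes(sim.landmarks).fit()
        assert fit.converged
        assert fit.distance_matrix().max() < 1e-6
        spread = fit.aligned - fit.aligned[0]
        assert np.abs(spread).max() < 1e-6

    def test_two_triangles_match_pairwise_opa_oracle(self):
        """GPA of two shapes equals an ordinary two-shape superimposition."""
        t1 = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        t2 = np.array([[0, 0, 0], [1.2, 0, 0], [0.1, 0.8, 0]], dtype=float)
        fit = lm.GeneralizedProcrustes(np.stack([t1, t2]), tol=1e-12).fit()
        d_gpa = fit.distance(0, 1)

        # oracle: direct two-shape partial Procrustes via scipy
        def unit(x):
            c = x - x.mean(0)
            return c / np.sqrt((c**2).sum())

        a, b = unit(t1), unit(t2)
        r, _ = Rotation.align_vectors(a, b)  # rotate b onto a
        d_opa = np.sqrt(((b @ r.as_matrix().T - a) ** 2).sum())
        assert d_gpa == pytest.approx(d_opa, abs=1e-6)

    def test_distances_invariant_under_common_rotation(self, two_group_sim):
        arr = two_group_sim.landmarks.as_array()
        fit1 = lm.GeneralizedProcrustes(arr).fit()
        rng = np.random.default_rng(13)
        common = Rotation.random(random_state=42).as_matrix()
        fit2 = lm.GeneralizedProcrustes(arr @ common.T).fit()
        assert np.allclose(
            fit1.distance_matrix(), fit2.distance_matrix(), atol=1e-8
        )

    def test_unit_centroid_sizes_and_centering(self, two_group_fit):
        for shape in two_group_fit.aligned:
            assert centroid_size(shape) == pytest.approx(1.0, abs=1e-9)
            assert np.linalg.norm(shape.mean(axis=0)) < 1e-9

    def test_consensus_is_mean_of_aligned(self, two_group_fit):
        mean = two_group_fit.aligned.mean(axis=0)
        mean = mean - mean.mean(axis=0)
        mean = mean / np.sqrt((mean**2).sum())
        assert np.allclose(mean, two_group_fit.consensus, atol=1e-7)

    def test_consensus_is_fixed_point(self, two_group_fit):
        refit = lm.GeneralizedProcrustes(two_group_fit.aligned).fit()
        assert refit.iterations <= 2
        assert np.allclose(
            refit.distance_matrix(), two_group_fit.distance_matrix(), atol=1e-8
        )

    def test_consensus_optimality(self, two_group_fit):
        """Summed squared distance to consensus beats any random reference."""
        rng = np.random.default_rng(17)
        flat = two_group_fit.flattened()
        cons = two_group_fit.consensus.ravel()
        ss_cons = np.sum((flat - cons) ** 2)
        for _ in range(10):
            ref = rng.normal(size=cons.shape)
            ref = ref.reshape(-1, 3)
            ref = ref - ref.mean(0)
            ref = (ref / np.sqrt((ref**2).sum())).ravel()
            assert ss_cons <= np.sum((flat - ref) ** 2) + 1e-12

    def test_centroid_sizes_recorded_in_mm(self, two_group_sim, two_group_fit):
        # drawn sizes are recovered up to the small noise-induced inflation
        assert np.allclose(
            two_group_fit.centroid_sizes, two_group_sim.sizes, rtol=0.05
        )

    def test_rotate_to_preserves_distances(self, two_group_fit, template):
        rotated = two_group_fit.rotate_to(template.coordinates)
        assert np.allclose(
            rotated.distance_matrix(), two_group_fit.distance_matrix(), atol=1e-10
        )

    def test_needs_two_configurations(self, template):
        with pytest.raises(ValueError):
            lm.GeneralizedProcrustes(template.coordinates[None])

    def test_procrustes_distance_metric_properties(self, two_group_fit):
        rng = np.random.default_rng(23)
        n = two_group_fit.n_specimens
        for _ in range(20):
            i, j, k = rng.integers(0, n, 3)
            a, b, c = (two_group_fit.aligned[x] for x in (i, j, k))
            assert procrustes_distance(a, b) == pytest.approx(
                procrustes_distance(b, a), abs=1e-12
            )
            assert procrustes_distance(a, c) <= (
                procrustes_distance(a, b) + procrustes_distance(b, c) + 1e-12
            )
        assert procrustes_distance(
            two_group_fit.aligned[0], two_group_fit.aligned[0]
        ) == 0.0
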