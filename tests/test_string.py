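"""String method: mean forces, reparametrization, evolution, projection."""

import numpy as np
import pytest

from pathsage.sampling import LangevinParams
from pathsage.string import (
    StringParams,
    StringPath,
    estimate_mean_force,
    evolve_string,
    project_progress,
    reparametrize,
)
from pathsage.systems import flat_system, quadratic_system


class TestStringPath:
    def test_arc_fractions_normalized_and_increasing(self):
        path = StringPath.from_images([[0, 0], [1, 0], [3, 0]])
        assert path.arc_fractions[0] == 0.0
        assert path.arc_fractions[-1] == 1.0
        assert np.all(np.diff(path.arc_fractions) > 0)
        np.testing.assert_allclose(path.arc_fractions, [0, 1 / 3, 1])

    def test_text_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        path = StringPath.from_images(rng.standard_normal((7, 2)), iteration=42)
        fname = tmp_path / "path.txt"
        path.save(fname)
        back = StringPath.load(fname)
        np.testing.assert_array_equal(back.images, path.images)
        np.testing.assert_array_equal(back.arc_fractions, path.arc_fractions)
        assert back.iteration == 42

    def test_degenerate_images_rejected(self):
        with pytest.raises(ValueError):
            StringPath.from_images(np.zeros((5, 2)))

    def test_resample_preserves_endpoints(self):
        path = StringPath.from_images([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
        fine = path.resample(11)
        np.testing.assert_allclose(fine.images[0], [0, 0])
        np.testing.assert_allclose(fine.images[-1], [2, 0])
        assert fine.n_images == 11


class TestReparametrize:
    def test_uneven_straight_line(self):
        path = StringPath.from_images([[0.0, 0.0], [0.9, 0.0], [1.0, 0.0]])
        out = reparametrize(path)
        np.testing.assert_allclose(
            out.images, [[0, 0], [0.5, 0], [1, 0]], atol=1e-12
        )

    def test_idempotent_on_equal_spacing(self):
        path = StringPath.from_images(np.linspace([0, 0], [1, 2], 9))
        once = reparametrize(path)
        twice = reparametrize(once)
        np.testing.assert_allclose(once.images, path.images, atol=1e-12)
        np.testing.assert_allclose(twice.images, once.images, atol=1e-10)

    def test_semicircle_equal_spacing_along_polyline(self):
        # 9 unevenly placed points on a semicircle; after redistribution the
        # points sit at equal distance measured along the original polyline
        t = np.sort(np.random.default_rng(5).uniform(0, np.pi, 7))
        t = np.concatenate([[0.0], t, [np.pi]])
        pts = np.stack([np.cos(t), np.sin(t)], axis=1)
        out = reparametrize(StringPath.from_images(pts))

        # oracle: dense scan of the original polyline
        seg = np.diff(pts, axis=0)
        lens = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0], np.cumsum(lens)])
        dense_s = np.linspace(0, cum[-1], 200001)
        dense = np.stack(
            [np.interp(dense_s, cum, pts[:, d]) for d in range(2)], axis=1
        )
        # position of each redistributed point along the original polyline
        arcs = []
        for p in out.images:
            arcs.append(dense_s[np.argmin(np.linalg.norm(dense - p, axis=1))])
        arcs = np.array(arcs)
        np.testing.assert_allclose(np.diff(arcs), cum[-1] / 8, atol=1e-4)
        # total span preserved
        assert arcs[-1] - arcs[0] == pytest.approx(cum[-1], abs=1e-8)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            reparametrize(StringPath(images=np.zeros((3, 2)),
                                     arc_fractions=np.array([0, 0.5, 1.0])))


class TestEstimateMeanForce:
    def test_quadratic_closed_form(self):
        # V=(k/2)x^2, k=1, kappa=100, z=1: grad A = kappa k z/(k+kappa) = 0.990
        system = quadratic_system(1.0)
        sampling = LangevinParams(dt=1e-3, n_steps=60_000, seed=21)
        mf, se = estimate_mean_force(system, np.array([1.0]), 100.0, sampling)
        assert abs(mf[0] - 100.0 / 101.0) < 3 * se[0]
        # block SE accounts for serial correlation (~tau = 1/(kappa dt))
        assert 0 < se[0] < 0.5

    def test_zero_at_unbiased_minimum(self):
        system = quadratic_system(2.0)
        sampling = LangevinParams(dt=1e-3, n_steps=60_000, seed=4)
        mf, se = estimate_mean_force(system, np.array([0.0]), 500.0, sampling)
        assert abs(mf[0]) < 3 * se[0]

    def test_zero_on_flat_potential(self):
        system = flat_system(2)
        sampling = LangevinParams(dt=1e-3, n_steps=50_000, seed=9)
        mf, se = estimate_mean_force(system, np.array([0.7, -0.3]), 50.0, sampling)
        assert np.all(np.abs(mf) < 3 * se)

    def test_too_few_samples_rejected(self):
        system = quadratic_system(1.0)
        sampling = LangevinParams(dt=1e-3, n_steps=50, seed=0)
        with pytest.raises(ValueError, match="100"):
            estimate_mean_force(system, np.array([0.0]), 10.0, sampling)


class TestProjectProgress:
    def test_image_points_map_to_their_arc_fraction(self):
        path = StringPath.from_images([[0, 0], [1, 0], [1, 1], [1, 3]])
        for k in range(path.n_images):
            s = project_progress(path.images[k], path)
            assert s == pytest.approx(path.arc_fractions[k], abs=1e-12)

    def test_segment_midpoint(self):
        path = StringPath.from_images([[0.0, 0.0], [2.0, 0.0]])
        assert project_progress([1.0, 0.5], path) == pytest.approx(0.5)

    def test_off_path_point_matches_dense_scan_oracle(self):
        rng = np.random.default_rng(8)
        pts = np.cumsum(rng.uniform(0.2, 1.0, size=(6, 2)), axis=0)
        path = StringPath.from_images(pts)
        theta = pts[2] + np.array([0.05, -0.08])
        s = project_progress(theta, path)
        # oracle: dense sampling of the polyline
        dense_t = np.linspace(0, 1, 500001)
        seg = np.diff(pts, axis=0)
        lens = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0], np.cumsum(lens)]) / lens.sum()
        dense = np.stack(
            [np.interp(dense_t, cum, pts[:, d]) for d in range(2)], axis=1
        )
        s_oracle = dense_t[np.argmin(np.linalg.norm(dense - theta, axis=1))]
        assert s == pytest.approx(s_oracle, abs=1e-4)


class TestEvolveString:
    def test_flat_potential_leaves_reparametrized_path_fixed(self):
        system = flat_system(2)
        init = StringPath.from_images(np.linspace([0, 0], [1, 1], 8))
        params = StringParams(kappa=100.0, step_size=1e-3, n_samples_per_image=500,
                              smoothing=0.0, max_iterations=5, tol=1e-12, seed=3,
                              sampling=LangevinParams(dt=1e-3, kT=0.0))
        path, _ = evolve_string(system, init, params)
        np.testing.assert_allclose(path.images, init.images, atol=1e-9)

    def test_endpoints_pinned_exactly(self):
        system = quadratic_system(1.0, dim=2)
        init = StringPath.from_images(np.linspace([-1, 0.5], [1, 0.5], 6))
        params = StringParams(kappa=200.0, step_size=1e-3, n_samples_per_image=400,
                              max_iterations=10, tol=1e-12, seed=5,
                              sampling=LangevinParams(dt=1e-3))
        path, _ = evolve_string(system, init, params)
        np.testing.assert_array_equal(path.images[0], init.images[0])
        np.testing.assert_array_equal(path.images[-1], init.images[-1])

    def test_separable_quadratic_converges_to_straight_segment(self):
        # the MFEP between two points of an isotropic quadratic basin is the
        # straight segment between them
        system = quadratic_system(1.0, dim=2)
        bent = np.linspace([-1, 0], [1, 0], 9) + np.array([0, 1.0]) * np.sin(
            np.linspace(0, np.pi, 9)
        )[:, None]
        # the transverse bow decays as exp(-step_size * k * iterations)
        params = StringParams(kappa=500.0, step_size=0.05, n_samples_per_image=1500,
                              smoothing=0.0, max_iterations=300, tol=1e-9, seed=2,
                              max_displacement=0.2,
                              sampling=LangevinParams(dt=5e-4, kT=1e-12))
        path, _ = evolve_string(system, StringPath.from_images(bent), params)
        straight = np.linspace([-1, 0], [1, 0], 9)
        assert np.abs(path.images - straight).max() < 1e-3

    def test_zero_temperature_deterministic_relaxation(self):
        """kT=0 sampling turns the update into noiseless path relaxation."""
        system = quadratic_system(1.0, dim=2)
        init = StringPath.from_images(np.linspace([-1, 1], [1, 1], 7))
        params = StringParams(kappa=500.0, step_size=1e-3, n_samples_per_image=300,
                              max_iterations=3, tol=1e-15, seed=1,
                              sampling=LangevinParams(dt=5e-4, kT=0.0))
        p1, _ = evolve_string(system, init, params)
        p2, _ = evolve_string(system, init, params)
        np.testing.assert_array_equal(p1.images, p2.images)

    def test_mueller_brown_string_tracks_mfep(self, converged_mb_string, mfep_oracle):
        """Converged 32-image string lies on the brute-force MFEP."""
        path, history = converged_mb_string
        from scipy.spatial import cKDTree

        d, _ = cKDTree(mfep_oracle).query(path.images)
        assert d.mean() < 0.05

    def test_convergence_metric_decreasing_tail(self, converged_mb_string):
        """Median-filtered displacement is non-increasing over the last half."""
        _, history = converged_mb_string
        disp = history["displacement"]
        half = disp[len(disp) // 2:]
        # median filter width 5 to suppress sampling noise
        med = np.array([np.median(half[max(0, i - 2): i + 3]) for i in range(len(half))])
        # allow tiny non-monotonicity at the noise floor
        assert np.all(np.diff(med) < 5e-5)
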