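"""Umbrella sampling, binless WHAM, and thermodynamic integration."""

import numpy as np
import pytest

from pathsage.free_energy import (
    PMFProfile,
    WindowSamples,
    run_umbrella,
    ti_pmf,
    wham_pmf,
)
from pathsage.sampling import LangevinParams
from pathsage.string import StringPath
from pathsage.systems import double_well_system, flat_system, quadratic_system


def straight_path_1d(lo, hi, k):
    return StringPath.from_images(np.linspace(lo, hi, k)[:, None])


class TestRunUmbrella:
    def test_flat_potential_window_means_at_centers(self):
        system = flat_system(1)
        path = straight_path_1d(-1.0, 1.0, 5)
        lp = LangevinParams(dt=1e-3, n_steps=40_000, seed=2)
        windows = run_umbrella(system, path, kappa=200.0, sampling=lp)
        for w in windows:
            se = w.samples.std() / np.sqrt(200)  # generous correlated-SE bound
            assert abs(w.samples.mean() - w.center[0]) < 3 * se + 5e-3

    def test_quadratic_window_means_shifted_toward_origin(self):
        # V=(k/2)x^2: window at c has mean kappa c/(k+kappa)
        k, kappa = 1.0, 10.0
        system = quadratic_system(k)
        path = straight_path_1d(-1.0, 1.0, 7)
        lp = LangevinParams(dt=5e-3, n_steps=60_000, seed=8)
        windows = run_umbrella(system, path, kappa=kappa, sampling=lp)
        for w in windows:
            expected = kappa * w.center[0] / (k + kappa)
            assert w.samples.mean() == pytest.approx(expected, abs=0.02)

    def test_deterministic_per_seed(self):
        system = quadratic_system(1.0)
        path = straight_path_1d(-1, 1, 4)
        lp = LangevinParams(dt=1e-3, n_steps=5000, seed=3)
        w1 = run_umbrella(system, path, kappa=20.0, sampling=lp)
        w2 = run_umbrella(system, path, kappa=20.0, sampling=lp)
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a.samples, b.samples)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            WindowSamples(0, np.array([0.0]), kappa=-1.0, samples=np.zeros((5, 1)))
        with pytest.raises(ValueError):
            WindowSamples(0, np.array([0.0]), kappa=1.0,
                          samples=np.array([[np.nan]]))


class TestWhamPmf:
    def test_near_unbiased_windows_recover_double_well(self):
        """With negligible bias the pooled samples reproduce V directly.

        The 2 kT barrier keeps the hopping rate high enough that both wells
        equilibrate within the run (well-to-well balance error scales as
        1/sqrt(number of barrier crossings)).
        """
        system = double_well_system(2.0)
        path = straight_path_1d(-1.6, 1.6, 2)
        lp = LangevinParams(dt=1e-3, n_steps=400_000, seed=13)
        # two effectively unbiased windows (kappa ~ 0) started in each well
        windows = run_umbrella(system, path, kappa=1e-9, sampling=lp, thin=2)
        prof = wham_pmf(windows, path, kT=1.0, n_bins=32)
        x = -1.6 + 3.2 * prof.grid
        v = system.energy(x[:, None])
        ok = np.isfinite(prof.values)
        assert ok.sum() > 20
        rms = np.sqrt(np.mean((prof.values[ok] - (v[ok] - v[ok].min())) ** 2))
        assert rms < 0.2

    def test_identical_windows_get_identical_free_energies(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(0.0, 0.5, size=(600, 1))
        w1 = WindowSamples(0, np.array([0.0]), kappa=2.0, samples=samples)
        w2 = WindowSamples(1, np.array([0.0]), kappa=2.0, samples=samples)
        path = straight_path_1d(-1, 1, 3)
        prof = wham_pmf([w1, w2], path, kT=1.0, n_bins=8)
        f = prof.window_free_energies
        assert f[0] == pytest.approx(f[1], abs=1e-10)

    def test_quadratic_curvature_recovered(self):
        k = 2.0
        system = quadratic_system(k)
        path = straight_path_1d(-1.2, 1.2, 13)
        lp = LangevinParams(dt=1e-3, n_steps=40_000, seed=5)
        windows = run_umbrella(system, path, kappa=30.0, sampling=lp, thin=2)
        prof = wham_pmf(windows, path, kT=1.0, n_bins=25)
        x = -1.2 + 2.4 * prof.grid
        ok = np.isfinite(prof.values) & (np.abs(x) < 0.9)
        coef = np.polyfit(x[ok], prof.values[ok], 2)
        assert coef[0] * 2 == pytest.approx(k, rel=0.1)

    def test_minimum_anchored_at_zero(self):
        system = double_well_system(2.0)
        path = straight_path_1d(-1.3, 1.3, 9)
        lp = LangevinParams(dt=5e-4, n_steps=20_000, seed=1)
        windows = run_umbrella(system, path, kappa=30.0, sampling=lp)
        prof = wham_pmf(windows, path, n_bins=18)
        assert np.nanmin(prof.values) == pytest.approx(0.0, abs=1e-12)

    def test_precondition_errors(self):
        path = straight_path_1d(-1, 1, 3)
        w = WindowSamples(0, np.array([0.0]), kappa=1.0,
                          samples=np.zeros((600, 1)))
        small = WindowSamples(0, np.array([0.0]), kappa=1.0,
                              samples=np.zeros((100, 1)))
        with pytest.raises(ValueError):
            wham_pmf([w], path)          # a single window is not combinable
        with pytest.raises(ValueError):
            wham_pmf([small, small], path)  # fewer than 1000 pooled samples

    def test_profile_text_round_trip(self, tmp_path):
        prof = PMFProfile(
            grid=np.linspace(0, 1, 5),
            values=np.array([0.0, 1.5, np.nan, 0.7, 2.0]),
            window_free_energies=np.array([0.0, -1.2]),
            converged=True,
            n_iterations=17,
        )
        fname = tmp_path / "pmf.txt"
        prof.save(fname)
        back = PMFProfile.from_text(fname.read_text())
        np.testing.assert_array_equal(back.grid, prof.grid)
        np.testing.assert_array_equal(back.values, prof.values)
        np.testing.assert_array_equal(back.window_free_energies,
                                      prof.window_free_energies)
        assert back.converged and back.n_iterations == 17


class TestTiPmf:
    def test_zero_forces_give_flat_profile(self):
        path = straight_path_1d(0, 1, 6)
        prof = ti_pmf(flat_system(1), path, np.zeros((6, 1)))
        np.testing.assert_allclose(prof, 0.0, atol=1e-15)

    def test_quadratic_exact_line_integral(self):
        # exact gradients kx along a fine straight path from 0 to 1: A(1) = k/2
        k = 3.0
        system = quadratic_system(k)
        path = straight_path_1d(0.0, 1.0, 2001)
        forces = k * path.images
        prof = ti_pmf(system, path, forces)
        assert prof[-1] == pytest.approx(k / 2, abs=1e-6)

    def test_double_well_barrier_from_exact_gradients(self):
        h = 4.0
        system = double_well_system(h)
        path = straight_path_1d(-1.0, 0.0, 4001)
        forces = system.gradient(path.images)
        prof = ti_pmf(system, path, forces)
        assert prof[-1] == pytest.approx(h, abs=1e-4)

    def test_length_mismatch_rejected(self):
        path = straight_path_1d(0, 1, 5)
        with pytest.raises(ValueError):
            ti_pmf(flat_system(1), path, np.zeros((4, 1)))


def test_doubling_samples_is_consistent_within_bootstrap_error():
    """A(s) from n and 2n samples agree within ~3x the bootstrap SE."""
    system = double_well_system(2.0)
    path = straight_path_1d(-1.3, 1.3, 9)
    # thin to roughly the correlation time so the iid bootstrap is honest
    lp1 = LangevinParams(dt=2e-3, n_steps=60_000, seed=31)
    lp2 = LangevinParams(dt=2e-3, n_steps=120_000, seed=32)
    w1 = run_umbrella(system, path, kappa=30.0, sampling=lp1, thin=15)
    w2 = run_umbrella(system, path, kappa=30.0, sampling=lp2, thin=15)
    p1 = wham_pmf(w1, path, n_bins=12)
    p2 = wham_pmf(w2, path, n_bins=12)

    # free energies are defined up to a constant; align on the common mean
    # over populated bins so the min-anchoring offset does not masquerade
    # as a per-bin difference
    ok = np.isfinite(p1.values) & np.isfinite(p2.values)

    def aligned(values):
        return values - np.mean(values[ok])

    # bootstrap over samples of the smaller run (50 resamples)
    rng = np.random.default_rng(0)
    boots = []
    for _ in range(50):
        res = []
        for w in w1:
            idx = rng.integers(0, w.n, size=w.n)
            res.append(WindowSamples(w.window_index, w.center, w.kappa,
                                     w.samples[idx]))
        boots.append(aligned(wham_pmf(res, path, n_bins=12, tol=1e-6).values))
    boots = np.array(boots)
    se = np.nanstd(boots, axis=0)
    good = ok & (se > 0)
    diff = np.abs(aligned(p1.values)[good] - aligned(p2.values)[good])
    assert np.all(diff < 3 * se[good] + 0.05)
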