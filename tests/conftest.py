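"""Shared fixtures and independent oracles.

The oracles here are deliberately primitive (grid searches, dense scans,
steepest-descent tracing) and never reuse the code paths they validate.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import minimum_filter
from scipy.optimize import minimize

from pathsage.systems import mueller_brown, mueller_brown_system


def mb_hessian(p, eps=1e-5):
    sys_ = mueller_brown_system()
    H = np.zeros((2, 2))
    for i in range(2):
        e = np.zeros(2)
        e[i] = eps
        H[:, i] = (sys_.gradient(p + e) - sys_.gradient(p - e)) / (2 * eps)
    return 0.5 * (H + H.T)


def find_mb_stationary_points():
    """Grid search + local refinement for all stationary points of the
    Mueller-Brown surface; classified by the Hessian."""
    sys_ = mueller_brown_system()
    n = 600
    xs = np.linspace(-1.8, 1.2, n)
    ys = np.linspace(-0.5, 2.2, n)
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    G = sys_.gradient(np.stack([XX, YY], axis=-1))
    gn = np.linalg.norm(G, axis=-1)
    loc = gn == minimum_filter(gn, size=7)
    pts = np.stack([XX[loc], YY[loc]], axis=-1)

    def gsq(q):
        return (sys_.gradient(q) ** 2).sum()

    found = []
    for p in pts:
        r = minimize(gsq, p, method="Nelder-Mead",
                     options=dict(xatol=1e-12, fatol=1e-16, maxiter=5000))
        if r.fun < 1e-10 and not any(np.linalg.norm(r.x - u) < 1e-3 for u, _ in found):
            ev = np.linalg.eigvalsh(mb_hessian(r.x))
            kind = "saddle" if ev[0] < 0 < ev[1] else ("min" if ev[0] > 0 else "max")
            found.append((r.x, kind))
    return found


def trace_mfep(step=2e-4, max_iter=400_000):
    """Steepest-descent paths from every saddle, both directions: the
    brute-force minimum free-energy path of the Mueller-Brown surface."""
    sys_ = mueller_brown_system()
    segments = []
    for sdl, kind in find_mb_stationary_points():
        if kind != "saddle":
            continue
        ev, evec = np.linalg.eigh(mb_hessian(sdl))
        v = evec[:, 0]  # unstable direction
        for sign in (1, -1):
            p = sdl + sign * 1e-3 * v
            pts = [p.copy()]
            for _ in range(max_iter):
                g = sys_.gradient(p)
                ng = np.linalg.norm(g)
                if ng < 1e-6:
                    break
                p = p - step * g / max(ng, 1.0)
                pts.append(p.copy())
            segments.append(np.array(pts))
    return np.vstack(segments)


@pytest.fixture(scope="session")
def mfep_oracle():
    return trace_mfep()


@pytest.fixture(scope="session")
def mb_minima():
    mins = {}
    for p, kind in find_mb_stationary_points():
        if kind == "min":
            mins[round(float(mueller_brown(p)), 2)] = p
    # deep minimum (~ -146.70), middle (~ -80.77), second deep (~ -108.17)
    vals = sorted(mins)
    return {"deep": mins[vals[0]], "second": mins[vals[1]], "middle": mins[vals[2]]}


@pytest.fixture(scope="session")
def converged_mb_string(mb_minima):
    """The 32-image Mueller-Brown string used by the path and PMF checks."""
    from pathsage.sampling import LangevinParams, tmd_path
    from pathsage.string import StringParams, evolve_string

    sys_ = mueller_brown_system()
    lp = LangevinParams(dt=1e-4, n_steps=20000, seed=1)
    init = tmd_path(sys_, mb_minima["deep"], mb_minima["second"],
                    schedule_steps=20000, n_images=32, params=lp, kappa=2000.0)
    params = StringParams(
        kappa=5000.0, step_size=2e-4, n_samples_per_image=2000, smoothing=0.1,
        max_iterations=300, tol=2e-4, seed=7, max_displacement=0.01,
        sampling=LangevinParams(dt=1e-4, seed=0),
    )
    path, history = evolve_string(sys_, init, params)
    return path, history
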