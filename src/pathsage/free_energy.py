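"""Umbrella sampling and free-energy profile estimation along a string.

One harmonic umbrella window is run per string image.  The windows are
combined with a *binless* self-consistent estimator (MBAR-style): the
per-window free energies f_k solve

    f_k = -kT ln sum_n exp(-u_k(x_n)/kT) / sum_m N_m exp((f_m - u_m(x_n))/kT)

over the pooled samples x_n with biases u_k(x) = (kappa/2)|x - z_k|^2.
Unbiased sample weights follow as w_n = 1 / sum_m N_m exp((f_m - u_m(x_n))/kT),
and the potential of mean force along the path progress coordinate s (the
orthogonal projection onto the string polyline) is

    A(s_b) = -kT ln sum_{n in bin b} w_n,    shifted so min A = 0.

Binning happens only at this final projection step; the bias lives in the
full CV space.  The self-consistent equations are solved by a short warm-up
of direct iteration followed by Newton-Raphson on the (convex)
pooled-likelihood stationarity conditions; convergence is certified by the
self-consistency residual max|delta f_k| < tol.

A thermodynamic-integration cross-check (`ti_pmf`) integrates string-method
mean forces along the path with the trapezoid rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .sampling import LangevinParams, _simulate_batch
from .string import StringPath, project_progress_batch
from .systems import CVSystem

__all__ = ["WindowSamples", "PMFProfile", "run_umbrella", "wham_pmf", "ti_pmf"]

log = logging.getLogger(__name__)


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    """Plain max-shifted logsumexp (hot path: K x N matrices)."""
    m = np.max(a, axis=axis, keepdims=True)
    out = np.exp(a - m).sum(axis=axis, keepdims=True)
    np.log(out, out=out)
    out += m
    return np.squeeze(out, axis=axis)


@dataclass
class WindowSamples:
    """Post-burn-in samples of one umbrella window."""

    window_index: int
    center: np.ndarray
    kappa: float
    samples: np.ndarray  # (n_k, dim)

    def __post_init__(self) -> None:
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.samples.shape[0] < 1:
            raise ValueError("window has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples in window")

    @property
    def n(self) -> int:
        return self.samples.shape[0]


@dataclass
class PMFProfile:
    """A free-energy profile along the path progress coordinate, in kT.

    Empty bins carry NaN ("missing"), never an interpolated value.
    """

    grid: np.ndarray                   # bin centers s_b in [0, 1]
    values: np.ndarray                 # A(s_b), min over populated bins = 0
    window_free_energies: np.ndarray   # f_k
    converged: bool
    n_iterations: int

    def to_text(self) -> str:
        lines = [
            f"# pathsage PMF  n_bins={len(self.grid)} converged={self.converged} "
            f"n_iterations={self.n_iterations}",
            "# f_k: " + " ".join(repr(float(f)) for f in self.window_free_energies),
            "# columns: s  A_kT",
        ]
        for s, a in zip(self.grid, self.values):
            lines.append(f"{float(s)!r} {float(a)!r}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "PMFProfile":
        fk = np.array([])
        converged, n_iter = False, 0
        rows = []
        for ln in text.splitlines():
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith("#"):
                if "converged=" in ln:
                    converged = "converged=True" in ln
                    n_iter = int(ln.split("n_iterations=")[1].split()[0])
                if ln.startswith("# f_k:"):
                    fk = np.array([float(t) for t in ln.split(":", 1)[1].split()])
                continue
            s, a = ln.split()
            rows.append((float(s), float(a)))
        grid = np.array([r[0] for r in rows])
        values = np.array([r[1] for r in rows])
        return cls(grid=grid, values=values, window_free_energies=fk,
                   converged=converged, n_iterations=n_iter)


def run_umbrella(
    system: CVSystem,
    path: StringPath,
    kappa: float,
    sampling: LangevinParams,
    thin: int = 1,
) -> List[WindowSamples]:
    """Run one umbrella window per string image.

    Window k is initialized at image z_k with bias (kappa/2)|theta - z_k|^2
    and seed ``sampling.seed + k``; the leading ``burn_in_fraction`` of each
    window is discarded.  Deterministic per seed.  ``thin`` keeps every
    thin-th retained sample — cheap decorrelation for the estimator, since
    consecutive Langevin steps are strongly correlated anyway.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    K = path.n_images
    seeds = [sampling.seed + k for k in range(K)]
    traj = _simulate_batch(system, path.images, path.images, kappa, sampling, seeds=seeds)
    skip = int(round(sampling.burn_in_fraction * sampling.n_steps))
    return [
        WindowSamples(window_index=k, center=path.images[k], kappa=kappa,
                      samples=traj[k, skip::thin, :])
        for k in range(K)
    ]


def _solve_window_free_energies(
    u_over_kt: np.ndarray,       # (K, N) reduced bias energies
    counts: np.ndarray,          # (K,)
    tol: float,
    max_iter: int,
):
    """Solve the self-consistent equations for the reduced f_k.

    Short direct-iteration warm-up, then Newton-Raphson on the pooled
    log-likelihood stationarity conditions (gauge f_0 = 0); each Newton
    step is followed by one direct sweep whose residual max|delta f| < tol
    certifies convergence.

    The K x N workspaces are reused in place and drop to float32 once the
    pooled matrix gets large (the f_k carry statistical errors orders of
    magnitude above float32 resolution, and these matrices dominate the
    memory cost); the convergence tolerance is then floored at the float32
    self-consistency resolution.
    """
    K, N = u_over_kt.shape
    log_counts = np.log(counts)
    dtype = np.float64 if K * N <= 2e7 else np.float32
    if dtype is np.float32:
        tol = max(tol, 2e-6)
    u32 = np.ascontiguousarray(u_over_kt, dtype=dtype)
    buf = np.empty_like(u32)

    def log_denominators(f):
        # log sum_m exp(log N_m + f_m - u_mn), in-place over buf
        np.subtract((log_counts + f)[:, None].astype(dtype), u32, out=buf)
        m = buf.max(axis=0)
        np.subtract(buf, m[None, :], out=buf)
        np.exp(buf, out=buf)
        s = buf.sum(axis=0, dtype=np.float64)
        return np.log(s) + m

    def sc_update(f):
        log_denom = log_denominators(f)
        np.add(u32, log_denom[None, :].astype(dtype), out=buf)
        np.negative(buf, out=buf)
        m = buf.max(axis=1)
        np.subtract(buf, m[:, None], out=buf)
        np.exp(buf, out=buf)
        f_new = -(np.log(buf.sum(axis=1, dtype=np.float64)) + m)
        return f_new - f_new[0], log_denom

    f = np.zeros(K)
    converged = False
    it = 0
    while it < max_iter:
        # a few self-consistent sweeps to get into the Newton basin
        for _ in range(5):
            it += 1
            f_new, _ = sc_update(f)
            delta = np.max(np.abs(f_new - f))
            f = f_new
            if delta < tol:
                converged = True
                break
        if converged:
            break
        # Newton-Raphson on the (convex) pooled-likelihood equations
        for _ in range(30):
            it += 1
            log_denom = log_denominators(f)
            # p_kn = N_k exp(f_k - u_kn) / denom_n, built in place
            np.subtract((log_counts + f)[:, None].astype(dtype), u32, out=buf)
            np.subtract(buf, log_denom[None, :].astype(dtype), out=buf)
            np.exp(buf, out=buf)
            rowsum = buf.sum(axis=1, dtype=np.float64)
            grad = rowsum - counts
            H = np.diag(rowsum) - (buf @ buf.T).astype(np.float64)
            # fix the gauge f_0 = 0 by solving in the remaining coordinates
            try:
                step = np.linalg.solve(H[1:, 1:], -grad[1:])
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(step)):
                break
            f = f + np.concatenate([[0.0], np.clip(step, -50.0, 50.0)])
            f_new, _ = sc_update(f)
            delta = np.max(np.abs(f_new - f))
            f = f_new
            it += 1
            if delta < tol:
                converged = True
                break
        if converged or it >= max_iter:
            break
    _, log_denom = sc_update(f)
    return f, log_denom, converged, it


def wham_pmf(
    windows: Sequence[WindowSamples],
    path: StringPath,
    kT: float = 1.0,
    n_bins: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    tube_confined: bool = True,
) -> PMFProfile:
    """Binless self-consistent PMF along the path progress coordinate.

    With ``tube_confined`` (default) the reported profile is that of the
    ensemble harmonically confined to the path tube: each sample weight
    carries an extra factor exp(-kappa y^2 / 2kT), y its transverse
    distance from the path polyline.  Without it, samples at the tube edge
    receive weights ~ exp(+kappa y^2 / 2kT) — the transverse tails are
    never sampled, so the "fully unbiased" projected profile has diverging
    variance in more than one CV dimension.  For stiff tubes the confined
    profile equals the potential along the path up to a constant, which is
    exactly what the thermodynamic-integration cross-check measures; for a
    1D identity CV the factor is 1 inside the path's span and merely
    suppresses the out-of-range endpoint pile-up.
    """
    if len(windows) < 2:
        raise ValueError("need at least 2 windows")
    total = sum(w.n for w in windows)
    if total < 1000:
        raise ValueError(f"need >= 1000 pooled samples, got {total}")
    if n_bins is None:
        n_bins = path.n_images

    X = np.vstack([w.samples for w in windows])          # (N, dim)
    counts = np.array([w.n for w in windows], dtype=float)
    centers = np.stack([w.center for w in windows])      # (K, dim)
    kappas = np.array([w.kappa for w in windows])

    # reduced bias energies u_k(x_n)/kT, built window-row by window-row
    N = X.shape[0]
    u_dtype = np.float64 if len(windows) * N <= 2e7 else np.float32
    u = np.empty((len(windows), N), dtype=u_dtype)
    for k in range(len(windows)):
        diff = X - centers[k]
        u[k] = 0.5 * kappas[k] * (diff * diff).sum(axis=1) / kT

    f, log_denom, converged, n_iter = _solve_window_free_energies(
        u, counts, tol=tol / kT, max_iter=max_iter
    )
    if not converged:
        log.warning("window free energies not converged after %d iterations", n_iter)

    log_w = -log_denom                                   # unnormalized ln w_n

    s, y, interior = project_progress_batch(X, path, return_distances=True)
    if tube_confined:
        log_w = log_w - 0.5 * np.mean(kappas) * y**2 / kT
    # points beyond the path ends have no orthogonal projection; counting
    # them would pool a half-space of weight into the terminal bins
    s, log_w = s[interior], log_w[interior]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(s, edges) - 1, 0, n_bins - 1)
    values = np.full(n_bins, np.nan)
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            values[b] = -kT * _logsumexp(log_w[mask], axis=0)
    finite = np.isfinite(values)
    values[finite] -= np.nanmin(values[finite])
    return PMFProfile(
        grid=0.5 * (edges[:-1] + edges[1:]),
        values=values,
        window_free_energies=kT * f,
        converged=converged,
        n_iterations=n_iter,
    )


def ti_pmf(
    system: CVSystem,
    path: StringPath,
    mean_forces: Sequence[np.ndarray],
) -> np.ndarray:
    """Trapezoidal thermodynamic integration of mean forces along the path.

    Returns A(z_k) at each image (kT), anchored so min A = 0:
    A(z_k) - A(z_1) = sum_{j<k} (1/2)(gradA_j + gradA_{j+1}) . (z_{j+1} - z_j).
    """
    mf = np.asarray(mean_forces, dtype=float)
    if mf.shape[0] != path.n_images:
        raise ValueError(
            f"{mf.shape[0]} mean-force vectors for {path.n_images} images"
        )
    dz = np.diff(path.images, axis=0)
    increments = 0.5 * ((mf[:-1] + mf[1:]) * dz).sum(axis=1)
    profile = np.concatenate([[0.0], np.cumsum(increments)])
    return profile - profile.min()
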