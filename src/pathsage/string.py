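"""Mean-force string method in collective-variable space.

A transition path is discretized as a *string* of K images z_1..z_K.  Each
iteration (i) estimates the free-energy gradient (mean force) at every
image from restrained sampling, (ii) moves each image downhill by a small
step, (iii) optionally smooths the string, and (iv) redistributes the
images at equal arc length.  At convergence the component of the mean
force perpendicular to the string vanishes, i.e. the string traces a
minimum free-energy path between its (by default fixed) endpoints.

The mean force at image z is estimated from samples theta of the
harmonically restrained ensemble as

    grad A(z)  ~=  kappa * (z - <theta>),

the standard restrained-ensemble estimator: for stiff springs the
restrained average displacement is proportional to the local free-energy
gradient.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

from .sampling import LangevinParams, Restraint, _simulate_batch, sample_restrained
from .systems import CVSystem

__all__ = [
    "StringPath",
    "StringParams",
    "estimate_mean_force",
    "reparametrize",
    "evolve_string",
    "project_progress",
]


@dataclass
class StringPath:
    """An ordered set of CV-space images with arc-length bookkeeping."""

    images: np.ndarray           # (K, dim)
    arc_fractions: np.ndarray    # (K,), s_1 = 0, s_K = 1, strictly increasing
    iteration: int = 0

    @classmethod
    def from_images(cls, images: np.ndarray, iteration: int = 0) -> "StringPath":
        images = np.asarray(images, dtype=float)
        if images.ndim != 2 or images.shape[0] < 2:
            raise ValueError("images must be a (K>=2, dim) array")
        seg = np.linalg.norm(np.diff(images, axis=0), axis=1)
        total = seg.sum()
        if total == 0:
            raise ValueError("all images coincide: zero path length")
        s = np.concatenate([[0.0], np.cumsum(seg)]) / total
        return cls(images=images, arc_fractions=s, iteration=iteration)

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    @property
    def dim(self) -> int:
        return self.images.shape[1]

    @property
    def length(self) -> float:
        """Total polyline length in CV units."""
        return float(np.linalg.norm(np.diff(self.images, axis=0), axis=1).sum())

    def resample(self, n_images: int) -> "StringPath":
        """Interpolate the polyline to ``n_images`` equal-arc-length images."""
        seg = np.linalg.norm(np.diff(self.images, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        targets = np.linspace(0.0, s[-1], n_images)
        new = np.stack(
            [np.interp(targets, s, self.images[:, d]) for d in range(self.dim)],
            axis=1,
        )
        out = StringPath.from_images(new, iteration=self.iteration)
        out.arc_fractions = np.linspace(0.0, 1.0, n_images)
        return out

    # -- plain-text round trip ------------------------------------------

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"# pathsage string path  K={self.n_images} dim={self.dim} "
                  f"iteration={self.iteration}\n")
        buf.write("# arc_fractions: " + " ".join(repr(float(s)) for s in self.arc_fractions) + "\n")
        for row in self.images:
            buf.write(" ".join(repr(float(v)) for v in row) + "\n")
        return buf.getvalue()

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "StringPath":
        lines = text.splitlines()
        iteration = 0
        arc = None
        rows = []
        for ln in lines:
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith("#"):
                if "iteration=" in ln:
                    iteration = int(ln.split("iteration=")[1].split()[0])
                if ln.startswith("# arc_fractions:"):
                    arc = np.array([float(t) for t in ln.split(":", 1)[1].split()])
                continue
            rows.append([float(t) for t in ln.split()])
        images = np.array(rows, dtype=float)
        path = cls.from_images(images, iteration=iteration)
        if arc is not None and arc.shape == path.arc_fractions.shape:
            path.arc_fractions = arc
        return path

    @classmethod
    def load(cls, path) -> "StringPath":
        with open(path) as fh:
            return cls.from_text(fh.read())


@dataclass(frozen=True)
class StringParams:
    """Knobs of the string iteration.

    ``kappa`` is the restraint strength used for mean-force sampling;
    ``step_size`` the image-update step h; ``smoothing`` the coefficient of
    the discrete-Laplacian smoothing term applied before reparametrization.
    ``max_displacement`` caps the per-image move per iteration (trust-region
    style): steep-wall images then relax without overshooting while images
    in soft directions keep making progress.

    Two stiffness conditions matter in practice: ``kappa`` should exceed
    the largest Hessian eigenvalue of the landscape (otherwise the mean
    force is the gradient of a Moreau-envelope-smoothed surface whose
    minimum free-energy path can differ), and ``step_size`` times that
    eigenvalue should stay below 1 for non-oscillatory relaxation.
    """

    kappa: float = 100.0
    step_size: float = 1e-3
    n_samples_per_image: int = 2000
    smoothing: float = 0.1
    fix_endpoints: bool = True
    max_iterations: int = 100
    tol: float = 1e-3
    seed: int = 0
    max_displacement: float = 0.02
    sampling: LangevinParams = field(default_factory=LangevinParams)

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not 0 <= self.smoothing < 0.5:
            raise ValueError("smoothing must be in [0, 0.5)")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


def estimate_mean_force(
    system: CVSystem,
    image: np.ndarray,
    kappa: float,
    sampling: LangevinParams,
) -> Tuple[np.ndarray, np.ndarray]:
    """Estimate grad A at ``image`` from restrained sampling.

    Returns ``(mean_force, standard_error)``, each of shape ``(dim,)``.
    The standard error is computed by block averaging (20 blocks), which
    accounts for the serial correlation of the Langevin chain.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    image = np.atleast_1d(np.asarray(image, dtype=float))
    samples = sample_restrained(system, Restraint(center=image, kappa=kappa), sampling)
    if samples.shape[0] < 100:
        raise ValueError(
            f"only {samples.shape[0]} post-burn-in samples; need >= 100 for a mean-force estimate"
        )
    mf = kappa * (image - samples.mean(axis=0))
    n_blocks = 20
    usable = (samples.shape[0] // n_blocks) * n_blocks
    blocks = samples[:usable].reshape(n_blocks, -1, samples.shape[1]).mean(axis=1)
    se = kappa * blocks.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    return mf, se


def reparametrize(path: StringPath) -> StringPath:
    """Redistribute images at equal arc length along the current polyline.

    Piecewise-linear interpolation along the existing polyline; the
    endpoints are untouched, and the redistributed points sit at exactly
    equal spacing measured along the original polyline.
    """
    if path.n_images < 3:
        raise ValueError("need at least 3 images to reparametrize")
    images = path.images
    seg = np.linalg.norm(np.diff(images, axis=0), axis=1)
    total = seg.sum()
    if total == 0:
        raise ValueError("zero total path length")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, path.n_images)
    new = np.empty_like(images)
    for d in range(path.dim):
        new[:, d] = np.interp(targets, s, images[:, d])
    new[0] = images[0]
    new[-1] = images[-1]
    out = StringPath.from_images(new, iteration=path.iteration)
    # by construction, uniform fractions
    out.arc_fractions = np.linspace(0.0, 1.0, path.n_images)
    return out


def _batch_mean_forces(
    system: CVSystem,
    images: np.ndarray,
    kappa: float,
    sampling: LangevinParams,
    seeds: np.ndarray,
) -> np.ndarray:
    """Mean forces at all images at once (one restrained chain per image)."""
    means = _simulate_batch(system, images, images, kappa, sampling,
                            seeds=list(seeds), record="mean")
    return kappa * (images - means)


def mean_forces_along_path(
    system: CVSystem,
    path: StringPath,
    kappa: float,
    sampling: LangevinParams,
) -> np.ndarray:
    """Restrained mean-force estimates at every image of ``path``.

    One chain per image, seeded ``sampling.seed + k``; returns ``(K, dim)``.
    Useful as input to thermodynamic integration: the stiffer ``kappa``,
    the closer the estimate is to the bare free-energy gradient (the
    systematic error scales as |grad A|^2 / kappa).
    """
    seeds = np.asarray([sampling.seed + k for k in range(path.n_images)])
    return _batch_mean_forces(system, path.images, kappa, sampling, seeds)


def evolve_string(
    system: CVSystem,
    initial: StringPath,
    params: StringParams,
):
    """Relax a string toward a minimum free-energy path.

    Returns ``(path, history)`` where ``history`` is a dict with keys
    ``displacement`` (per-iteration normalized RMS image displacement),
    ``converged`` and ``n_iterations``.  Non-convergence within
    ``max_iterations`` is flagged, not raised.
    """
    if initial.n_images < 3:
        raise ValueError("need at least 3 images")
    images = np.array(initial.images, dtype=float)
    if np.allclose(np.ptp(images, axis=0), 0):
        raise ValueError("initial images are all coincident")

    # n_samples_per_image counts post-burn-in samples
    n_steps = int(np.ceil(max(params.n_samples_per_image, 125)
                          / (1.0 - params.sampling.burn_in_fraction)))
    sampling = replace(params.sampling, n_steps=n_steps)
    root = np.random.default_rng(params.seed)
    K = images.shape[0]

    history = []
    converged = False
    it = 0
    for it in range(1, params.max_iterations + 1):
        seeds = root.integers(0, 2**31 - 1, size=K)
        mf = _batch_mean_forces(system, images, params.kappa, sampling, seeds)
        if not np.all(np.isfinite(mf)):
            raise RuntimeError(f"non-finite mean force at iteration {it}")

        prev = images.copy()
        dz = -params.step_size * mf
        if params.max_displacement is not None:
            nrm = np.linalg.norm(dz, axis=1, keepdims=True)
            dz *= np.minimum(1.0, params.max_displacement / np.maximum(nrm, 1e-300))
        upd = images + dz
        if params.fix_endpoints:
            upd[0] = images[0]
            upd[-1] = images[-1]
        if params.smoothing > 0:
            sm = upd.copy()
            sm[1:-1] += params.smoothing * (upd[2:] - 2.0 * upd[1:-1] + upd[:-2])
            upd = sm
        path = reparametrize(StringPath.from_images(upd, iteration=it))
        images = path.images
        if not np.all(np.isfinite(images)):
            raise RuntimeError(f"non-finite image at iteration {it}")

        length = path.length
        disp = float(np.sqrt(np.mean(np.sum((images - prev) ** 2, axis=1))) / length)
        history.append(disp)
        if disp < params.tol:
            converged = True
            break

    final = StringPath.from_images(images, iteration=it)
    final.arc_fractions = np.linspace(0.0, 1.0, K)
    return final, {
        "displacement": np.array(history),
        "converged": converged,
        "n_iterations": it,
    }


def project_progress(theta: np.ndarray, path: StringPath) -> float:
    """Arc fraction of the orthogonal projection of ``theta`` onto the string.

    The point is projected onto every segment of the piecewise-linear path
    (clamped to segment ends); the closest projection wins, ties broken
    toward the lower segment index.
    """
    return float(project_progress_batch(np.atleast_1d(theta)[None, :], path)[0])


def project_progress_batch(
    thetas: np.ndarray, path: StringPath, return_distances: bool = False
):
    """Vectorized :func:`project_progress` for an ``(N, dim)`` array.

    With ``return_distances`` also returns each point's distance to its
    projection (the transverse offset from the path) and an ``interior``
    mask that is False for points lying beyond the path's ends (their
    nearest polyline point is a clamped endpoint, so they have no
    orthogonal projection onto the open path).
    """
    thetas = np.asarray(thetas, dtype=float)
    z = path.images
    s = path.arc_fractions
    a = z[:-1]                       # (K-1, dim)
    d = z[1:] - z[:-1]               # (K-1, dim)
    dd = (d * d).sum(axis=1)         # (K-1,)
    dd = np.where(dd == 0, 1.0, dd)
    n_seg = a.shape[0]

    best_dist = np.full(thetas.shape[0], np.inf)
    best_s = np.zeros(thetas.shape[0])
    interior = np.ones(thetas.shape[0], dtype=bool)
    # loop over segments (K is small); vectorized over samples
    for k in range(n_seg):
        t_raw = ((thetas - a[k]) @ d[k]) / dd[k]
        t = np.clip(t_raw, 0.0, 1.0)
        proj = a[k] + t[:, None] * d[k]
        dist = np.linalg.norm(thetas - proj, axis=1)
        better = dist < best_dist - 1e-15
        best_dist = np.where(better, dist, best_dist)
        best_s = np.where(better, s[k] + t * (s[k + 1] - s[k]), best_s)
        beyond = np.zeros(thetas.shape[0], dtype=bool)
        if k == 0:
            beyond |= t_raw < 0.0
        if k == n_seg - 1:
            beyond |= t_raw > 1.0
        interior = np.where(better, ~beyond, interior)
    if return_distances:
        return best_s, best_dist, interior
    return best_s
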