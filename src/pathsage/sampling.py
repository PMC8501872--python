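"""Overdamped Langevin sampling with harmonic restraints.

The sampler integrates the Euler--Maruyama discretization of overdamped
Langevin dynamics,

    x <- x - (dt / gamma) * grad[V + bias](x) + sqrt(2 kT dt / gamma) * xi,

with ``xi`` standard normal, under an optional static or moving harmonic
restraint ``(kappa/2) |x - c|^2``.  This is the sampling backend for
mean-force estimation, umbrella sampling, and targeted (moving-restraint)
path generation.

All randomness flows through explicitly seeded ``numpy`` generators; a call
with the same parameters twice yields bitwise-identical sample streams.
Many independent chains can be advanced simultaneously (one numpy update
per time step) which is what makes per-image sampling of a 64-image string
affordable in pure Python.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .systems import CVSystem

__all__ = [
    "LangevinParams",
    "Restraint",
    "sample_restrained",
    "tmd_path",
    "DivergenceError",
    "save_samples",
    "load_samples",
]


class DivergenceError(RuntimeError):
    """Raised when a trajectory leaves the system domain box by 10x."""

    def __init__(self, step: int, chain: int | None = None):
        where = f" (chain {chain})" if chain is not None else ""
        super().__init__(f"trajectory diverged at step {step}{where}")
        self.step = step
        self.chain = chain


@dataclass(frozen=True)
class LangevinParams:
    """Integrator parameters in reduced units (kT = 1, gamma = 1 defaults)."""

    dt: float = 1e-4
    friction: float = 1.0
    kT: float = 1.0
    n_steps: int = 10_000
    seed: int = 0
    burn_in_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        if self.kT < 0:
            raise ValueError("kT must be non-negative")
        if not 0 <= self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in [0, 1)")


@dataclass(frozen=True)
class Restraint:
    """Harmonic bias ``(kappa/2)|x - center|^2``; optionally moving.

    If ``moving_target`` is given, the center is interpolated linearly from
    ``center`` to ``moving_target`` over ``schedule_steps`` integrator steps
    (targeted-dynamics style driving) and held at the target afterwards.
    """

    center: np.ndarray
    kappa: float
    moving_target: Optional[np.ndarray] = None
    schedule_steps: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.atleast_1d(np.asarray(self.center, dtype=float)))
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.moving_target is not None:
            tgt = np.atleast_1d(np.asarray(self.moving_target, dtype=float))
            if tgt.shape != self.center.shape:
                raise ValueError("moving_target dimensionality differs from center")
            object.__setattr__(self, "moving_target", tgt)
            if not self.schedule_steps or self.schedule_steps <= 0:
                raise ValueError("moving restraint requires positive schedule_steps")


def _simulate_batch(
    system: CVSystem,
    x0: np.ndarray,
    centers: np.ndarray,
    kappa: float,
    params: LangevinParams,
    seeds: Sequence[int],
    moving_targets: np.ndarray | None = None,
    schedule_steps: int | None = None,
    record: bool | str = True,
) -> np.ndarray:
    """Advance ``n_chains`` independent restrained chains simultaneously.

    Each chain draws its noise from its own seeded generator so that a
    chain's sample stream is independent of how many chains run alongside
    it.  Returns the recorded positions, shape ``(n_chains, n_steps, dim)``;
    with ``record=False`` only the final positions ``(n_chains, dim)``;
    with ``record="mean"`` the post-burn-in time average per chain
    ``(n_chains, dim)`` (constant memory — used for stiff mean-force
    estimation where storing every step would be wasteful).
    """
    x = np.array(x0, dtype=float, copy=True).reshape(-1, system.dim)
    n_chains = x.shape[0]
    centers = np.asarray(centers, dtype=float).reshape(n_chains, system.dim)
    if len(seeds) != n_chains:
        raise ValueError("one seed per chain required")

    n = params.n_steps
    mean_only = record == "mean"
    # Pre-drawn per-chain noise keeps per-chain streams seed-stable while the
    # time loop stays a single vectorized update over all chains.  In
    # mean-only mode noise is drawn in blocks to bound memory.
    generators = [np.random.default_rng(int(s)) for s in seeds]
    block = 20_000 if mean_only else n
    noise = np.empty((n_chains, min(block, n), system.dim))

    def fill_noise(n_draw):
        for i, g in enumerate(generators):
            noise[i, :n_draw] = g.standard_normal((n_draw, system.dim))

    fill_noise(min(block, n))
    sigma = np.sqrt(2.0 * params.kT * params.dt / params.friction)
    a = params.dt / params.friction

    lo = system.domain[:, 0]
    hi = system.domain[:, 1]
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    guard = 10.0 * half  # divergence guard at 10x the domain box

    if moving_targets is not None:
        moving_targets = np.asarray(moving_targets, dtype=float).reshape(n_chains, system.dim)

    full_record = record is True
    out = np.empty((n_chains, n, system.dim)) if full_record else None
    skip = int(round(params.burn_in_fraction * n)) if mean_only else 0
    acc = np.zeros((n_chains, system.dim)) if mean_only else None
    n_acc = 0
    c = centers.copy()
    for t in range(n):
        tb = t % block
        if mean_only and tb == 0 and t > 0:
            fill_noise(min(block, n - t))
        if moving_targets is not None:
            frac = min(1.0, (t + 1) / schedule_steps)
            c = centers + frac * (moving_targets - centers)
        g = system.gradient(x) + kappa * (x - c)
        x = x - a * g + sigma * noise[:, tb, :]
        if full_record:
            out[:, t, :] = x
        elif mean_only and t >= skip:
            acc += x
            n_acc += 1
        if not np.all(np.abs(x - mid) <= guard):
            bad = int(np.argmax(np.any(np.abs(x - mid) > guard, axis=1)))
            raise DivergenceError(step=t, chain=bad if n_chains > 1 else None)
    if full_record:
        return out
    if mean_only:
        return acc / max(n_acc, 1)
    return x


def sample_restrained(
    system: CVSystem,
    restraint: Restraint,
    params: LangevinParams,
    start: np.ndarray | None = None,
) -> np.ndarray:
    """Sample a single restrained chain; returns post-burn-in CV samples.

    The chain starts at the restraint center unless ``start`` is given.
    Shape of the result: ``(n_kept, dim)``.
    """
    if restraint.center.shape[0] != system.dim:
        raise ValueError(
            f"restraint center dim {restraint.center.shape[0]} != system dim {system.dim}"
        )
    x0 = restraint.center if start is None else np.asarray(start, dtype=float)
    traj = _simulate_batch(
        system,
        x0[None, :],
        restraint.center[None, :],
        restraint.kappa,
        params,
        seeds=[params.seed],
        moving_targets=None if restraint.moving_target is None else restraint.moving_target[None, :],
        schedule_steps=restraint.schedule_steps,
    )[0]
    skip = int(round(params.burn_in_fraction * params.n_steps))
    return traj[skip:]


def save_samples(
    path,
    samples: np.ndarray,
    system: CVSystem,
    restraint: Restraint,
    params: LangevinParams,
) -> None:
    """Write samples as a plain-text columnar file (one CV vector per line)
    with a header naming the system, restraint and seed."""
    center = " ".join(repr(float(c)) for c in restraint.center)
    header = (
        f"system={system.name} kappa={restraint.kappa!r} "
        f"center=[{center}] seed={params.seed}"
    )
    np.savetxt(path, np.atleast_2d(samples), header=header)


def load_samples(path) -> np.ndarray:
    """Read a columnar sample file written by :func:`save_samples`."""
    return np.atleast_2d(np.loadtxt(path))


def _resample_equal_arclength(trace: np.ndarray, n_images: int) -> np.ndarray:
    """Resample a polyline trace at ``n_images`` equal-arc-length points."""
    seg = np.linalg.norm(np.diff(trace, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise ValueError("trace has zero length")
    targets = np.linspace(0.0, total, n_images)
    out = np.empty((n_images, trace.shape[1]))
    for d in range(trace.shape[1]):
        out[:, d] = np.interp(targets, s, trace[:, d])
    return out


def tmd_path(
    system: CVSystem,
    start: np.ndarray,
    target: np.ndarray,
    schedule_steps: int,
    n_images: int,
    params: LangevinParams,
    kappa: float = 200.0,
    smooth_window: int | None = None,
):
    """Generate an initial path by driving a restrained chain from start to target.

    A harmonic restraint of strength ``kappa`` has its center moved linearly
    from ``start`` to ``target`` over ``schedule_steps`` integrator steps;
    the chain's CV trace is recorded and resampled at ``n_images`` points of
    equal arc length.  The first and last images are pinned exactly to
    ``start`` and ``target``.

    At finite temperature the raw trace carries thermal jitter whose
    accumulated arc length dwarfs the net displacement, so the trace is
    first smoothed with a boxcar filter (``smooth_window`` steps, default
    ``schedule_steps // (2 * n_images)``) — otherwise equal-arc-length
    resampling lands on noise wiggles instead of the driven path.
    """
    from .string import StringPath  # local import to avoid a cycle

    start = np.atleast_1d(np.asarray(start, dtype=float))
    target = np.atleast_1d(np.asarray(target, dtype=float))
    if n_images < 3:
        raise ValueError("n_images must be >= 3")
    if np.allclose(start, target):
        raise ValueError("degenerate path: start equals target")

    p = params if params.n_steps >= schedule_steps else LangevinParams(
        dt=params.dt, friction=params.friction, kT=params.kT,
        n_steps=schedule_steps, seed=params.seed,
        burn_in_fraction=params.burn_in_fraction,
    )
    traj = _simulate_batch(
        system,
        start[None, :],
        start[None, :],
        kappa,
        p,
        seeds=[p.seed],
        moving_targets=target[None, :],
        schedule_steps=schedule_steps,
    )[0]
    trace = traj[:schedule_steps]
    if smooth_window is None:
        smooth_window = max(1, schedule_steps // (2 * n_images))
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        trace = np.stack(
            [np.convolve(trace[:, d], kernel, mode="valid") for d in range(trace.shape[1])],
            axis=1,
        )
    trace = np.vstack([start[None, :], trace, target[None, :]])
    images = _resample_equal_arclength(trace, n_images)
    images[0] = start
    images[-1] = target
    return StringPath.from_images(images)
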