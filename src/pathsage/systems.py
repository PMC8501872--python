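"""Analytic collective-variable (CV) energy landscapes.

A :class:`CVSystem` bundles a low-dimensional energy surface (in units of
kT) with its analytic gradient.  These landscapes stand in for the
high-dimensional molecular potential when exercising the string method and
umbrella sampling at desk scale: the Mueller--Brown surface provides a
two-dimensional landscape with three minima and two saddles, the symmetric
double well provides a one-dimensional barrier of known height, and the
quadratic basin has closed-form restrained statistics used throughout the
test-suite oracles.

Systems are addressable by name through :func:`get_system`, e.g.
``"mueller_brown"``, ``"double_well(5)"`` or ``"quadratic(2, dim=2)"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "CVSystem",
    "mueller_brown",
    "mueller_brown_system",
    "double_well_system",
    "quadratic_system",
    "get_system",
    "MUELLER_BROWN_MINIMA",
]


@dataclass(frozen=True)
class CVSystem:
    """An energy landscape over a low-dimensional CV space.

    Parameters
    ----------
    dim:
        CV dimensionality.
    energy:
        Callable mapping an array of shape ``(..., dim)`` to energies of
        shape ``(...,)``, in units of kT.
    gradient:
        Callable mapping ``(..., dim)`` to gradients ``(..., dim)``.
    name:
        Registry label.
    domain:
        ``(dim, 2)`` array of per-coordinate box bounds on which the energy
        is guaranteed finite; also used for the divergence guard during
        sampling.
    """

    dim: int
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    name: str
    domain: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.domain is None:
            box = np.tile(np.array([-3.0, 3.0]), (self.dim, 1))
            object.__setattr__(self, "domain", box)
        else:
            object.__setattr__(
                self, "domain", np.asarray(self.domain, dtype=float).reshape(self.dim, 2)
            )


# -- Mueller-Brown ----------------------------------------------------------

_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])

#: Approximate locations of the three local minima (deep, shallow, deep).
MUELLER_BROWN_MINIMA = {
    "A": np.array([-0.55822364, 1.44172584]),
    "B": np.array([-0.05001083, 0.46669410]),
    "C": np.array([0.62349942, 0.02803776]),
}


def mueller_brown(point: np.ndarray) -> np.ndarray:
    """Evaluate the four-term Mueller--Brown potential.

    Accepts a single 2-vector or an array of shape ``(..., 2)``.
    """
    p = np.asarray(point, dtype=float)
    if p.shape[-1] != 2:
        raise ValueError("mueller_brown expects 2-vectors")
    if not np.all(np.isfinite(p)):
        raise ValueError("mueller_brown: non-finite input point")
    dx = p[..., 0, None] - _MB_x0
    dy = p[..., 1, None] - _MB_y0
    terms = _MB_A * np.exp(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2)
    return terms.sum(axis=-1)


def _mueller_brown_grad(point: np.ndarray) -> np.ndarray:
    p = np.asarray(point, dtype=float)
    dx = p[..., 0, None] - _MB_x0
    dy = p[..., 1, None] - _MB_y0
    e = _MB_A * np.exp(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2)
    gx = (e * (2.0 * _MB_a * dx + _MB_b * dy)).sum(axis=-1)
    gy = (e * (_MB_b * dx + 2.0 * _MB_c * dy)).sum(axis=-1)
    return np.stack([gx, gy], axis=-1)


def mueller_brown_system() -> CVSystem:
    """The Mueller--Brown landscape as a :class:`CVSystem` on [-3, 3]^2."""
    return CVSystem(
        dim=2,
        energy=mueller_brown,
        gradient=_mueller_brown_grad,
        name="mueller_brown",
        domain=np.array([[-3.0, 3.0], [-3.0, 3.0]]),
    )


# -- 1D double well ---------------------------------------------------------


def double_well_system(h: float = 5.0) -> CVSystem:
    """Symmetric quartic double well ``V(x) = h (x^2 - 1)^2``.

    Minima at x = +-1 with V = 0 and a barrier of height ``h`` kT at x = 0.
    """
    h = float(h)

    def energy(p: np.ndarray) -> np.ndarray:
        x = np.asarray(p, dtype=float)[..., 0]
        return h * (x**2 - 1.0) ** 2

    def gradient(p: np.ndarray) -> np.ndarray:
        x = np.asarray(p, dtype=float)[..., 0]
        return (4.0 * h * x * (x**2 - 1.0))[..., None]

    return CVSystem(
        dim=1, energy=energy, gradient=gradient,
        name=f"double_well({h:g})", domain=np.array([[-3.0, 3.0]]),
    )


def quadratic_system(k: float = 1.0, dim: int = 1) -> CVSystem:
    """Isotropic harmonic basin ``V(z) = (k/2) |z|^2``."""
    k = float(k)

    def energy(p: np.ndarray) -> np.ndarray:
        z = np.asarray(p, dtype=float)
        return 0.5 * k * (z**2).sum(axis=-1)

    def gradient(p: np.ndarray) -> np.ndarray:
        return k * np.asarray(p, dtype=float)

    return CVSystem(
        dim=dim, energy=energy, gradient=gradient,
        name=f"quadratic({k:g}, dim={dim})",
        domain=np.tile(np.array([-10.0, 10.0]), (dim, 1)),
    )


def flat_system(dim: int = 2) -> CVSystem:
    """Zero-energy landscape (useful for degenerate-limit checks)."""

    def energy(p: np.ndarray) -> np.ndarray:
        return np.zeros(np.asarray(p, dtype=float).shape[:-1])

    def gradient(p: np.ndarray) -> np.ndarray:
        return np.zeros_like(np.asarray(p, dtype=float))

    return CVSystem(
        dim=dim, energy=energy, gradient=gradient, name=f"flat(dim={dim})",
        domain=np.tile(np.array([-100.0, 100.0]), (dim, 1)),
    )


_CALL_RE = re.compile(r"^(?P<fn>[a-z_]+)\((?P<args>[^()]*)\)$")


def get_system(name: str) -> CVSystem:
    """Resolve a system by registry name.

    Supported forms: ``mueller_brown``, ``double_well(h)``, ``quadratic(k)``,
    ``quadratic(k, dim=d)``, ``flat``, ``flat(dim=d)``.
    """
    name = name.strip()
    if name == "mueller_brown":
        return mueller_brown_system()
    if name == "flat":
        return flat_system()
    m = _CALL_RE.match(name)
    if not m:
        raise KeyError(f"unknown system {name!r}")
    fn = m.group("fn")
    args, kwargs = [], {}
    for tok in filter(None, (t.strip() for t in m.group("args").split(","))):
        if "=" in tok:
            key, val = (s.strip() for s in tok.split("=", 1))
            kwargs[key] = float(val)
        else:
            args.append(float(tok))
    if fn == "double_well":
        return double_well_system(*args, **kwargs)
    if fn == "quadratic":
        if "dim" in kwargs:
            kwargs["dim"] = int(kwargs["dim"])
        return quadratic_system(*args, **kwargs)
    if fn == "flat":
        return flat_system(int(kwargs.get("dim", args[0] if args else 2)))
    raise KeyError(f"unknown system {name!r}")
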