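"""Rigid-body superposition, distance-RMS, and geometric observables.

``superpose`` is least-squares rigid superposition (Kabsch) with a proper
rotation enforced; ``drms`` is the distance RMSD

    dRMS(A, B) = sqrt( (1/P) sum_{i<j} (d_ij(A) - d_ij(B))^2 ),

over all pairs of the selected atoms (P = n(n-1)/2), which is invariant
under rigid transforms of either structure and therefore needs no prior
superposition.  The remaining operations are per-structure/per-frame
observables: three-atom bend angles, minimum inter-group distances, and
contact frequencies along a trajectory.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.spatial.transform import Rotation

from .structure import SelectionError, Structure, Trajectory, matched_coords

__all__ = [
    "superpose",
    "apply_transform",
    "drms",
    "bend_angle",
    "group_min_distance",
    "contact_frequency",
]


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with ``x_fit = R @ x + t``; ``R`` is a proper
    rotation (det = +1, reflections never used) and ``rmsd`` the post-fit
    value.  Requires >= 3 non-collinear points in each set.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape:
        raise ValueError(f"point count mismatch: {mob.shape} vs {ref.shape}")
    if mob.ndim != 2 or mob.shape[1] != 3 or mob.shape[0] < 3:
        raise ValueError("need >= 3 points of dimension 3")
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    mob0, ref0 = mob - mc, ref - rc
    if np.linalg.matrix_rank(mob0, tol=1e-9) < 2 or np.linalg.matrix_rank(ref0, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point set")
    rot, rssd = Rotation.align_vectors(ref0, mob0)
    R = rot.as_matrix()
    t = rc - R @ mc
    rmsd = float(rssd / np.sqrt(mob.shape[0]))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ np.asarray(R).T + np.asarray(t)


def drms(a: Structure, b: Structure, selection: str = "name CA") -> float:
    """Distance RMSD over all selected-atom pairs, in Angstrom."""
    ca, cb = matched_coords(a, b, selection)
    if ca.shape[0] < 3:
        raise SelectionError("need >= 3 matched atoms for dRMS")
    da, db = pdist(ca), pdist(cb)
    return float(np.sqrt(np.mean((da - db) ** 2)))


def drms_coords(ca: np.ndarray, cb: np.ndarray) -> float:
    """dRMS on bare coordinate arrays (same atom order assumed)."""
    da, db = pdist(ca), pdist(cb)
    return float(np.sqrt(np.mean((da - db) ** 2)))


def bend_angle(s: Structure, a1: str, a2: str, a3: str) -> float:
    """Angle (degrees) at ``a2`` between the three selected atoms.

    Each selector must resolve to exactly one atom, e.g.
    ``"resid 89 and name CA"``.
    """
    pts = []
    for spec in (a1, a2, a3):
        sel = s.select(spec)
        if sel.n_atoms != 1:
            raise SelectionError(f"atom spec {spec!r} resolves to {sel.n_atoms} atoms")
        pts.append(sel.coords[0])
    p1, p2, p3 = pts
    v1, v2 = p1 - p2, p3 - p2
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("coincident points in angle definition")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _pair_min_distance(ca: np.ndarray, cb: np.ndarray, exclude_same: np.ndarray | None) -> float:
    d = cdist(ca, cb)
    if exclude_same is not None:
        d[exclude_same] = np.inf
    return float(d.min())


def group_min_distance(s: Structure, sel_a: str, sel_b: str) -> float:
    """Minimum pairwise distance (A) between two atom groups.

    If the selections overlap, self-pairs (identical atoms) are excluded so
    the nearest *distinct* pair is reported.
    """
    ga, gb = s.select(sel_a), s.select(sel_b)
    ka = ga.atom_keys()
    kb = gb.atom_keys()
    shared = set(ka) & set(kb)
    excl = None
    if shared:
        excl = np.zeros((len(ka), len(kb)), dtype=bool)
        idx_b = {k: i for i, k in enumerate(kb)}
        for i, k in enumerate(ka):
            if k in shared:
                excl[i, idx_b[k]] = True
    return _pair_min_distance(ga.coords, gb.coords, excl)


def contact_frequency(
    t: Trajectory, sel_a: str, sel_b: str, cutoff: float = 4.0
) -> float:
    """Fraction of frames whose minimum A-B distance is below ``cutoff``."""
    ma, mb = t.mask(sel_a), t.mask(sel_b)
    if not ma.any():
        raise SelectionError(f"selection {sel_a!r} matches no atoms")
    if not mb.any():
        raise SelectionError(f"selection {sel_b!r} matches no atoms")
    coords = t.coords
    hits = 0
    for f in range(t.n_frames):
        if cdist(coords[f][ma], coords[f][mb]).min() < cutoff:
            hits += 1
    return hits / t.n_frames
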