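"""Synthetic structures and trajectories with planted ground truth.

Every analysis operation in this package is exercised against fixtures
whose answer is known by construction: two-domain Calpha traces with a
planted rigid-body rotation, trajectories with planted metastable
substates, membrane snapshots with a planted lipid hotspot, and ion
trajectories with planted site occupancies.  The generators return the
ground truth alongside the data and are bitwise deterministic per seed.

These fixtures carry the *statistical and geometric* structure the
analyses look for; they make no attempt at physical realism (no side
chains, no excluded-volume membrane, no electrostatics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import biotite.structure as struc
from scipy.spatial.transform import Rotation

from .structure import Structure, Trajectory

__all__ = [
    "PlantedDomainSpec",
    "PlantedPathSpec",
    "make_ca_trace",
    "make_two_domain_pair",
    "make_multi_domain_pair",
    "make_substate_trajectory",
    "make_membrane_snapshot",
    "make_ion_frames",
]

CA_SPACING = 3.8  # consecutive Calpha distance, Angstrom


@dataclass(frozen=True)
class PlantedDomainSpec:
    """Two-domain fixture: ``n_mobile`` residues rotated against ``n_fixed``."""

    n_fixed: int = 40
    n_mobile: int = 40
    angle: float = 30.0           # degrees
    axis: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    pivot: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sigma: float = 0.0      # Angstrom, added to the second structure
    seed: int = 0
    trace_seed: int | None = None  # share one backbone across many draws

    def __post_init__(self) -> None:
        if self.n_fixed < 10 or self.n_mobile < 10:
            raise ValueError("domain sizes must be >= 10 residues")
        if not 0 <= self.angle <= 180:
            raise ValueError("angle must be in [0, 180] degrees")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass(frozen=True)
class PlantedPathSpec:
    """Trajectory with contiguous metastable substate segments."""

    n_frames: int = 64
    n_substates: int = 5
    n_residues: int = 30
    intra_spread: float = 0.3     # per-frame jitter RMSD around its anchor, A
    separation: float = 5.0       # RMSD between consecutive anchors, A
    boundaries: Tuple[int, ...] = ()   # optional segment start indices
    seed: int = 0

    def segment_bounds(self) -> List[Tuple[int, int]]:
        if self.boundaries:
            starts = list(self.boundaries)
            if starts[0] != 0:
                raise ValueError("first boundary must be 0")
        else:
            starts = [round(i * self.n_frames / self.n_substates) for i in range(self.n_substates)]
        starts.append(self.n_frames)
        bounds = [(starts[i], starts[i + 1]) for i in range(len(starts) - 1)]
        if any(hi <= lo for lo, hi in bounds):
            raise ValueError("boundaries must partition the frames contiguously")
        return bounds


def _ca_atom_array(coords: np.ndarray, chain: str = "A") -> struc.AtomArray:
    n = coords.shape[0]
    atoms = struc.AtomArray(n)
    atoms.coord = coords.astype(np.float32)
    atoms.chain_id = np.full(n, chain)
    atoms.res_id = np.arange(1, n + 1)
    atoms.res_name = np.full(n, "ALA")
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    return atoms


_TRACE_CACHE: dict = {}


def _trace_cached(n_residues: int, seed: int) -> np.ndarray:
    key = (n_residues, seed)
    if key not in _TRACE_CACHE:
        _TRACE_CACHE[key] = make_ca_trace(n_residues, seed=seed)
    return _TRACE_CACHE[key]


def make_ca_trace(n_residues: int, seed: int = 0, min_separation: float = 3.0) -> np.ndarray:
    """Self-avoiding random Calpha trace with 3.8 A consecutive spacing."""
    rng = np.random.default_rng(seed)
    coords = np.zeros((n_residues, 3))
    direction = np.array([1.0, 0.0, 0.0])
    for i in range(1, n_residues):
        for _ in range(200):
            # persistent direction with random kink keeps the walk open
            step = direction + 0.9 * rng.standard_normal(3)
            step *= CA_SPACING / np.linalg.norm(step)
            cand = coords[i - 1] + step
            clashes = np.linalg.norm(coords[: max(i - 1, 0)] - cand, axis=1)
            if clashes.size == 0 or clashes.min() >= min_separation:
                coords[i] = cand
                direction = step / CA_SPACING
                break
        else:
            raise RuntimeError("self-avoiding walk failed; try another seed")
    return coords


def _rotate_about(coords: np.ndarray, angle_deg: float, axis, pivot) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()
    pivot = np.asarray(pivot, dtype=float)
    return (coords - pivot) @ R.T + pivot


def make_multi_domain_pair(
    domain_sizes: Sequence[int],
    motions: Sequence[Tuple[float, Sequence[float], Sequence[float]]],
    noise_sigma: float = 0.0,
    seed: int = 0,
    trace_seed: int | None = None,
) -> Tuple[Structure, Structure, Dict]:
    """General planted-domain pair: the first domain stays, the rest move.

    ``motions[i]`` = (angle_deg, axis, pivot) applied to domain ``i+1``.
    Returns (A, B, ground_truth) with ground-truth domain labels per residue.
    ``trace_seed`` fixes the backbone independently of the noise seed, so
    many noise realizations can share one (expensive) self-avoiding trace.
    """
    if len(motions) != len(domain_sizes) - 1:
        raise ValueError("need one motion per non-reference domain")
    n = int(sum(domain_sizes))
    coords_a = _trace_cached(n, seed if trace_seed is None else trace_seed)
    coords_b = coords_a.copy()
    labels = np.zeros(n, dtype=int)
    start = domain_sizes[0]
    for d, (size, (angle, axis, pivot)) in enumerate(zip(domain_sizes[1:], motions), start=1):
        seg = slice(start, start + size)
        labels[seg] = d
        coords_b[seg] = _rotate_about(coords_b[seg], angle, axis, pivot)
        start += size
    rng = np.random.default_rng(seed + 1)
    if noise_sigma > 0:
        coords_b = coords_b + noise_sigma * rng.standard_normal(coords_b.shape)
    truth = {
        "domain_labels": labels,
        "motions": [
            {"angle": float(a), "axis": list(map(float, ax)), "pivot": list(map(float, pv))}
            for a, ax, pv in motions
        ],
        "noise_sigma": noise_sigma,
    }
    return Structure(_ca_atom_array(coords_a)), Structure(_ca_atom_array(coords_b)), truth


def make_two_domain_pair(spec: PlantedDomainSpec) -> Tuple[Structure, Structure, Dict]:
    """Two-domain Calpha pair with one planted rigid rotation."""
    return make_multi_domain_pair(
        [spec.n_fixed, spec.n_mobile],
        [(spec.angle, spec.axis, spec.pivot)],
        noise_sigma=spec.noise_sigma,
        seed=spec.seed,
        trace_seed=spec.trace_seed,
    )


def make_substate_trajectory(spec: PlantedPathSpec) -> Tuple[Trajectory, np.ndarray]:
    """Trajectory of frames clustered around successive anchor conformations.

    Consecutive anchors are ``separation`` (RMSD) apart; frames jitter
    ``intra_spread`` (RMSD) around their segment's anchor.  Returns the
    frames in path order plus the true substate label per frame.
    """
    if spec.separation <= spec.intra_spread:
        raise ValueError(
            "anchor separation must exceed intra-substate spread for a "
            "resolvable clustering task"
        )
    rng = np.random.default_rng(spec.seed)
    base = make_ca_trace(spec.n_residues, seed=spec.seed)
    bounds = spec.segment_bounds()

    anchors = [base]
    for _ in range(1, len(bounds)):
        disp = rng.standard_normal(base.shape)
        disp *= spec.separation / np.sqrt(np.mean(np.sum(disp**2, axis=1)))
        anchors.append(anchors[-1] + disp)

    frames, labels = [], []
    for lab, (lo, hi) in enumerate(bounds):
        for _ in range(lo, hi):
            jitter = rng.standard_normal(base.shape)
            jitter *= spec.intra_spread / np.sqrt(np.mean(np.sum(jitter**2, axis=1)))
            frames.append(Structure(_ca_atom_array(anchors[lab] + jitter)))
            labels.append(lab)
    return Trajectory.from_structures(frames), np.array(labels)


def make_membrane_snapshot(
    n_lipids: int = 2000,
    hotspot_xy: Tuple[float, float] = (30.0, 0.0),
    enrichment_factor: float = 1.0,
    n_frames: int = 10,
    seed: int = 0,
    annulus: Tuple[float, float] = (20.0, 60.0),
    leaflet_z: float = 18.0,
    hotspot_radius: float = 8.0,
) -> Tuple[Trajectory, Dict]:
    """Membrane snapshots: lipid P atoms in an annulus, with a hotspot.

    Lipids are distributed uniformly over the annulus around a protein
    placeholder (a ring of Calpha pseudo-atoms at the origin), except that
    a disc at ``hotspot_xy`` in the *upper* leaflet carries
    ``enrichment_factor`` times the background density.  Leaflets sit at
    z = +-``leaflet_z``.
    """
    if enrichment_factor < 1.0:
        raise ValueError("enrichment_factor must be >= 1")
    rng = np.random.default_rng(seed)
    r_in, r_out = annulus
    hot = np.asarray(hotspot_xy, dtype=float)

    # protein placeholder: ring of 20 CA atoms, radius just inside the annulus
    ring_angles = np.linspace(0, 2 * np.pi, 20, endpoint=False)
    ring = np.stack(
        [0.8 * r_in * np.cos(ring_angles), 0.8 * r_in * np.sin(ring_angles), np.zeros(20)],
        axis=1,
    )

    def sample_annulus(n):
        r = np.sqrt(rng.uniform(r_in**2, r_out**2, size=n))
        phi = rng.uniform(0, 2 * np.pi, size=n)
        return np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)

    def sample_disc(n):
        # peaked (truncated-Gaussian) cloud, as for a lipid bound at a
        # residue: the density maximum sits at the hotspot center
        out = np.empty((n, 2))
        filled = 0
        while filled < n:
            cand = rng.normal(0.0, hotspot_radius / 2.5, size=(2 * (n - filled), 2))
            cand = cand[np.hypot(cand[:, 0], cand[:, 1]) < hotspot_radius]
            take = min(len(cand), n - filled)
            out[filled:filled + take] = cand[:take]
            filled += take
        return hot + out

    # acceptance-ratio bookkeeping: the hotspot disc carries (factor - 1)
    # extra lipids on top of the uniform background, upper leaflet only
    disc_area = np.pi * hotspot_radius**2
    ann_area = np.pi * (r_out**2 - r_in**2)
    extra_frac = (enrichment_factor - 1.0) * disc_area / ann_area
    n_extra = int(round(n_lipids * extra_frac / (1.0 + extra_frac)))
    n_uniform = n_lipids - n_extra

    frames = []
    for _ in range(n_frames):
        xy = sample_annulus(n_uniform)
        z = np.where(rng.uniform(size=n_uniform) < 0.5, leaflet_z, -leaflet_z)
        if n_extra:
            xy_hot = sample_disc(n_extra)
            xy = np.vstack([xy, xy_hot])
            z = np.concatenate([z, np.full(n_extra, leaflet_z)])
        n_atoms = len(ring) + n_lipids
        atoms = struc.AtomArray(n_atoms)
        coords = np.zeros((n_atoms, 3), dtype=np.float32)
        coords[: len(ring)] = ring
        coords[len(ring):, :2] = xy
        coords[len(ring):, 2] = z
        atoms.coord = coords
        atoms.chain_id = np.array(["A"] * len(ring) + ["L"] * n_lipids)
        atoms.res_id = np.concatenate(
            [np.arange(1, len(ring) + 1), np.arange(1, n_lipids + 1)]
        )
        atoms.res_name = np.array(["ALA"] * len(ring) + ["DOP"] * n_lipids)
        atoms.atom_name = np.array(["CA"] * len(ring) + ["P"] * n_lipids)
        atoms.element = np.array(["C"] * len(ring) + ["P"] * n_lipids)
        atoms.hetero = np.array([False] * len(ring) + [True] * n_lipids)
        frames.append(Structure(atoms))
    truth = {
        "hotspot_xy": hot.tolist(),
        "enrichment_factor": enrichment_factor,
        "n_hotspot_lipids_per_frame": n_extra,
        "leaflet_z": leaflet_z,
    }
    return Trajectory.from_structures(frames), truth


def make_ion_frames(
    n_frames: int,
    occupancy_counts: Sequence[int],
    site_center: Tuple[float, float, float] = (0.0, 0.0, 0.0),
    cutoff: float = 4.0,
    n_decoys: int = 5,
    seed: int = 0,
) -> Tuple[Trajectory, Dict]:
    """Ion trajectory with a planted per-frame site occupancy.

    Each frame places ``occupancy_counts[f]`` potassium ions within
    ``cutoff`` of the binding-site atoms and parks the remaining ions
    (plus ``n_decoys`` permanent decoys) far outside.  The site is modeled
    as four oxygen pseudo-atoms around ``site_center``.
    """
    counts = np.asarray(occupancy_counts, dtype=int)
    if len(counts) != n_frames:
        raise ValueError("one occupancy count per frame required")
    if (counts < 0).any():
        raise ValueError("occupancy counts must be >= 0")
    rng = np.random.default_rng(seed)
    center = np.asarray(site_center, dtype=float)
    site = center + np.array(
        [[1.5, 0, 0], [-1.5, 0, 0], [0, 1.5, 0], [0, -1.5, 0]]
    )
    n_ions = int(counts.max(initial=0)) + n_decoys

    frames = []
    for f in range(n_frames):
        ions = np.empty((n_ions, 3))
        k = counts[f]
        for i in range(k):
            # uniform in a small ball around a random site atom, safely inside the cutoff
            v = rng.standard_normal(3)
            v *= (0.5 * cutoff * rng.uniform() ** (1 / 3)) / np.linalg.norm(v)
            ions[i] = site[rng.integers(len(site))] + v
        far = center + np.array([60.0, 0.0, 0.0])
        for i in range(k, n_ions):
            ions[i] = far + 10.0 * rng.standard_normal(3) + np.array([0, 10.0 * i, 0])
        n_atoms = len(site) + n_ions
        atoms = struc.AtomArray(n_atoms)
        coords = np.vstack([site, ions]).astype(np.float32)
        atoms.coord = coords
        atoms.chain_id = np.array(["A"] * len(site) + ["I"] * n_ions)
        atoms.res_id = np.concatenate([np.arange(1, len(site) + 1), np.arange(1, n_ions + 1)])
        atoms.res_name = np.array(["ASP"] * len(site) + ["K"] * n_ions)
        atoms.atom_name = np.array(["OD1"] * len(site) + ["K"] * n_ions)
        atoms.element = np.array(["O"] * len(site) + ["K"] * n_ions)
        atoms.hetero = np.array([False] * len(site) + [True] * n_ions)
        frames.append(Structure(atoms))
    truth = {"counts": counts.tolist(), "cutoff": cutoff}
    return Trajectory.from_structures(frames), truth
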